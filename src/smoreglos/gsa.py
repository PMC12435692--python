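"""Global sensitivity engines (Morris/MOAT and eFAST) and the surrogate-
transfer estimator.

Both engines operate on an arbitrary scalar metric f over a parameter box
Omega, so the same machinery serves direct ABM evaluation and the
surrogate-transfer shortcut:

* **MOAT (Morris one-at-a-time screening).**  Randomized trajectories on a
  p-level grid of the unit hypercube perturb each parameter exactly once by
  Delta = p/(2(p-1)).  The elementary effect of parameter i is the scaled
  output difference along that step; its mean (mu), mean magnitude
  (mu_star) and standard deviation (sigma) over r trajectories summarize
  sensitivity.  Effects are computed in normalized parameter units by
  default, so they carry the metric's own units per full-range change.

* **eFAST (extended Fourier amplitude sensitivity test).**  Each parameter
  in turn is driven along a space-filling search curve at the highest
  frequency omega_max = floor((Ns-1)/(2M)) while the complementary
  parameters oscillate at low frequencies; the output variance at
  omega_max's first M harmonics gives the main-effect index S_i, and the
  variance in the low-frequency band (omega <= omega_max/2) gives the
  complementary variance behind the total-effect index S_Ti = 1 - V_c/V.
  Estimates are averaged over Nr random phase resamplings.

* **Surrogate transfer.**  The metric at an ABM parameter vector is
  approximated by the mean of the surrogate-side metric over a Monte-Carlo
  sample of the hyperrectangle of surrogate parameters consistent with
  that vector, after which any GSA method is applied unchanged.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .hypersurface import HyperrectangleField, sample_hyperrectangle
from .metrics import Trajectory

__all__ = [
    "ParameterSpace",
    "MetricFunction",
    "MoatResult",
    "EfastResult",
    "morris_design",
    "morris_indices",
    "efast_design",
    "efast_indices",
    "surrogate_metric",
    "abm_metric",
    "run_gsa",
]


@dataclass
class ParameterSpace:
    """Named parameter box Omega with a sampling distribution (uniform)."""

    names: list
    bounds: np.ndarray
    distribution: str = "uniform"

    def __post_init__(self):
        self.names = list(self.names)
        self.bounds = np.asarray(self.bounds, float)
        if self.bounds.shape != (len(self.names), 2):
            raise ValueError("bounds must be (m, 2)")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("bounds must be ordered lower < upper")
        if self.distribution != "uniform":
            raise ValueError("only the uniform distribution is supported")

    @property
    def m(self) -> int:
        return len(self.names)

    def unit_to_native(self, u):
        u = np.asarray(u, float)
        return self.bounds[:, 0] + u * (self.bounds[:, 1] - self.bounds[:, 0])

    def native_to_unit(self, x):
        x = np.asarray(x, float)
        return (x - self.bounds[:, 0]) / (self.bounds[:, 1] - self.bounds[:, 0])


class MetricFunction:
    """Scalar metric over Omega with an evaluation ledger and result cache.

    ``flag`` records whether values come from direct ABM simulation or the
    surrogate-transfer estimator.  Evaluations are cached by parameter
    vector, so repeated design points cost nothing.
    """

    def __init__(self, fn, flag: str, cache: bool = True):
        self._fn = fn
        self.flag = flag
        self.n_calls = 0
        self.n_evaluations = 0
        self._cache = {} if cache else None

    def __call__(self, p) -> float:
        self.n_calls += 1
        key = tuple(np.asarray(p, float)) if self._cache is not None else None
        if key is not None and key in self._cache:
            return self._cache[key]
        self.n_evaluations += 1
        val = float(self._fn(np.asarray(p, float)))
        if not np.isfinite(val):
            raise RuntimeError(f"metric returned non-finite value at {p}")
        if key is not None:
            self._cache[key] = val
        return val


def _point_seed(seed: int, p: np.ndarray) -> np.random.SeedSequence:
    digest = zlib.crc32(np.ascontiguousarray(np.asarray(p, float)).tobytes())
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest])


# -- Morris / MOAT -----------------------------------------------------------


@dataclass
class MorrisDesign:
    space: ParameterSpace
    X: np.ndarray          # (r*(m+1), m) native-unit points
    X_unit: np.ndarray
    perms: np.ndarray      # (r, m) order in which parameters are perturbed
    signs: np.ndarray      # (r, m) +-1 step direction per perturbed parameter
    delta: float
    levels: int
    r: int


@dataclass
class MoatResult:
    """Morris screening summary: mu, mu_star, sigma per parameter."""

    names: list
    mu: np.ndarray
    mu_star: np.ndarray
    sigma: np.ndarray
    r: int
    n_evaluations: int = 0


def morris_design(space: ParameterSpace, r: int, levels: int = 4, seed: int = 0) -> MorrisDesign:
    """Standard Morris trajectories on a ``levels``-level unit grid."""
    if levels % 2 != 0:
        raise ValueError("levels (p) must be even")
    if r < 1:
        raise ValueError("need at least one trajectory")
    m = space.m
    p = levels
    delta = p / (2.0 * (p - 1.0))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x4D4F4154]))
    lower_vals = np.arange(p) / (p - 1.0)
    lower_vals = lower_vals[lower_vals <= 1.0 - delta + 1e-12]
    X = np.empty((r * (m + 1), m))
    perms = np.empty((r, m), np.int64)
    signs = np.empty((r, m), np.int64)
    for t in range(r):
        v = rng.choice(lower_vals, size=m)          # feasible start of the +delta step
        d = rng.choice([-1, 1], size=m)
        base = np.where(d == 1, v, v + delta)       # mirrored for -delta steps
        perm = rng.permutation(m)
        x = base.copy()
        rows = t * (m + 1)
        X[rows] = x
        for j, i_param in enumerate(perm):
            x = x.copy()
            x[i_param] += d[i_param] * delta
            X[rows + j + 1] = x
        perms[t] = perm
        signs[t] = d[perm]
    X = np.clip(X, 0.0, 1.0)
    native = space.bounds[:, 0] + X * (space.bounds[:, 1] - space.bounds[:, 0])
    return MorrisDesign(space, native, X, perms, signs, delta, p, r)


def morris_indices(design: MorrisDesign, f_values, normalized: bool = True) -> MoatResult:
    """Elementary-effect statistics from metric values at the design points."""
    f_values = np.asarray(f_values, float)
    m, r = design.space.m, design.r
    if f_values.shape != (r * (m + 1),):
        raise ValueError("f_values misaligned with the Morris design")
    ee = np.empty((r, m))
    scale = design.space.bounds[:, 1] - design.space.bounds[:, 0]
    for t in range(r):
        rows = t * (m + 1)
        for j in range(m):
            i_param = design.perms[t, j]
            diff = f_values[rows + j + 1] - f_values[rows + j]
            e = design.signs[t, j] * diff / design.delta
            if not normalized:
                e = e / scale[i_param]
            ee[t, i_param] = e
    mu = ee.mean(axis=0)
    mu_star = np.abs(ee).mean(axis=0)
    sigma = ee.std(axis=0, ddof=1) if r > 1 else np.zeros(m)
    return MoatResult(list(design.space.names), mu, mu_star, sigma, r)


# -- eFAST -------------------------------------------------------------------


@dataclass
class EfastDesign:
    space: ParameterSpace
    X: np.ndarray          # (m, Nr, Ns, m) native points, axis 0 = parameter of interest
    omegas: np.ndarray     # (m, m) frequency table per parameter of interest
    Ns: int
    M: int
    Nr: int
    omega_max: int


@dataclass
class EfastResult:
    """Variance-based indices: main effect S_i and total effect S_Ti."""

    names: list
    S: np.ndarray
    ST: np.ndarray
    Ns: int = 0
    M: int = 0
    Nr: int = 0
    omega_max: int = 0
    n_evaluations: int = 0


def _complementary_frequencies(omega_max: int, M: int) -> list:
    """Low frequencies for the complementary parameters.

    Candidates stay below the omega_max/2 total-effect cutoff.  A frequency
    is rejected when one of its low-order harmonics (order <= M+1) lands on
    a counted main-effect frequency k*omega_max, which would attribute
    complementary variance to the parameter of interest (e.g. frequency
    omega_max/4 pollutes omega_max through any fourth-order nonlinearity).
    Larger frequencies come first (better per-curve exploration), and two
    complementary parameters share a frequency only when more are needed
    than survive the filter — sharing makes them perfectly correlated along
    the curve, so users with many parameters should raise Ns.
    """
    counted = {k * omega_max for k in range(1, M + 1)}
    good = []
    for w in range(max(1, omega_max // 2 - 1), 0, -1):
        orders = [c // w for c in counted if c % w == 0]
        if not orders or min(orders) > M + 1:
            good.append(w)
    return good or [1]


def efast_design(space: ParameterSpace, Ns: int = 65, M: int = 4, Nr: int = 4, seed: int = 0) -> EfastDesign:
    """eFAST search-curve design with random phase resamplings.

    The parameter of interest is driven at omega_max = floor((Ns-1)/(2M)),
    so the highest counted harmonic M*omega_max satisfies the Nyquist bound
    (Ns-1)/2; complementary parameters cycle through frequencies
    1..max(1, omega_max/(2M)).
    """
    m = space.m
    if m < 2:
        raise ValueError("eFAST needs at least two parameters")
    omega_max = (Ns - 1) // (2 * M)
    if omega_max < 1 or Ns < 2 * M * omega_max + 1:
        raise ValueError("Ns too small for M harmonics (need Ns >= 2*M + 1)")
    comp_freqs = _complementary_frequencies(omega_max, M)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x46415354]))
    s = 2.0 * np.pi * np.arange(Ns) / Ns
    X = np.empty((m, Nr, Ns, m))
    omegas = np.empty((m, m), np.int64)
    for i in range(m):
        om = np.empty(m, np.int64)
        om[i] = omega_max
        comp = [j for j in range(m) if j != i]
        for rank, j in enumerate(comp):
            om[j] = comp_freqs[rank % len(comp_freqs)]
        omegas[i] = om
        for rep in range(Nr):
            phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
            u = 0.5 + np.arcsin(np.sin(om[None, :] * s[:, None] + phi[None, :])) / np.pi
            X[i, rep] = space.bounds[:, 0] + u * (space.bounds[:, 1] - space.bounds[:, 0])
    return EfastDesign(space, X, omegas, Ns, M, Nr, omega_max)


def efast_indices(design: EfastDesign, outputs) -> EfastResult:
    """Fourier-amplitude variance decomposition of the curve outputs.

    ``outputs`` has shape (m, Nr, Ns), aligned with the design's points.
    """
    outputs = np.asarray(outputs, float)
    m = design.space.m
    if outputs.shape != (m, design.Nr, design.Ns):
        raise ValueError("outputs misaligned with the eFAST design")
    if not np.all(np.isfinite(outputs)):
        raise ValueError("outputs must be finite")
    Ns, M, wmax = design.Ns, design.M, design.omega_max
    n_freq = (Ns - 1) // 2
    S = np.zeros(m)
    ST = np.zeros(m)
    for i in range(m):
        Si_acc, STi_acc, used = 0.0, 0.0, 0
        for rep in range(design.Nr):
            y = outputs[i, rep]
            F = np.fft.rfft(y)
            power = 2.0 * (np.abs(F[1 : n_freq + 1]) / Ns) ** 2  # index k -> omega k+1
            V = power.sum()
            # relative floor: FFT roundoff of a constant signal is not variance
            if V <= (1e-10 * max(1.0, abs(F[0]) / Ns)) ** 2:
                warnings.warn("zero output variance; indices set to 0", RuntimeWarning, stacklevel=2)
                continue
            harmonics = np.arange(1, M + 1) * wmax - 1
            Vi = power[harmonics].sum()
            Vc = power[: wmax // 2].sum()
            Si_acc += Vi / V
            STi_acc += 1.0 - Vc / V
            used += 1
        if used:
            S[i] = Si_acc / used
            ST[i] = STi_acc / used
    return EfastResult(list(design.space.names), S, ST, Ns, M, design.Nr, wmax)


# -- metric construction -----------------------------------------------------


def surrogate_metric(
    field: HyperrectangleField,
    model,
    metric,
    times,
    init,
    n_mc: int = 100,
    seed: int = 0,
) -> MetricFunction:
    """Surrogate-transfer metric: mean of the SM-side metric over the box.

    At each ABM point the hyperrectangle of consistent surrogate parameters
    is queried from ``field`` and the metric of the surrogate trajectory is
    averaged over ``n_mc`` uniform samples of the box.  Sampling is seeded
    deterministically from ``(seed, p_abm)`` so repeated evaluation is
    stable.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    times = np.asarray(times, float)
    init = np.atleast_1d(np.asarray(init, float))

    def fn(p):
        rect = field.query(p)
        rng = np.random.default_rng(_point_seed(seed, p))
        thetas = sample_hyperrectangle(rect, n_mc, rng)
        vals = np.empty(n_mc)
        for j, theta in enumerate(thetas):
            traj = model.predict(theta, times, init)
            vals[j] = metric(Trajectory(times, np.asarray(traj).sum(axis=1)))
        return vals.mean()

    return MetricFunction(fn, "surrogate-transfer")


def abm_metric(
    space: ParameterSpace,
    metric,
    template=None,
    n_replicates: int = 5,
    seed: int = 0,
    **sim_options,
) -> MetricFunction:
    """Direct metric: ABM ensemble-mean trajectory -> scalar.

    Integer-valued ABM parameters (``T_con``) are rounded here before
    simulation.  The per-point replicate base seed derives from
    ``(seed, p_abm)``, so repeated evaluation at a point is identical.
    """
    from .abm import ABMParams, run_ensemble

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    def fn(p):
        params = ABMParams.from_vector(space.names, p, template)
        base = int(_point_seed(seed, p).generate_state(1)[0]) & 0x7FFFFFFF
        ens = run_ensemble(params, n_replicates=n_replicates, base_seed=base, **sim_options)
        return metric(Trajectory(ens.times, ens.total().mean(axis=0)))

    return MetricFunction(fn, "direct-ABM")


def run_gsa(method: str, f, space: ParameterSpace, options=None, seed: int = 0):
    """Run a GSA method over ``space`` with metric ``f``.

    ``f`` may be a plain callable or a :class:`MetricFunction`.  Returns a
    :class:`MoatResult` or :class:`EfastResult` with the evaluation count
    recorded.  Any metric failure aborts with the failing point reported.
    """
    options = dict(options or {})
    if not isinstance(f, MetricFunction):
        f = MetricFunction(f, "callable")
    start_evals = f.n_evaluations

    def evaluate(points):
        vals = np.empty(len(points))
        for i, p in enumerate(points):
            try:
                vals[i] = f(p)
            except Exception as exc:
                raise RuntimeError(f"metric failed at design point {list(p)}: {exc}") from exc
        return vals

    if method == "moat":
        design = morris_design(
            space, r=options.get("r", 30), levels=options.get("levels", 4), seed=seed
        )
        vals = evaluate(design.X)
        res = morris_indices(design, vals, normalized=options.get("normalized", True))
    elif method == "efast":
        design = efast_design(
            space,
            Ns=options.get("Ns", 65),
            M=options.get("M", 4),
            Nr=options.get("Nr", 4),
            seed=seed,
        )
        flat = design.X.reshape(-1, space.m)
        vals = evaluate(flat).reshape(space.m, design.Nr, design.Ns)
        res = efast_indices(design, vals)
    else:
        raise ValueError(f"unknown GSA method {method!r}")
    res.n_evaluations = f.n_evaluations - start_evals
    return res
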