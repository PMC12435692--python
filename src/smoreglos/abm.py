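"""2D on-lattice cell-proliferation agent-based model and ensemble utilities.

The bundled ABM is a birth-death-free migration-proliferation model on a
square lattice with at most one cell per site.  Each cell carries a
cell-cycle phase (G1, S, G2, M) and advances by four Poisson-rate processes:

* phase transitions G1->S, S->G2, G2->M, M->G1 at rates ``rho_*`` (1/day);
* the M->G1 transition is a division: the parent re-enters G1 and a daughter
  G1 cell is placed on a uniformly chosen empty Moore neighbor; the daughter
  is produced with probability ``1 - N/K_A`` (logistic birth thinning, so
  the division yield falls from two cells to one as the population
  approaches the carrying capacity, mirroring the surrogate's crowding
  term) and only when an empty neighbor exists — the parent completes the
  transition regardless, so cycling continues at capacity;
* contact inhibition arrests the cycle in G1, as in confluent cultures: the
  G1->S transition is blocked while more than ``T_con`` Moore neighbors are
  occupied, so crowded cultures accumulate cells in G1/S;
* migration moves a cell to a uniformly chosen empty Moore neighbor at rate
  ``s`` (moves/cell/day).

Dynamics are integrated with a fixed time step (``DT`` = 0.01 day).  Within
a step, cells are updated sequentially in a freshly randomized order; each
cell first attempts a phase transition (probability ``1 - exp(-rho*dt)``)
and then a migration step (probability ``1 - exp(-s*dt)``).  Cells born
during a step act from the following step onward.  The lattice boundary is
closed (edge sites simply have fewer neighbors).

Output is recorded as counts of cells in G1/S (``N_G1S``) and G2/M
(``N_G2M``) at the requested recording times, the same two aggregate series
the two-compartment surrogate describes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.stats import qmc

__all__ = [
    "ABMParams",
    "EnsembleTimeSeries",
    "simulate_abm",
    "run_ensemble",
    "sample_parameter_space",
    "mock_growth_ensemble",
    "DEFAULT_LATTICE_SIZE",
    "DEFAULT_N_INITIAL",
    "DEFAULT_RECORD_TIMES",
    "DEFAULT_T_END",
    "default_parameter_space",
]

# -- study-condition defaults ------------------------------------------------
# Lattice and seeding for the desk-scale in vitro proliferation assay: a
# 50x50 dish seeded with 400 cells (16% density) at random distinct sites,
# simulated through day 3 with recordings every half day.  Phase-transition
# rates span phase durations of 4-8 h (total cycle 16-32 h, typical of
# proliferative lines), so cultures approach their density-limited plateau
# within the 3-day window across the whole parameter box and the final
# count reflects the confluence ceiling rather than the growth rate (see
# docs/methods.md).
DEFAULT_LATTICE_SIZE = 50
DEFAULT_N_INITIAL = 400
DEFAULT_T_END = 3.0
DEFAULT_RECORD_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
DT = 0.01  # integration step, days

#: default biological ranges for the 7-parameter sensitivity box
DEFAULT_BOUNDS = {
    "K_A": (500.0, 2400.0),
    "T_con": (1.0, 7.0),
    "s": (0.0, 50.0),
    "rho_G1_S": (3.0, 6.0),
    "rho_S_G2": (3.0, 6.0),
    "rho_G2_M": (3.0, 6.0),
    "rho_M_G1": (3.0, 6.0),
}


class CapacityError(ValueError):
    """Requested cell numbers exceed what the lattice can hold."""


@dataclass(frozen=True)
class ABMParams:
    """Input parameters of the 2D lattice ABM.

    Attributes
    ----------
    K_A : float
        Carrying capacity (cells); global ceiling on the population.
    T_con : int
        Contact-inhibition threshold: G1->S is blocked while more than
        ``T_con`` Moore neighbors are occupied (0-8).
    s : float
        Migration rate (moves/cell/day).
    rho_G1_S, rho_S_G2, rho_G2_M, rho_M_G1 : float
        Cell-cycle phase-transition rates (1/day); M->G1 is division.
    """

    K_A: float = 1450.0
    T_con: int = 4
    s: float = 25.0
    rho_G1_S: float = 4.5
    rho_S_G2: float = 4.5
    rho_G2_M: float = 4.5
    rho_M_G1: float = 4.5

    def __post_init__(self):
        rates = (self.rho_G1_S, self.rho_S_G2, self.rho_G2_M, self.rho_M_G1)
        if any(r < 0 for r in rates) or self.s < 0:
            raise ValueError("phase-transition and migration rates must be >= 0")
        if self.K_A <= 0:
            raise ValueError("K_A must be positive")
        if not float(self.T_con).is_integer() or not 0 <= self.T_con <= 8:
            raise ValueError("T_con must be an integer in [0, 8]")

    @property
    def rates(self) -> np.ndarray:
        return np.array(
            [self.rho_G1_S, self.rho_S_G2, self.rho_G2_M, self.rho_M_G1], float
        )

    @classmethod
    def from_vector(cls, names, values, template: "ABMParams | None" = None):
        """Build parameters from a named vector, rounding ``T_con``."""
        base = template or cls()
        updates = {}
        for name, v in zip(names, values):
            updates[name] = int(round(v)) if name == "T_con" else float(v)
        return replace(base, **updates)


@dataclass
class EnsembleTimeSeries:
    """Replicate-resolved time series of named count variables.

    ``counts`` has shape (n_replicates, n_times, n_variables) and is
    nonnegative; times are strictly increasing.
    """

    times: np.ndarray
    variables: tuple
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.counts = np.asarray(self.counts, float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (replicates, times, variables)")
        R, T, V = self.counts.shape
        if T != self.times.size or V != len(self.variables):
            raise ValueError("counts dimensions inconsistent with times/variables")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    def mean(self) -> np.ndarray:
        """Ensemble mean, shape (n_times, n_variables)."""
        return self.counts.mean(axis=0)

    def std(self) -> np.ndarray:
        """Ensemble standard deviation (ddof=1; zero for one replicate)."""
        if self.n_replicates < 2:
            return np.zeros(self.counts.shape[1:])
        return self.counts.std(axis=0, ddof=1)

    def total(self) -> np.ndarray:
        """Per-replicate total count, shape (n_replicates, n_times)."""
        return self.counts.sum(axis=2)

    @classmethod
    def stack(cls, members: "list[EnsembleTimeSeries]") -> "EnsembleTimeSeries":
        first = members[0]
        for m in members[1:]:
            if not np.array_equal(m.times, first.times) or m.variables != first.variables:
                raise ValueError("cannot stack ensembles with differing grids")
        counts = np.concatenate([m.counts for m in members], axis=0)
        return cls(first.times, first.variables, counts, dict(first.meta))


# -- numba kernel ------------------------------------------------------------

_G1, _S, _G2, _M = 0, 1, 2, 3


@njit(cache=True)
def _simulate_kernel(L, n_initial, rates, s, T_con, K_A, dt, rec_steps, seed):
    np.random.seed(seed)
    cap = L * L
    occ = np.zeros((L, L), np.uint8)
    px = np.empty(cap, np.int64)
    py = np.empty(cap, np.int64)
    ph = np.empty(cap, np.int8)

    # initial seeding: distinct uniform sites, uniform phases
    n = 0
    while n < n_initial:
        x = np.random.randint(0, L)
        y = np.random.randint(0, L)
        if occ[x, y] == 0:
            occ[x, y] = 1
            px[n] = x
            py[n] = y
            ph[n] = np.random.randint(0, 4)
            n += 1

    p_trans = 1.0 - np.exp(-rates * dt)
    p_mig = 1.0 - np.exp(-s * dt)

    n_rec = rec_steps.shape[0]
    out = np.zeros((n_rec, 2), np.int64)
    rec_i = 0
    # record t = 0 if requested
    while rec_i < n_rec and rec_steps[rec_i] == 0:
        for c in range(n):
            out[rec_i, 0 if ph[c] <= _S else 1] += 1
        rec_i += 1
    if rec_i >= n_rec:
        return out

    last_step = rec_steps[n_rec - 1]
    nx = np.empty(8, np.int64)
    ny = np.empty(8, np.int64)
    for step in range(1, last_step + 1):
        order = np.random.permutation(n)
        for k in range(order.shape[0]):
            c = order[k]
            x = px[c]
            y = py[c]
            p = ph[c]
            if np.random.random() < p_trans[p]:
                if p == _G1:
                    # contact inhibition: G1 arrest while locally crowded
                    occupied = 0
                    for dx in range(-1, 2):
                        for dy in range(-1, 2):
                            if dx == 0 and dy == 0:
                                continue
                            xx = x + dx
                            yy = y + dy
                            if 0 <= xx < L and 0 <= yy < L and occ[xx, yy] == 1:
                                occupied += 1
                    if occupied <= T_con:
                        ph[c] = _S
                elif p == _S:
                    ph[c] = _G2
                elif p == _G2:
                    ph[c] = _M
                else:
                    # M -> G1 always completes; the daughter is produced
                    # with probability 1 - N/K_A (logistic birth thinning)
                    # and placed only when an empty neighbor exists
                    ph[c] = _G1
                    if np.random.random() * K_A >= n:
                        m = 0
                        for dx in range(-1, 2):
                            for dy in range(-1, 2):
                                if dx == 0 and dy == 0:
                                    continue
                                xx = x + dx
                                yy = y + dy
                                if 0 <= xx < L and 0 <= yy < L and occ[xx, yy] == 0:
                                    nx[m] = xx
                                    ny[m] = yy
                                    m += 1
                        if m > 0:
                            j = np.random.randint(0, m)
                            occ[nx[j], ny[j]] = 1
                            px[n] = nx[j]
                            py[n] = ny[j]
                            ph[n] = _G1
                            n += 1
            if p_mig > 0.0 and np.random.random() < p_mig:
                m = 0
                for dx in range(-1, 2):
                    for dy in range(-1, 2):
                        if dx == 0 and dy == 0:
                            continue
                        xx = x + dx
                        yy = y + dy
                        if 0 <= xx < L and 0 <= yy < L and occ[xx, yy] == 0:
                            nx[m] = xx
                            ny[m] = yy
                            m += 1
                if m > 0:
                    j = np.random.randint(0, m)
                    occ[x, y] = 0
                    occ[nx[j], ny[j]] = 1
                    px[c] = nx[j]
                    py[c] = ny[j]
        while rec_i < n_rec and rec_steps[rec_i] == step:
            for c in range(n):
                out[rec_i, 0 if ph[c] <= _S else 1] += 1
            rec_i += 1
        if rec_i >= n_rec:
            break
    return out


def simulate_abm(
    params: ABMParams,
    lattice_size: int = DEFAULT_LATTICE_SIZE,
    n_initial: int = DEFAULT_N_INITIAL,
    t_end: float = DEFAULT_T_END,
    record_times=DEFAULT_RECORD_TIMES,
    seed: int = 0,
) -> EnsembleTimeSeries:
    """Run one stochastic realization of the lattice ABM.

    Returns a single-replicate :class:`EnsembleTimeSeries` with variables
    ``N_G1S`` and ``N_G2M``.  Identical ``(params, seed)`` and options give
    an identical trajectory.
    """
    capacity = lattice_size * lattice_size
    if n_initial > capacity:
        raise CapacityError(
            f"n_initial={n_initial} exceeds lattice capacity {capacity}"
        )
    if n_initial > params.K_A:
        raise CapacityError("n_initial exceeds carrying capacity K_A")
    if params.K_A > capacity:
        raise CapacityError("K_A exceeds lattice capacity")
    record_times = np.asarray(sorted(record_times), float)
    if record_times.size == 0:
        raise ValueError("record_times must be nonempty")
    if record_times[0] < 0 or record_times[-1] > t_end + 1e-9:
        raise ValueError("record_times must lie in [0, t_end]")
    rec_steps = np.round(record_times / DT).astype(np.int64)
    counts = _simulate_kernel(
        lattice_size,
        int(n_initial),
        params.rates,
        float(params.s),
        int(params.T_con),
        float(params.K_A),
        DT,
        rec_steps,
        int(seed) & 0x7FFFFFFF,
    )
    meta = {
        "lattice_size": lattice_size,
        "n_initial": n_initial,
        "seed": int(seed),
        "params": params.__dict__.copy(),
    }
    return EnsembleTimeSeries(record_times, ("N_G1S", "N_G2M"), counts[None, :, :], meta)


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Stable per-replicate seeds derived from ``base_seed``.

    Uses a splittable :class:`numpy.random.SeedSequence` keyed by
    ``(base_seed, index)``; the mapping is documented and stable across runs.
    """
    return [
        int(np.random.SeedSequence([int(base_seed), i]).generate_state(1)[0])
        & 0x7FFFFFFF
        for i in range(n)
    ]


def run_ensemble(
    params: ABMParams,
    n_replicates: int = 6,
    base_seed: int = 0,
    **sim_options,
) -> EnsembleTimeSeries:
    """Run ``n_replicates`` independent ABM realizations and stack them."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = replicate_seeds(base_seed, n_replicates)
    members = [simulate_abm(params, seed=sd, **sim_options) for sd in seeds]
    ens = EnsembleTimeSeries.stack(members)
    ens.meta = dict(members[0].meta)
    ens.meta["seed"] = int(base_seed)
    ens.meta["n_replicates"] = n_replicates
    return ens


def sample_parameter_space(space, design: str = "grid", levels=2, n_points: int | None = None, seed: int = 0) -> np.ndarray:
    """Sample ABM parameter vectors over the box Omega.

    ``design="grid"`` returns the full factorial of per-dimension linspaces
    (``levels`` scalar or per-dimension); ``design="lhs"`` returns
    ``n_points`` Latin-hypercube interior points with all ``2^m`` corner
    points of Omega appended, so the boundary is always represented.
    """
    bounds = np.asarray(space.bounds, float)
    if not np.all(np.isfinite(bounds)):
        raise ValueError("parameter bounds must be finite")
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("parameter bounds must satisfy lower < upper")
    m = bounds.shape[0]
    if design == "grid":
        levels_arr = np.full(m, levels, int) if np.isscalar(levels) else np.asarray(levels, int)
        if np.any(levels_arr < 2):
            raise ValueError("grid design needs >= 2 levels per dimension")
        axes = [np.linspace(lo, hi, lv) for (lo, hi), lv in zip(bounds, levels_arr)]
        pts = np.array(list(itertools.product(*axes)))
        return pts
    if design == "lhs":
        if n_points is None or n_points < 1:
            raise ValueError("LHS design requires n_points >= 1")
        sampler = qmc.LatinHypercube(d=m, seed=seed)
        unit = sampler.random(n_points)
        interior = bounds[:, 0] + unit * (bounds[:, 1] - bounds[:, 0])
        corners = np.array(list(itertools.product(*bounds)))
        return np.vstack([interior, corners])
    raise ValueError(f"unknown design {design!r}")


def mock_growth_ensemble(
    truth_model: str,
    truth_params: dict,
    noise_sd: float,
    times,
    n_replicates: int,
    seed: int = 0,
    N0: float = 100.0,
) -> EnsembleTimeSeries:
    """Synthetic growth ensembles from a known ODE truth.

    Stand-in generator for an expensive external growth ABM: each replicate
    is the deterministic growth-law solution multiplied by i.i.d. lognormal
    noise with log-scale ``noise_sd`` (median-1 factors), clipped at zero.
    Used to exercise surrogate selection among the growth laws.
    """
    from .surrogate import GrowthSMParams, solve_growth

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    gp = GrowthSMParams(model=truth_model, **truth_params)
    times = np.asarray(times, float)
    traj = solve_growth(gp, N0, times).values[:, 0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6D6F636B]))
    if noise_sd == 0:
        counts = np.tile(traj, (n_replicates, 1))
    else:
        factors = rng.lognormal(mean=0.0, sigma=noise_sd, size=(n_replicates, times.size))
        counts = np.clip(traj[None, :] * factors, 0.0, None)
    meta = {"truth_model": truth_model, "truth_params": dict(truth_params), "seed": int(seed), "N0": N0}
    return EnsembleTimeSeries(times, ("N",), counts[:, :, None], meta)


def default_parameter_space():
    """The documented 7-parameter biological box for the bundled ABM."""
    from .gsa import ParameterSpace

    names = list(DEFAULT_BOUNDS)
    return ParameterSpace(names=names, bounds=[DEFAULT_BOUNDS[n] for n in names])
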