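"""Confidence hypersurfaces over ABM parameter space and hyperrectangle queries.

Each surrogate parameter is viewed as an unknown function of the ABM
parameters.  The per-point 95% profile bounds computed during calibration
are discrete samples of its lower and upper confidence hypersurfaces; this
module interpolates those samples into continuous scalar fields over the
sampled region and answers point queries with the Cartesian product of the
per-parameter intervals — a hyperrectangle in surrogate parameter space
describing the surrogate parameters consistent with the ABM at that point.

Interpolation is multilinear on a rectangular grid when the sampled points
form one, and barycentric on a Delaunay triangulation otherwise.  Queries
outside the convex hull of the samples raise :class:`DomainError`; there is
no extrapolation.  Unbounded confidence intervals must be clipped to the
biologically relevant range (:func:`clip_bounds`) before field construction;
clipping is recorded because it degrades the field's fidelity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator

__all__ = [
    "DomainError",
    "SampledBounds",
    "Hyperrectangle",
    "HyperrectangleField",
    "clip_bounds",
    "build_field",
    "sample_hyperrectangle",
]


class DomainError(ValueError):
    """Query point lies outside the sampled region (no extrapolation)."""


def clip_bounds(ci, relevant_range):
    """Replace infinite or out-of-range CI endpoints by the range endpoints.

    Returns ``(lower, upper, clipped)`` with finite bounds; ``clipped`` is
    True when either endpoint had to be replaced.
    """
    lo_r, hi_r = relevant_range
    if not (math.isfinite(lo_r) and math.isfinite(hi_r)):
        raise ValueError("relevant_range must be finite")
    lower, upper = ci.lower, ci.upper
    clipped = False
    if not math.isfinite(lower) or lower < lo_r or lower > hi_r:
        lower, clipped = lo_r, True
    if not math.isfinite(upper) or upper > hi_r or upper < lo_r:
        upper, clipped = hi_r, True
    if lower > upper:
        lower, upper = upper, lower
    return float(lower), float(upper), clipped


@dataclass
class SampledBounds:
    """Finite lower/upper SM-parameter bounds at sampled ABM points."""

    abm_names: tuple
    abm_points: np.ndarray   # (n_points, m)
    sm_names: tuple
    lower: np.ndarray        # (n_points, P)
    upper: np.ndarray        # (n_points, P)

    def __post_init__(self):
        self.abm_points = np.asarray(self.abm_points, float)
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        n, m = self.abm_points.shape
        if self.lower.shape != (n, len(self.sm_names)) or self.upper.shape != self.lower.shape:
            raise ValueError("bounds arrays inconsistent with points/names")
        if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
            raise ValueError("bounds must be finite; clip them first")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds must not exceed upper bounds")

    def to_json_dict(self) -> dict:
        return {
            "schema": "smoreglos.hypersurface/1",
            "abm_names": list(self.abm_names),
            "abm_points": self.abm_points.tolist(),
            "sm_names": list(self.sm_names),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SampledBounds":
        return cls(
            tuple(d["abm_names"]), np.array(d["abm_points"], float),
            tuple(d["sm_names"]), np.array(d["lower"], float),
            np.array(d["upper"], float),
        )


@dataclass(frozen=True)
class Hyperrectangle:
    """Per-SM-parameter interval [lo, hi]; the box Omega_SM(p_ABM)."""

    names: tuple
    intervals: np.ndarray  # (P, 2)

    def __post_init__(self):
        object.__setattr__(self, "intervals", np.asarray(self.intervals, float))
        if not np.all(np.isfinite(self.intervals)):
            raise ValueError("hyperrectangle bounds must be finite")
        if np.any(self.intervals[:, 0] > self.intervals[:, 1]):
            raise ValueError("lo must not exceed hi")

    def __getitem__(self, name):
        return tuple(self.intervals[self.names.index(name)])


def _detect_grid(points):
    """Return per-varied-dimension axes if the points form a full factorial."""
    n, m = points.shape
    axes = [np.unique(points[:, j]) for j in range(m)]
    sizes = [a.size for a in axes]
    if int(np.prod(sizes)) != n:
        return None
    # verify every combination appears exactly once
    idx = np.zeros(n, np.int64)
    for j in range(m):
        pos = np.searchsorted(axes[j], points[:, j])
        idx = idx * sizes[j] + pos
    if np.unique(idx).size != n:
        return None
    return axes, idx


class HyperrectangleField:
    """Interpolated lower/upper bound fields over ABM parameter space."""

    def __init__(self, samples: SampledBounds, scheme: str = "auto"):
        self.samples = samples
        pts = samples.abm_points
        self._varied = [j for j in range(pts.shape[1]) if np.unique(pts[:, j]).size > 1]
        self._fixed_vals = pts[0].copy()
        sub = pts[:, self._varied]
        if sub.shape[1] == 0:
            raise DomainError("degenerate sample set: no varied ABM dimension")
        grid = _detect_grid(sub)
        if scheme == "auto":
            scheme = "multilinear-grid" if grid is not None else "simplex"
        if scheme == "multilinear-grid":
            if grid is None:
                raise ValueError("samples are not grid-structured; use scheme='simplex'")
            axes, idx = grid
            sizes = [a.size for a in axes]
            order = np.argsort(idx)
            self._interp = []
            for p in range(len(samples.sm_names)):
                lo = samples.lower[order, p].reshape(sizes)
                hi = samples.upper[order, p].reshape(sizes)
                self._interp.append(
                    (
                        RegularGridInterpolator(axes, lo, method="linear", bounds_error=True),
                        RegularGridInterpolator(axes, hi, method="linear", bounds_error=True),
                    )
                )
        elif scheme == "simplex":
            if sub.shape[1] == 1:
                raise ValueError("1D samples: use the multilinear-grid scheme")
            try:
                self._interp = [
                    (
                        LinearNDInterpolator(sub, samples.lower[:, p]),
                        LinearNDInterpolator(sub, samples.upper[:, p]),
                    )
                    for p in range(len(samples.sm_names))
                ]
            except Exception as exc:  # degenerate hull
                raise DomainError(f"cannot triangulate samples: {exc}") from exc
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        self.scheme = scheme

    @property
    def sm_names(self) -> tuple:
        return self.samples.sm_names

    def query(self, p_abm) -> Hyperrectangle:
        """Evaluate the bound fields at ``p_abm`` -> hyperrectangle.

        Raises :class:`DomainError` outside the convex hull of the samples
        (including any mismatch on non-varied ABM coordinates).
        """
        p = np.asarray(p_abm, float)
        if p.shape != (self.samples.abm_points.shape[1],):
            raise ValueError("query point has wrong dimension")
        for j, v in enumerate(p):
            if j not in self._varied and not np.isclose(v, self._fixed_vals[j], rtol=1e-9, atol=1e-12):
                raise DomainError(f"coordinate {self.samples.abm_names[j]} was not varied")
        sub = p[self._varied]
        intervals = np.empty((len(self.sm_names), 2))
        for i, (f_lo, f_hi) in enumerate(self._interp):
            try:
                lo = float(np.asarray(f_lo(sub)).ravel()[0])
                hi = float(np.asarray(f_hi(sub)).ravel()[0])
            except ValueError as exc:
                raise DomainError(f"query outside sampled region: {exc}") from exc
            if math.isnan(lo) or math.isnan(hi):
                raise DomainError("query outside the convex hull of the samples")
            if lo > hi:
                warnings.warn(
                    f"interpolated bounds crossed for {self.sm_names[i]}; swapping",
                    RuntimeWarning,
                    stacklevel=2,
                )
                lo, hi = hi, lo
            intervals[i] = (lo, hi)
        return Hyperrectangle(self.sm_names, intervals)

    # -- serialization ------------------------------------------------------

    def to_json(self, path):
        d = self.samples.to_json_dict()
        d["scheme"] = self.scheme
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "HyperrectangleField":
        with open(path) as fh:
            d = json.load(fh)
        return cls(SampledBounds.from_json_dict(d), scheme=d["scheme"])


def build_field(samples: SampledBounds, scheme: str = "auto") -> HyperrectangleField:
    """Build the interpolated bound fields (exact at every sample node)."""
    return HyperrectangleField(samples, scheme=scheme)


def sample_hyperrectangle(rect: Hyperrectangle, n: int, seed=0) -> np.ndarray:
    """Draw ``n`` i.i.d. uniform SM parameter vectors from the box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = rect.intervals[:, 0]
    hi = rect.intervals[:, 1]
    return lo + rng.random((n, lo.size)) * (hi - lo)
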