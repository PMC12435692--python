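"""Profile likelihoods, 95% confidence bounds, and the identifiability index.

For each surrogate parameter the profile fixes that parameter on a grid and
re-optimizes all remaining parameters, giving the profiled weighted RSS as a
function of the parameter.  With Gaussian errors the likelihood-ratio rule
places the 95% confidence bounds where the profile crosses

    best_rss + best_rss * chi2_{0.95}(1) / n_obs        ("lr_scaled", default)

under the 1/n_obs-normalized objective; the ``best_rss`` factor plays the
role of the estimated error variance.  When the weights are exact known
standard deviations the alternative rule "chi2" uses the fixed offset
chi2_{0.95}(1)/n_obs instead (exact 95% coverage for linear models).

An **identifiability index** summarizes each interval: 2 when both bounds
are finite and inside the biologically relevant range (U-shaped profile),
1 when only one is (L-shaped), 0 when neither is informative (flat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .surrogate import FitProblem, FitResult

__all__ = [
    "ProfileCurve",
    "ConfidenceInterval",
    "profile_parameter",
    "confidence_bounds",
    "identifiability_index",
    "CHI2_95_1",
    "DEFAULT_RELEVANT_RANGES",
]

CHI2_95_1 = float(chi2.ppf(0.95, 1))  # 3.8414588...

#: biologically relevant ranges used by the identifiability index
DEFAULT_RELEVANT_RANGES = {
    "rate": (0.0, 100.0),       # 1/day
    "capacity": (1.0, 1e6),     # cells (a capacity below one cell is meaningless)
}


class InvalidProfileError(RuntimeError):
    """Too many failed re-optimizations to trust the profile."""


@dataclass
class ProfileCurve:
    """Profiled RSS of one parameter over a (log-spaced) grid.

    ``evaluator``, when present, re-evaluates the profiled RSS at an
    arbitrary parameter value (re-optimizing the nuisance parameters from a
    warm start near grid index ``i``); it lets the confidence-bound search
    refine a threshold crossing below the grid resolution.
    """

    param_name: str
    grid: np.ndarray
    rss_profile: np.ndarray
    best_value: float
    best_rss: float
    n_obs: int
    failed: np.ndarray | None = None
    evaluator: object = None


@dataclass(frozen=True)
class ConfidenceInterval:
    """Profile-likelihood interval; infinite sentinels mark missing crossings."""

    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self):
        if math.isfinite(self.lower) and math.isfinite(self.upper) and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def profile_parameter(
    model,
    data,
    fit: FitResult,
    param_name: str,
    search_range=None,
    n_grid: int = 41,
    sigma=None,
    max_fail_frac: float = 0.2,
) -> ProfileCurve:
    """Compute the profile likelihood of one surrogate parameter.

    The parameter is fixed at each of ``n_grid`` log-spaced values spanning
    ``search_range`` (default: best/100 .. best*100, clipped to the model's
    fit bounds) and the remaining parameters are re-optimized, marching
    outward from the best fit with warm starts from the neighboring grid
    point.  Failed re-optimizations are flagged and linearly interpolated
    over; more than ``max_fail_frac`` failures invalidates the profile.
    """
    idx = list(model.param_names).index(param_name)
    problem = FitProblem(model, data, sigma=sigma)
    best = float(fit.params[idx])
    lo_b, hi_b = model.bounds[idx]
    if search_range is None:
        search_range = (max(best / 100.0, lo_b), min(best * 100.0, hi_b))
    lo, hi = search_range
    if not lo <= best <= hi:
        raise ValueError("search_range must contain the best-fit value")
    if lo > 0:
        grid = np.geomspace(lo, hi, n_grid)
    else:
        grid = np.linspace(lo, hi, n_grid)
    # the best-fit value itself is always on the grid, so the profile
    # always contains a point at (or below) the threshold
    grid = np.unique(np.concatenate([grid, [best]]))
    n_grid = grid.size
    rss = np.full(n_grid, np.nan)
    failed = np.zeros(n_grid, bool)
    warms = np.tile(problem.encode(fit.params), (n_grid, 1))
    x_best = problem.encode(fit.params)
    i0 = int(np.argmin(np.abs(grid - best)))
    for direction in (range(i0, n_grid), range(i0 - 1, -1, -1)):
        warm = x_best.copy()
        for i in direction:
            fv = problem.encode(np.full(model.k, grid[i]))[idx]
            try:
                x, val, ok = _reopt(problem, warm, idx, fv)
            except Exception:
                failed[i] = True
                continue
            if not np.isfinite(val):
                failed[i] = True
                continue
            rss[i] = val
            warm = x
            warms[i] = x
    if failed.mean() > max_fail_frac:
        raise InvalidProfileError(
            f"{failed.sum()}/{n_grid} profile points failed for {param_name}"
        )
    if failed.any():
        good = ~failed
        rss[failed] = np.interp(grid[failed], grid[good], rss[good])
    best_rss = min(float(fit.rss), float(np.nanmin(rss)))

    def evaluator(value: float, near: int) -> float:
        fv = problem.encode(np.full(model.k, value))[idx]
        _, val, _ = _reopt(problem, warms[near].copy(), idx, fv)
        return val

    return ProfileCurve(
        param_name, grid, rss, best, best_rss, problem.n_obs, failed, evaluator
    )


def _reopt(problem, warm, idx, fixed_val):
    from .surrogate import _minimize

    if problem.model.k == 1:
        # single-parameter model: the profile is the raw 1D RSS curve
        val = problem.rss_enc(np.array([fixed_val]))
        return np.array([fixed_val]), val, True
    return _minimize(problem, warm, fixed_idx=idx, fixed_val=fixed_val)


def confidence_bounds(
    profile: ProfileCurve, n_obs: int | None = None, threshold_rule: str = "lr_scaled"
) -> ConfidenceInterval:
    """95% bounds from the outermost threshold crossings of a profile.

    Crossings are located by linear interpolation between grid points; a
    side with no crossing inside the search range gets an infinite
    sentinel.  A profile whose total relief is below a tenth of the
    threshold offset is classified flat (both bounds infinite).
    """
    n = n_obs if n_obs is not None else profile.n_obs
    if threshold_rule == "lr_scaled":
        delta = profile.best_rss * CHI2_95_1 / n
    elif threshold_rule == "chi2":
        delta = CHI2_95_1 / n
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    rss = profile.rss_profile
    grid = profile.grid
    thr = profile.best_rss + delta
    if np.nanmin(rss) > thr:
        raise InvalidProfileError("profile lies entirely above the threshold")
    if np.nanmax(rss) - np.nanmin(rss) < delta / 10.0:
        return ConfidenceInterval(-np.inf, np.inf)
    below = rss <= thr
    idx = np.flatnonzero(below)
    i_lo, i_hi = idx[0], idx[-1]
    if i_lo == 0:
        lower = -np.inf
    else:
        lower = _crossing(profile, i_lo - 1, i_lo, thr)
    if i_hi == len(grid) - 1:
        upper = np.inf
    else:
        upper = _crossing(profile, i_hi + 1, i_hi, thr)
    return ConfidenceInterval(lower, upper)


def _crossing(profile: ProfileCurve, i_out: int, i_in: int, thr: float) -> float:
    """Locate the threshold crossing between two grid points.

    The bracket (outside point above the threshold, inside point at or
    below it) is first narrowed by bisection with re-optimized profile
    evaluations when the profile carries an evaluator — the grid is much
    coarser than a sharp parameter's confidence interval — and the final
    sub-bracket is resolved by linear interpolation.
    """
    x_out, x_in = profile.grid[i_out], profile.grid[i_in]
    y_out, y_in = profile.rss_profile[i_out], profile.rss_profile[i_in]
    if profile.evaluator is not None:
        log_space = x_out > 0 and x_in > 0
        for _ in range(12):
            mid = math.sqrt(x_out * x_in) if log_space else 0.5 * (x_out + x_in)
            try:
                y_mid = profile.evaluator(mid, i_in)
            except Exception:
                break
            if not math.isfinite(y_mid):
                break
            if y_mid > thr:
                x_out, y_out = mid, y_mid
            else:
                x_in, y_in = mid, y_mid
    if y_out == y_in:
        return x_in
    frac = (thr - y_in) / (y_out - y_in)
    return x_in + frac * (x_out - x_in)


def identifiability_index(ci: ConfidenceInterval, relevant_range) -> int:
    """Count the 95% bounds that are finite and within the relevant range."""
    lo, hi = relevant_range
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError("relevant_range must be finite")
    n = 0
    for b in (ci.lower, ci.upper):
        if math.isfinite(b) and lo <= b <= hi:
            n += 1
    return n
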