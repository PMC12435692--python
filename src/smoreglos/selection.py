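"""Surrogate-model selection: AIC comparison and identifiability aggregation.

Candidate surrogates fitted at every sampled ABM parameter vector are
compared with the Gaussian-error Akaike Information Criterion

    AIC = n_obs * ln(RSS / n_obs) + 2 k,

where RSS is the un-normalized weighted residual sum of squares.  Relative
log-likelihood of a reference model against an alternative at one point is
(AIC_alt - AIC_ref) / 2 (positive when the reference is more likely).  The
documented selection heuristic balances fit quality against parameter
uncertainty: candidates are first filtered to those whose parameters all
have an identifiability-index-2 frequency of at least 80%, and the filtered
candidate with the highest AIC win fraction is chosen (falling back, with a
warning, to the overall win-fraction leader if the filter empties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "aic",
    "aicc",
    "ModelComparison",
    "compare_models",
    "aggregate_identifiability",
    "select_surrogate",
]


def aic(rss_unnormalized: float, n_obs: int, k: int) -> float:
    """Gaussian-error AIC from an un-normalized weighted RSS."""
    if n_obs <= k:
        raise ValueError("need n_obs > k")
    if rss_unnormalized < 0:
        raise ValueError("rss must be nonnegative")
    if rss_unnormalized == 0:
        warnings.warn("zero RSS: AIC is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    return n_obs * np.log(rss_unnormalized / n_obs) + 2 * k


def aicc(rss_unnormalized: float, n_obs: int, k: int) -> float:
    """Small-sample corrected AIC (optional alternative)."""
    base = aic(rss_unnormalized, n_obs, k)
    if n_obs - k - 1 <= 0:
        raise ValueError("AICc requires n_obs > k + 1")
    return base + 2 * k * (k + 1) / (n_obs - k - 1)


@dataclass
class ModelComparison:
    """Per-point AICs, winners, and aggregate win fractions."""

    candidates: tuple
    reference: str
    aics: dict            # name -> array of per-point AIC
    rel_loglik: dict      # name -> (AIC_name - AIC_ref)/2 per point
    winners: list         # per-point winning model name
    win_fractions: dict   # name -> fraction of points won

    @property
    def n_points(self) -> int:
        return len(self.winners)


def compare_models(fits: dict, reference: str, use_aicc: bool = False) -> ModelComparison:
    """Compare >= 2 candidate surrogates fitted at the same ABM points.

    ``fits`` maps model name to a list of :class:`FitResult`, one per
    sampled ABM parameter vector (same order for every candidate).  Ties in
    AIC are won by the candidate with fewest parameters (then by name).
    """
    names = tuple(fits)
    if len(names) < 2:
        raise ValueError("need at least two candidate models")
    if reference not in fits:
        raise ValueError(f"reference {reference!r} not among candidates")
    n_pts = len(fits[names[0]])
    for nm in names:
        missing = [i for i, f in enumerate(fits[nm]) if f is None]
        if len(fits[nm]) != n_pts or missing:
            raise ValueError(f"candidate {nm!r} missing fits at points {missing}")
    crit = aicc if use_aicc else aic
    aics = {
        nm: np.array([crit(f.rss_unnormalized, f.n_obs, f.k) for f in fits[nm]])
        for nm in names
    }
    ks = {nm: fits[nm][0].k for nm in names}
    rel = {nm: (aics[nm] - aics[reference]) / 2.0 for nm in names}
    winners = []
    for i in range(n_pts):
        best = min(names, key=lambda nm: (aics[nm][i], ks[nm], nm))
        winners.append(best)
    fractions = {nm: winners.count(nm) / n_pts for nm in names}
    return ModelComparison(names, reference, aics, rel, winners, fractions)


def aggregate_identifiability(indices: dict) -> dict:
    """Per-parameter frequencies of identifiability indices 0/1/2.

    ``indices`` maps parameter name to a sequence of per-point indices.
    Returns ``{param: {0: f0, 1: f1, 2: f2}}`` with fractions summing to 1.
    """
    out = {}
    for pname, vals in indices.items():
        vals = list(vals)
        if not vals:
            raise ValueError(f"no indices recorded for parameter {pname!r}")
        n = len(vals)
        out[pname] = {j: vals.count(j) / n for j in (0, 1, 2)}
    return out


def select_surrogate(
    comparison: ModelComparison,
    identifiability: dict,
    min_index2_frac: float = 0.8,
) -> str:
    """Pick the surrogate balancing AIC wins and identifiability.

    ``identifiability`` maps model name to the per-parameter frequency
    table from :func:`aggregate_identifiability`.
    """
    eligible = [
        nm
        for nm in comparison.candidates
        if all(freq[2] >= min_index2_frac for freq in identifiability[nm].values())
    ]
    if not eligible:
        warnings.warn(
            "no candidate meets the identifiability filter; "
            "falling back to the AIC win-fraction leader",
            RuntimeWarning,
            stacklevel=2,
        )
        eligible = list(comparison.candidates)
    return max(eligible, key=lambda nm: (comparison.win_fractions[nm], nm))
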