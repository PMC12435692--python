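"""Scalar output metrics on trajectories, the targets of sensitivity analysis.

A trajectory is a pair of arrays (times, values); helpers accept either a
``Trajectory`` tuple, an object exposing ``times``/``values`` (surrogate
solutions), or two positional arrays.  All three metrics ignore duplicated
interior time points.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["Trajectory", "final_value", "auc", "time_to_half_max", "get_metric"]


class Trajectory(NamedTuple):
    times: np.ndarray
    values: np.ndarray


class UndefinedMetricError(ValueError):
    """The metric is not defined for this trajectory (e.g. all zeros)."""


def _coerce(traj, values=None) -> Trajectory:
    if values is not None:
        t, v = traj, values
    elif hasattr(traj, "times"):
        t = traj.times
        v = traj.values
        v = np.asarray(v)
        if v.ndim > 1:
            v = v.sum(axis=1)  # total count over variables
    else:
        t, v = traj
    t = np.asarray(t, float)
    v = np.asarray(v, float).ravel()
    if t.size != v.size or t.size == 0:
        raise ValueError("trajectory times and values must align and be nonempty")
    keep = np.concatenate([[True], np.diff(t) > 0])
    return Trajectory(t[keep], v[keep])


def final_value(traj, values=None) -> float:
    """Value at the last recorded time (e.g. final cell count)."""
    t, v = _coerce(traj, values)
    return float(v[-1])


def auc(traj, values=None) -> float:
    """Trapezoidal area under the trajectory (count * days)."""
    t, v = _coerce(traj, values)
    if t.size < 2:
        raise ValueError("auc needs at least two distinct time points")
    return float(np.trapezoid(v, t))


def time_to_half_max(traj, values=None) -> float:
    """First time the trajectory reaches half of its own maximum.

    Linear interpolation between the bracketing points; if the trajectory
    already starts at or above half-maximum, returns the first time.
    """
    t, v = _coerce(traj, values)
    if t.size < 2:
        raise ValueError("time_to_half_max needs at least two time points")
    vmax = v.max()
    if vmax <= 0:
        raise UndefinedMetricError("all-zero trajectory has no half-maximum")
    half = vmax / 2.0
    if v[0] >= half:
        return float(t[0])
    above = np.flatnonzero(v >= half)
    i = above[0]
    t0, t1 = t[i - 1], t[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (half - v0) / (v1 - v0) * (t1 - t0))


_METRICS = {"final": final_value, "auc": auc, "t_half": time_to_half_max}


def get_metric(name: str):
    """Look up a metric by its config/CLI name (final, auc, t_half)."""
    try:
        return _METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; choose from {sorted(_METRICS)}")
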