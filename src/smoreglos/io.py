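"""Serialization helpers: ensemble CSV round-trip, fit results, plotting.

Ensembles are stored as long-format CSV (columns ``time, variable,
replicate, count``) with a JSON sidecar (``<path>.json``) carrying the
simulation metadata (parameters, seed, lattice size) and a schema version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import EnsembleTimeSeries

__all__ = ["write_ensemble", "read_ensemble", "ensemble_to_frame", "frame_to_ensemble", "plot_ensemble"]

SCHEMA_VERSION = 1
_COLUMNS = ["time", "variable", "replicate", "count"]


class EnsembleParseError(ValueError):
    """Malformed ensemble file; the message names the offending row/column."""


def ensemble_to_frame(ens: EnsembleTimeSeries) -> pd.DataFrame:
    """Long-format view of an ensemble (time, variable, replicate, count)."""
    R, T, V = ens.counts.shape
    rep, t_idx, v_idx = np.meshgrid(
        np.arange(R), np.arange(T), np.arange(V), indexing="ij"
    )
    return pd.DataFrame(
        {
            "time": ens.times[t_idx.ravel()],
            "variable": np.asarray(ens.variables)[v_idx.ravel()],
            "replicate": rep.ravel(),
            "count": ens.counts.ravel(),
        }
    )


def frame_to_ensemble(df: pd.DataFrame, meta: dict | None = None) -> EnsembleTimeSeries:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise EnsembleParseError(f"missing column(s): {', '.join(missing)}")
    times = np.sort(df["time"].unique())
    variables = tuple(pd.unique(df["variable"]))
    reps = np.sort(df["replicate"].unique())
    counts = np.full((reps.size, times.size, len(variables)), np.nan)
    t_pos = {t: i for i, t in enumerate(times)}
    v_pos = {v: i for i, v in enumerate(variables)}
    r_pos = {r: i for i, r in enumerate(reps)}
    for row in df.itertuples(index=False):
        counts[r_pos[row.replicate], t_pos[row.time], v_pos[row.variable]] = row.count
    if np.isnan(counts).any():
        raise EnsembleParseError("incomplete ensemble: missing (time, variable, replicate) cells")
    return EnsembleTimeSeries(times, variables, counts, dict(meta or {}))


def write_ensemble(ens: EnsembleTimeSeries, path) -> None:
    """Write an ensemble as long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    ensemble_to_frame(ens).to_csv(path, index=False)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "variables": list(ens.variables),
        "n_replicates": ens.n_replicates,
        **{k: v for k, v in ens.meta.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, default=float))


def read_ensemble(path) -> EnsembleTimeSeries:
    """Read an ensemble written by :func:`write_ensemble`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise EnsembleParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("time", "count"):
        if col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # 1-based, after header
                raise EnsembleParseError(f"non-numeric {col!r} at line {line} of {path}")
            df[col] = pd.to_numeric(df[col])
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return frame_to_ensemble(df, meta)


def plot_ensemble(ens: EnsembleTimeSeries, path) -> None:
    """Minimal static plot: per-variable ensemble mean +- SD over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = ens.mean()
    sd = ens.std()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for v, name in enumerate(ens.variables):
        (line,) = ax.plot(ens.times, mean[:, v], label=name)
        ax.fill_between(
            ens.times, mean[:, v] - sd[:, v], mean[:, v] + sd[:, v],
            alpha=0.25, color=line.get_color(),
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cell count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
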