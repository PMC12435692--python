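"""End-to-end pipeline: sample -> simulate -> fit -> profile -> select ->
field -> GSA, with serialized, resumable intermediates.

The pipeline ties the framework's stages together for the bundled lattice
ABM: it samples ABM parameter vectors over the configured box, generates
replicate ensembles at each vector, calibrates the candidate surrogate
models with profile-likelihood uncertainty and identifiability indices,
selects a surrogate (AIC + identifiability) when several candidates are
configured, interpolates the 95% bound hypersurfaces into a hyperrectangle
field, and finally runs the requested global sensitivity method either
directly on the ABM or through the surrogate-transfer estimator.

Every stage writes its artifact (JSON/CSV) into the run directory together
with a content hash of the configuration subsections it depends on; reruns
with an unchanged configuration load the artifact instead of recomputing,
so a completed run is byte-stable.  All randomness derives from the single
configured master seed via named, documented sub-seeds recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abm as abm_mod
from .abm import ABMParams, run_ensemble, sample_parameter_space
from .gsa import ParameterSpace, abm_metric, run_gsa, surrogate_metric
from .hypersurface import HyperrectangleField, SampledBounds, clip_bounds
from .io import read_ensemble, write_ensemble
from .metrics import get_metric
from .profiles import confidence_bounds, identifiability_index, profile_parameter
from .selection import aggregate_identifiability, compare_models, select_surrogate
from .surrogate import CellCycleModel, FitResult, GrowthModel, fit_sm

__all__ = ["RunConfig", "run_pipeline", "relevant_range_for"]

log = logging.getLogger("smoreglos")

STAGES = ("sample", "simulate", "fit", "profile", "select", "field", "gsa")


def relevant_range_for(param_name: str, capacity: float | None = None) -> tuple:
    """Biologically relevant range used by the identifiability index.

    Carrying capacities are bounded below by one cell and above by the
    physical capacity of the system when one is known (for the bundled ABM,
    the number of lattice sites); rates by 100/day.
    """
    if param_name in ("K_C", "K"):
        return (1.0, capacity if capacity is not None else 1e6)
    if param_name == "nu":
        return (1.0, 20.0)
    return (0.0, 100.0)  # rates, 1/day


def make_model(name: str):
    if name == "cellcycle":
        return CellCycleModel()
    return GrowthModel(name)


@dataclass
class RunConfig:
    """Validated pipeline configuration with all defaults materialized."""

    parameters: dict                      # varied ABM parameters -> (lo, hi)
    fixed: dict = dc_field(default_factory=dict)
    design: dict = dc_field(default_factory=lambda: {"type": "grid", "levels": 2, "n_points": 16})
    abm: dict = dc_field(
        default_factory=lambda: {
            "lattice_size": abm_mod.DEFAULT_LATTICE_SIZE,
            "n_initial": abm_mod.DEFAULT_N_INITIAL,
            "t_end": abm_mod.DEFAULT_T_END,
            "record_times": list(abm_mod.DEFAULT_RECORD_TIMES),
            "n_replicates": 6,
        }
    )
    sm_candidates: list = dc_field(default_factory=lambda: ["cellcycle"])
    fitting: dict = dc_field(default_factory=lambda: {"n_starts": 10})
    profiles: dict = dc_field(default_factory=lambda: {"n_grid": 41})
    gsa: dict = dc_field(
        default_factory=lambda: {
            "method": "moat",
            "mode": "surrogate",
            "metric": "final",
            "n_mc": 100,
            "options": {"r": 10, "levels": 4},
        }
    )
    seed: int = 0

    def __post_init__(self):
        if not self.parameters:
            raise ValueError("config must vary at least one ABM parameter")
        valid = {f.name for f in dataclasses.fields(ABMParams)}
        unknown = set(self.parameters) | set(self.fixed) - valid
        unknown -= valid
        if unknown:
            raise ValueError(f"unknown ABM parameter(s): {sorted(unknown)}")
        for name, b in self.parameters.items():
            if len(b) != 2 or not b[0] < b[1]:
                raise ValueError(f"bad bounds for {name}: {b}")
        if self.gsa["mode"] not in ("direct", "surrogate", "both"):
            raise ValueError("gsa mode must be direct|surrogate|both")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls(parameters=d["parameters"])
        kw = {"parameters": d["parameters"]}
        for f in ("fixed", "design", "abm", "fitting", "profiles", "gsa"):
            merged = dict(getattr(base, f))
            merged.update(d.get(f, {}))
            kw[f] = merged
        kw["sm_candidates"] = list(d.get("sm_candidates", base.sm_candidates))
        kw["seed"] = int(d.get("seed", 0))
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def space(self) -> ParameterSpace:
        names = list(self.parameters)
        return ParameterSpace(names=names, bounds=[self.parameters[n] for n in names])

    def template(self) -> ABMParams:
        return ABMParams(**{k: (int(v) if k == "T_con" else v) for k, v in self.fixed.items()})

    def sub_seed(self, label: str) -> int:
        tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
        return int(np.random.SeedSequence([self.seed, tag]).generate_state(1)[0]) & 0x7FFFFFFF

    def stage_hash(self, stage: str) -> str:
        deps = {
            "sample": ["parameters", "design", "seed"],
            "simulate": ["parameters", "design", "fixed", "abm", "seed"],
            "fit": ["parameters", "design", "fixed", "abm", "sm_candidates", "fitting", "seed"],
            "profile": ["parameters", "design", "fixed", "abm", "sm_candidates", "fitting", "profiles", "seed"],
            "select": ["parameters", "design", "fixed", "abm", "sm_candidates", "fitting", "profiles", "seed"],
            "field": ["parameters", "design", "fixed", "abm", "sm_candidates", "fitting", "profiles", "seed"],
            "gsa": ["parameters", "design", "fixed", "abm", "sm_candidates", "fitting", "profiles", "gsa", "seed"],
        }[stage]
        payload = json.dumps({k: getattr(self, k) for k in deps}, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_if_cached(path: Path, expect_hash: str):
    if path.exists():
        data = json.loads(path.read_text())
        if data.get("config_hash") == expect_hash:
            return data
    return None


def run_pipeline(config: RunConfig, outdir, stages=STAGES) -> dict:
    """Execute (a prefix of) the pipeline; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "pipeline.log")
    log.addHandler(fh)
    manifest = {
        "seed": config.seed,
        "sub_seeds": {},
        "stages": {},
        "evaluation_counts": {},
    }
    try:
        ctx = {}
        for stage in STAGES:
            if stage not in stages:
                break
            _STAGE_FUNCS[stage](config, outdir, ctx, manifest)
            manifest["stages"][stage] = config.stage_hash(stage)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    except Exception:
        log.exception("pipeline stage failed; partial artifacts retained in %s", outdir)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    return manifest


# -- stages ------------------------------------------------------------------


def _stage_sample(config, outdir, ctx, manifest):
    h = config.stage_hash("sample")
    path = outdir / "points.json"
    cached = _load_if_cached(path, h)
    space = config.space()
    if cached:
        pts = np.array(cached["points"], float)
        log.info("sample: loaded %d cached points", len(pts))
    else:
        seed = config.sub_seed("sample")
        manifest["sub_seeds"]["sample"] = seed
        d = config.design
        pts = sample_parameter_space(
            space, design=d.get("type", "grid"), levels=d.get("levels", 2),
            n_points=d.get("n_points"), seed=seed,
        )
        path.write_text(json.dumps(
            {"config_hash": h, "names": space.names, "points": pts.tolist()}
        ))
        log.info("sample: %d points over %s", len(pts), space.names)
    ctx["space"] = space
    ctx["points"] = pts


def _stage_simulate(config, outdir, ctx, manifest):
    h = config.stage_hash("simulate")
    ens_dir = outdir / "ensembles"
    ens_dir.mkdir(exist_ok=True)
    marker = ens_dir / "stage.json"
    cached = _load_if_cached(marker, h)
    seed = config.sub_seed("simulate")
    manifest["sub_seeds"]["simulate"] = seed
    space, pts = ctx["space"], ctx["points"]
    template = config.template()
    a = config.abm
    ensembles = []
    for i, p in enumerate(pts):
        path = ens_dir / f"point_{i:04d}.csv"
        if cached and path.exists():
            ensembles.append(read_ensemble(path))
            continue
        params = ABMParams.from_vector(space.names, p, template)
        ens = run_ensemble(
            params,
            n_replicates=a["n_replicates"],
            base_seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0]) & 0x7FFFFFFF,
            lattice_size=a["lattice_size"],
            n_initial=a["n_initial"],
            t_end=a["t_end"],
            record_times=a["record_times"],
        )
        write_ensemble(ens, path)
        ensembles.append(ens)
    marker.write_text(json.dumps({"config_hash": h, "n_points": len(pts)}))
    manifest["evaluation_counts"]["abm_setup_simulations"] = len(pts) * a["n_replicates"]
    ctx["ensembles"] = ensembles
    log.info("simulate: %d ensembles x %d replicates", len(pts), a["n_replicates"])


def _stage_fit(config, outdir, ctx, manifest):
    h = config.stage_hash("fit")
    path = outdir / "fits.json"
    cached = _load_if_cached(path, h)
    seed = config.sub_seed("fit")
    manifest["sub_seeds"]["fit"] = seed
    fits = {}
    if cached:
        for name, entries in cached["fits"].items():
            model = make_model(name)
            fits[name] = [
                FitResult(
                    name, tuple(model.param_names),
                    np.array([e["params"][p] for p in model.param_names]),
                    e["rss"], e["n_obs"], e["k"], e["converged"],
                    np.array(e["init"]), e["seed"],
                )
                for e in entries
            ]
        log.info("fit: loaded cached fits")
    else:
        for name in config.sm_candidates:
            model = make_model(name)
            fits[name] = [
                fit_sm(model, ens, n_starts=config.fitting["n_starts"], seed=seed)
                for ens in ctx["ensembles"]
            ]
        path.write_text(json.dumps(
            {
                "config_hash": h,
                "fits": {n: [f.to_json_dict() for f in fs] for n, fs in fits.items()},
            }
        ))
        log.info("fit: %d candidates x %d points", len(fits), len(ctx["points"]))
    ctx["fits"] = fits


def _stage_profile(config, outdir, ctx, manifest):
    h = config.stage_hash("profile")
    path = outdir / "profiles.json"
    cached = _load_if_cached(path, h)
    if cached:
        ctx["cis"] = {
            name: [
                {p: tuple(ci) for p, ci in point.items()} for point in per_point
            ]
            for name, per_point in cached["cis"].items()
        }
        ctx["indices"] = cached["indices"]
        log.info("profile: loaded cached profiles")
        return
    n_grid = config.profiles["n_grid"]
    capacity = float(config.abm["lattice_size"]) ** 2
    cis = {}
    indices = {}
    for name, fit_list in ctx["fits"].items():
        model = make_model(name)
        cis[name] = []
        indices[name] = []
        for ens, fit in zip(ctx["ensembles"], fit_list):
            point_ci = {}
            point_idx = {}
            for pname in model.param_names:
                prof = profile_parameter(model, ens, fit, pname, n_grid=n_grid)
                ci = confidence_bounds(prof)
                point_ci[pname] = (ci.lower, ci.upper)
                point_idx[pname] = identifiability_index(
                    ci, relevant_range_for(pname, capacity)
                )
            cis[name].append(point_ci)
            indices[name].append(point_idx)
    path.write_text(json.dumps({"config_hash": h, "cis": cis, "indices": indices}, default=float))
    ctx["cis"] = cis
    ctx["indices"] = indices
    log.info("profile: done")


def _stage_select(config, outdir, ctx, manifest):
    h = config.stage_hash("select")
    path = outdir / "selection.json"
    donuts = {
        name: aggregate_identifiability(
            {
                p: [pt[p] for pt in ctx["indices"][name]]
                for p in make_model(name).param_names
            }
        )
        for name in ctx["fits"]
    }
    if len(config.sm_candidates) == 1:
        chosen = config.sm_candidates[0]
        log.info("select: single candidate %r, selection skipped", chosen)
        payload = {"config_hash": h, "selected": chosen, "skipped": True, "donuts": donuts}
    else:
        comparison = compare_models(ctx["fits"], reference=config.sm_candidates[-1])
        chosen = select_surrogate(comparison, donuts)
        payload = {
            "config_hash": h,
            "selected": chosen,
            "win_fractions": comparison.win_fractions,
            "donuts": donuts,
        }
        log.info("select: chose %r (win fractions %s)", chosen, comparison.win_fractions)
    path.write_text(json.dumps(payload, default=float))
    ctx["selected"] = chosen
    ctx["donuts"] = donuts


def _stage_field(config, outdir, ctx, manifest):
    h = config.stage_hash("field")
    path = outdir / "field.json"
    name = ctx["selected"]
    model = make_model(name)
    n_clipped = 0

    class _CI:
        def __init__(self, lo, hi):
            self.lower, self.upper = lo, hi

    capacity = float(config.abm["lattice_size"]) ** 2
    lower = np.empty((len(ctx["points"]), model.k))
    upper = np.empty_like(lower)
    for i, point_ci in enumerate(ctx["cis"][name]):
        for j, pname in enumerate(model.param_names):
            lo, hi, clipped = clip_bounds(
                _CI(*point_ci[pname]), relevant_range_for(pname, capacity)
            )
            n_clipped += clipped
            lower[i, j], upper[i, j] = lo, hi
    if n_clipped:
        log.warning("field: clipped %d unbounded/out-of-range CIs", n_clipped)
    samples = SampledBounds(
        tuple(ctx["space"].names), ctx["points"], tuple(model.param_names), lower, upper
    )
    field = HyperrectangleField(samples)
    field.to_json(path)
    d = json.loads(path.read_text())
    d["config_hash"] = h
    d["n_clipped"] = int(n_clipped)
    path.write_text(json.dumps(d))
    ctx["field"] = field
    log.info("field: %s scheme over %d samples", field.scheme, len(ctx["points"]))


def _stage_gsa(config, outdir, ctx, manifest):
    g = config.gsa
    seed = config.sub_seed("gsa")
    manifest["sub_seeds"]["gsa"] = seed
    metric = get_metric(g["metric"])
    space = ctx["space"]
    model = make_model(ctx["selected"])
    a = config.abm
    results = {}
    if g["mode"] in ("surrogate", "both"):
        init0 = np.mean([e.mean()[0] for e in ctx["ensembles"]], axis=0)
        if model.n_vars == 1:
            init0 = np.atleast_1d(init0.sum())
        f = surrogate_metric(
            ctx["field"], model, metric,
            times=np.asarray(a["record_times"], float), init=init0,
            n_mc=g["n_mc"], seed=seed,
        )
        results["surrogate"] = run_gsa(g["method"], f, space, options=g["options"], seed=seed)
        manifest["evaluation_counts"]["surrogate_metric"] = f.n_evaluations
    if g["mode"] in ("direct", "both"):
        f = abm_metric(
            space, metric, template=config.template(),
            n_replicates=a["n_replicates"], seed=seed,
            lattice_size=a["lattice_size"], n_initial=a["n_initial"],
            t_end=a["t_end"], record_times=a["record_times"],
        )
        results["direct"] = run_gsa(g["method"], f, space, options=g["options"], seed=seed)
        manifest["evaluation_counts"]["direct_abm_metric"] = f.n_evaluations
    rows = []
    for mode, res in results.items():
        for i, nm in enumerate(res.names):
            row = {"mode": mode, "parameter": nm}
            if hasattr(res, "mu"):
                row.update(mu=res.mu[i], mu_star=res.mu_star[i], sigma=res.sigma[i])
            else:
                row.update(S=res.S[i], ST=res.ST[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "gsa_results.csv", index=False)
    (outdir / "gsa_results.json").write_text(
        json.dumps(
            {
                "config_hash": config.stage_hash("gsa"),
                "method": g["method"],
                "results": {
                    mode: {
                        k: getattr(res, k).tolist()
                        for k in ("mu", "mu_star", "sigma", "S", "ST")
                        if hasattr(res, k)
                    }
                    for mode, res in results.items()
                },
                "names": space.names,
            },
            default=float,
        )
    )
    ctx["gsa_results"] = results
    log.info("gsa: %s (%s mode) done", g["method"], g["mode"])


_STAGE_FUNCS = {
    "sample": _stage_sample,
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "profile": _stage_profile,
    "select": _stage_select,
    "field": _stage_field,
    "gsa": _stage_gsa,
}
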