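# smoreglos

Surrogate-model based **global sensitivity analysis for agent-based
models** (ABMs).

Agent-based models of cell populations are expensive to simulate, and
variance- or screening-based global sensitivity analysis (GSA) needs
hundreds to thousands of model evaluations — usually the binding cost.
`smoreglos` sidesteps it: a cheap, explicitly formulated ODE **surrogate
model** (SM) is calibrated to ABM ensembles at a modest number of sampled
parameter vectors; the 95% profile-likelihood bounds of the SM parameters,
viewed as functions over ABM parameter space Ω, are interpolated into
lower/upper **confidence hypersurfaces**; and any GSA method is then run on

    f(p_ABM) ≈ ∫_{Ω_SM(p_ABM)} f̃(p_SM) dμ

where Ω_SM(p_ABM) is the **hyperrectangle** (Cartesian product of the
per-parameter confidence intervals) of SM parameters consistent with the
ABM at p_ABM, μ is the uniform distribution on it, and f̃ is the metric
evaluated on SM trajectories.  The GSA design never touches the ABM.

The package is aimed at modelers who have (or can generate) replicate ABM
time-series output and want Morris/MOAT screening or eFAST variance
decomposition of its parameters at a small fraction of the direct cost.

What's inside:

* a bundled 2D on-lattice cell-proliferation ABM (cell-cycle phases,
  contact inhibition `T_con`, carrying capacity `K_A`, migration `s`,
  four phase-transition rates) as a self-contained test system, plus a
  synthetic growth-ensemble generator;
* ODE surrogates: a two-compartment cell-cycle model
  (dN1S/dt = −λ_C N1S + α_C(2 − (N1S+N2M)/K_C) N2M,
  dN2M/dt = λ_C N1S − α_C N2M) and exponential / logistic /
  von Bertalanffy growth laws;
* weighted least-squares calibration, profile likelihoods with 95%
  bounds, and the 0/1/2 **identifiability index** per SM parameter;
* AIC-based model comparison and a selection rule balancing fit quality
  against identifiability;
* hyperrectangle fields over Ω (multilinear or simplex interpolation) and
  the seeded Monte-Carlo box-mean metric;
* from-scratch **Morris/MOAT** (μ, μ*, σ) and **eFAST** (S_i, S_Ti)
  engines that work on any scalar metric — direct or surrogate-transferred;
* a staged, resumable pipeline with a `smoreglos` CLI.

## Worked example

Calibrate the cell-cycle surrogate to one ABM ensemble and inspect the
uncertainty of its parameters:

```python
import numpy as np
from smoreglos import (ABMParams, run_ensemble, CellCycleModel, fit_sm,
                       profile_parameter, confidence_bounds, identifiability_index)

params = ABMParams(K_A=1450, T_con=4, s=25)
ens = run_ensemble(params, n_replicates=6, base_seed=3)
print("day-3 mean counts (G1/S, G2/M):", np.round(ens.mean()[-1], 1))

model = CellCycleModel()
fit = fit_sm(model, ens, seed=0)
print(f"weighted RSS = {fit.rss:.2f}")
for name, value in fit.params_dict.items():
    prof = profile_parameter(model, ens, fit, name)
    ci = confidence_bounds(prof)
    idx = identifiability_index(ci, (0.0, 100.0) if name != "K_C" else (1.0, 2500.0))
    print(f"{name:9s} = {value:8.2f}  95% CI [{ci.lower:8.2f}, {ci.upper:8.2f}]  index {idx}")
```

Output:

```
day-3 mean counts (G1/S, G2/M): [707.7 549.2]
weighted RSS = 0.90
lambda_C  =     2.07  95% CI [    1.89,     2.26]  index 2
alpha_C   =     2.19  95% CI [    1.96,     2.44]  index 2
K_C       =  1404.94  95% CI [ 1295.94,  1552.43]  index 2
```

Reading it: the culture grows from 400 cells toward its density-limited
plateau; the normalized weighted RSS of 0.90 means the surrogate matches
the ensemble to within its replicate noise (a well-specified fit sits
near 1).  Both transition rates and the carrying capacity have finite
95% bounds inside their biological ranges — identifiability index 2, a
U-shaped profile — so this ABM point contributes a tight hyperrectangle
(λ_C, α_C, K_C ranges above) to the confidence hypersurfaces.

The full pipeline — sample Ω, simulate ensembles, fit, profile, build the
field, and run the screening both directly and through the surrogate —
is one command:

```sh
smoreglos pipeline --config examples/config.yaml --out runs/demo
```

`runs/demo/gsa_results.csv` then holds per-parameter μ, μ*, σ for both
modes.  Stages are cached: rerunning with the same configuration reuses
every completed artifact, and `smoreglos simulate|fit|profile|select|
build-field|gsa` run the pipeline up to the named stage.

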