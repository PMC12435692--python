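# Methods

`smoreglos` infers global sensitivity indices of agent-based-model (ABM)
parameters without running the ABM inside the sensitivity design.  The
five-stage procedure is: (1) simulate replicate ABM ensembles at parameter
vectors sampled over the box Ω (boundary corners plus interior points);
(2) calibrate one or more explicit ODE surrogate models to each ensemble;
(3) quantify surrogate-parameter uncertainty with profile likelihoods,
score each parameter's practical identifiability, and — when several
candidate surrogates are configured — select one by balancing AIC against
identifiability; (4) interpolate the per-point 95% confidence bounds into
lower/upper hypersurfaces over Ω, so that any point of Ω maps to a
hyperrectangle of consistent surrogate parameters; (5) run any global
sensitivity method (Morris/MOAT or eFAST here) on the scalar metric
f(p_ABM) ≈ mean of the surrogate-side metric over that hyperrectangle,
estimated by seeded uniform Monte-Carlo sampling of the box.

## The bundled lattice ABM

The test system is a 2D on-lattice birth–migration model of an in vitro
proliferation assay.  Cells occupy at most one site each and carry a
cell-cycle phase (G1, S, G2, M).  Seven parameters are exposed:

| name | meaning | units | default | box |
|------|---------|-------|---------|-----|
| `K_A` | carrying capacity | cells | 1450 | [500, 2400] |
| `T_con` | contact-inhibition threshold | occupied Moore neighbors | 4 | [1, 7] |
| `s` | migration rate | moves/cell/day | 25 | [0, 50] |
| `rho_G1_S` … `rho_M_G1` | phase-transition rates | 1/day | 4.5 | [3, 6] |

Update rules (fixed step Δt = 0.01 day, cells visited in a fresh random
order each step; each cell first attempts its phase transition with
probability 1 − exp(−ρΔt), then a migration move with probability
1 − exp(−sΔt)):

* **Contact inhibition is G1 arrest.**  The G1→S transition is blocked
  while more than `T_con` of the cell's Moore neighbors are occupied.
  This is the standard biology of confluence — arrest in G1 — and it is
  what produces the accumulation of cells in G1/S as a culture saturates.
  The arrest is local and partial (colony-edge cells keep cycling), so the
  G2/M compartment never empties.
* **Division is the M→G1 transition.**  The parent always re-enters G1;
  a daughter G1 cell appears on a uniformly chosen empty Moore neighbor
  with probability 1 − N/K_A (logistic birth thinning) and only when an
  empty neighbor exists.  Cycling therefore continues at the plateau with
  the division yield reduced from two cells to one — exactly the crowding
  semantics of the surrogate below.  Two simpler alternatives (a blocked
  division leaving the cell in M; carrying-capacity arrest at the G1 gate)
  were rejected because each traps the whole population in a single
  aggregate phase at saturation, which neither matches a desynchronized
  confluent culture nor leaves the surrogate's two transition rates
  identifiable from plateau data.
* The boundary is closed (edge sites have fewer neighbors).  Initial
  cells occupy distinct uniformly random sites with uniformly random
  phases, so replicate ensembles include initial-condition variability.

Default study conditions: 50×50 lattice, 400 initial cells (16% density),
simulated through day 3 with recordings every half day; the output
variables are the aggregate counts N_G1S and N_G2M.  Rates of 3–6/day per
phase give total cycle times of 16–32 h, typical of proliferative lines,
and — together with the dense seeding — put the whole parameter box in the
regime where cultures approach their density-limited plateau within the
3-day window.  This matters scientifically: the final-count metric then
reflects the confluence ceiling (set by `K_A` and `T_con`), the transition
rates only modulate the approach, and the direct sensitivity structure is
capacity-dominated.  With sparser seeding or slower cycling the assay
becomes growth-dominated and the transition rates would control the final
count instead; the defaults deliberately encode the former regime.

## Surrogate models

For the two recorded aggregates the surrogate is the two-compartment
cell-cycle system

    dN1S/dt = −λ_C N1S + α_C (2 − (N1S+N2M)/K_C) N2M
    dN2M/dt =  λ_C N1S − α_C N2M

whose total equilibrates at K_C (at steady state the two transition fluxes
balance and the division yield term forces N1S + N2M = K_C).  For scalar
growth data three classical laws are provided: exponential (λ), logistic
(r, K) and von Bertalanffy (α, β, ν > 1; equilibrium (α/β)^ν).
Exponential and logistic use their closed forms.  Von Bertalanffy is
solved through u = N^(1/ν), which turns it into the linear ODE
du/dt = (α − βu)/ν and hence also into an exact closed form — this avoids
the fractional-power stiffness near N = 0 entirely.  The cell-cycle system
is integrated by classical RK4 with a state-adaptive step
h ≤ 0.2/(λ_C + α_C(1 + max(1, N/K_C))); the crowding factor matters
because hyperrectangle sampling can legitimately produce boxes whose K_C
is far below the state, where the quadratic term dominates the stiffness.
Accuracy is ~10⁻⁹ relative against an adaptive reference integrator at
the default rates; a trajectory that still exceeds the step budget is
reported as non-finite and the corresponding fit is flagged as failed.

## Calibration, profiles, identifiability

Fits minimize the ensemble-SD-weighted residual sum of squares,
normalized by the number of fitted observations:

    RSS = (1/n_obs) Σ_{t,v} [(SM(t,v) − mean(t,v)) / SD(t,v)]²

with the SD floored at max(replicate SD, 1% of the final-time mean,
1 cell).  The surrogate initial condition is pinned to the ensemble mean
at the first recorded time and that point is excluded from the residuals.
With correct weights a well-specified surrogate lands near RSS ≈ 1, which
is what the cell-cycle surrogate achieves on the bundled ABM.  The
optimizer is a bounded Powell search over log-parameters from 10
Latin-hypercube starts (ties broken by lowest RSS, then lexicographically
smallest parameter vector).

Profile likelihoods fix one parameter on a 41-point log grid spanning
[best/100, best×100] (clipped to the fit bounds, with the best-fit value
inserted into the grid) and re-optimize the others, marching outward with
warm starts.  95% bounds are the outermost crossings of
best_RSS + Δ, with Δ = best_RSS · χ²₀.₉₅(1)/n_obs by default (the
best_RSS factor estimates the residual variance; the alternative rule
`chi2` drops it for known-variance weights and is exact for linear
models — the calibration test shows 95.3% empirical coverage over 1000
replications).  Because a well-identified parameter's interval is much
narrower than the log-grid spacing, each crossing bracket is refined by
~12 bisection steps of re-optimized profile evaluations before the final
linear interpolation; without this refinement the intervals are grid-
resolution artifacts and their coverage collapses.

The identifiability index of a parameter is 2 if both 95% bounds are
finite and inside its biologically relevant range, 1 if only one is, 0
otherwise (flat profile).  Relevant ranges: rates (0, 100]/day;
carrying capacities [1 cell, physical capacity of the system] — for the
bundled ABM the number of lattice sites.  A capacity range reaching 10⁶
cells would be meaningless for a 2500-site dish, and clipping unbounded
capacity CIs to such a range floods the hyperrectangle sampler with
implausible boxes; bounding it by the dish is both the biologically
defensible choice and the numerically stable one.

Model selection uses the Gaussian-error AIC,
n_obs ln(RSS_unnorm/n_obs) + 2k (AICc available as an option), plus the
documented heuristic: candidates whose parameters are at least 80%
index-2 are kept, and among those the highest AIC win fraction is chosen;
if no candidate survives the filter the win-fraction leader is used with
a warning.

## Hypersurfaces and the surrogate-transfer estimator

Per-point bounds are clipped to the relevant ranges (clips are counted
and logged — they degrade the field and typically trace back to poorly
identified parameters) and interpolated over Ω: multilinearly when the
sampled points form a rectangular grid, barycentrically on a Delaunay
triangulation otherwise.  The field is exact at sample nodes, continuous
inside the convex hull, and refuses to extrapolate.  Integer ABM
parameters (`T_con`) are interpolated on the real line; rounding happens
only when the ABM itself is simulated.

The transferred metric at p_ABM is the mean of the surrogate-side metric
over n_mc (default 100) uniform samples of the queried hyperrectangle,
seeded deterministically from (seed, p_ABM) so that repeated evaluation
is stable; its standard error scales as 1/√n_mc.  Because each design
point draws its own Monte-Carlo sample, elementary-effect differences
carry √2× that noise — the end-to-end checks use n_mc = 100, at which the
noise is well below the signal of the dominant parameters.

## Sensitivity engines

**Morris/MOAT** uses standard randomized trajectories on a p-level grid
(default p = 4, r = 30 trajectories; the desk-scale end-to-end runs use
r = 10) with Δ = p/(2(p−1)); every trajectory perturbs each parameter
exactly once.  Elementary effects are computed in normalized units by
default, so μ, μ*, σ carry the metric's own units per full-range change
(native-unit effects are an option).

**eFAST** drives the parameter of interest at
ω_max = ⌊(Ns−1)/(2M)⌋ along x = ½ + arcsin(sin(ωs + φ))/π with a random
phase per resampling (defaults Ns = 65, M = 4, Nr = 4).  Main-effect
indices read the spectrum at ω_max's first M harmonics; total effects use
1 − V_c/V with V_c the band ω ≤ ω_max/2.  Two non-obvious design rules
are enforced for the complementary parameters: their frequencies are
pairwise distinct (two parameters sharing a frequency are perfectly
correlated along the curve, which corrupts the per-curve variance — the
dominant error mode at small Ns), and any candidate frequency with a
low-order harmonic (≤ M+1) on a counted frequency k·ω_max is rejected
(e.g. ω_max/4 would alias every fourth-order nonlinearity onto the main
effect).  At Ns = 65 this leaves {3, 1}, which reproduces the Ishigami
closed-form main effects within 0.05.  Known limitation: with
complementary fundamentals as large as ω_max/2 − 1, part of their
higher-harmonic content falls above the ω_max/2 cutoff, so total-effect
indices are biased upward at small Ns; orderings (and S_i ≤ S_Ti) are
preserved.  With more than three parameters at Ns = 65 complementary
frequencies must repeat — raise Ns when total-effect precision matters.

## Reproducibility

Every stochastic component draws from a seed derived by
`numpy.random.SeedSequence` from a single master seed plus a stable tag
(replicate index, stage name, design point digest).  Identical
configuration and seed reproduce results bit-for-bit; the pipeline writes
each stage's artifact with a hash of the configuration subsections it
depends on and reuses artifacts on rerun.

## What the synthetic generators do and do not show

The mock growth generator (deterministic growth law × i.i.d. lognormal
noise) exercises surrogate selection and parameter recovery under a
correctly specified noise model; it has no spatial structure, no
replicate-to-replicate initial-condition variability and no model
misspecification, so recovery there is a soundness check, not evidence
about real ABM output.  The bundled lattice ABM provides genuine
misspecification (the surrogate ignores space), but it remains a desk-
scale stand-in: demographic noise shrinks with population size, the
observation schedule is short and regular, and the parameter box was
chosen to sit in the saturation-dominated regime described above.
Passing tests therefore demonstrate the machinery — calibration,
identifiability scoring, hypersurface transfer, engine correctness — and
the method's central consistency property on this system, not the
transferability of any particular sensitivity ranking to other ABMs.

## Problem sizes used by the shipped checks

Field construction for the end-to-end comparison uses the 2-level corner
grid of the 7-parameter box (128 points × 6 replicates); direct MOAT uses
r = 10 trajectories with 5 replicates per point, repeated 10 times with
different seeds; the identifiability survey uses the corner grid plus 16
interior points with 6 replicates each.  These sizes give stable rankings
and index frequencies on this system while keeping a full run on a single
CPU in the minutes range.
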