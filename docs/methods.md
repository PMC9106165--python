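# Methods

## Model

`osteomac` implements a nine-variable ordinary-differential-equation model of
the cellular response to a localized bone injury in mice. The state vector,
in canonical order, is:

| Symbol | Meaning | Units |
|---|---|---|
| `Mo` | undifferentiated monocytes | cells |
| `M`  | unpolarized macrophages | cells |
| `M1` | pro-inflammatory (M1) macrophages | cells |
| `M2` | anti-inflammatory (M2) macrophages | cells |
| `Mo1`| pro-inflammatory monocytes | cells |
| `OB` | osteoblasts | cells |
| `OC` | osteoclasts | cells |
| `B`  | woven-bone volume | mm³ |
| `D`  | injury signal (cell debris) | dimensionless |

The injury signal `D` decays as it is cleared by pro-inflammatory cells
(`dD/dt = -delta_D * (M1 + Mo1) * D`) and drives monocyte recruitment,
macrophage polarization and (in some model variants) osteoblast expansion.
Osteoblasts deposit woven bone; osteoclasts resorb it; both populations relax
back to homeostasis as the injury resolves.

## Hypothesis space

Three biological questions are each encoded as interchangeable functional
forms, giving an 18-member model space (`a ∈ {1,2,3} × b ∈ {1,2} × c ∈
{1,2,3}`, named e.g. `a3b2c2`):

* **a — osteoclast regulation.** a1: formation from macrophages at a constant
  (optionally debris-boosted) rate, inhibited by M2; a2: the same form with
  inhibition by osteoblasts; a3: formation proportional to the osteoblast
  count, inhibited by M2.
* **b — osteoblast expansion.** b1: driven by anti-inflammatory macrophages
  (`gamma_OB * M2`); b2: driven directly by the injury signal
  (`gamma_OB * D`).
* **c — polarization pathways.** c1/c2 differ in whether anti-inflammatory
  polarization is driven by debris or by pro-inflammatory cells; c3 is a
  reduced pathway with constant depolarization and M1-driven monocyte
  polarization.

`hypotheses.parameter_manifest` assigns every parameter a role per
combination — *free* (fitted), *fixed* (literature lifespans `delta_Mo`,
`delta_M`, `delta_OC`) or *derived* (homeostasis, below) — and parameters of
unused branches are excluded entirely, so the AIC penalty `p` is
combination-specific (e.g. 18 for `a3b2c2`, 20 for `a1b2c2`, 15 for
`a3b2c3`).

## Homeostasis constraint

The uninjured baseline (day 0 means) must be a fixed point of the uninjured
system (`M1 = M2 = Mo1 = D = 0`). Solving the steady-state equations yields
the replenishment/formation rates:

* `H_Mo = delta_Mo * Mo0`
* `Pi_B = delta_B * OC0 * B0 / OB0`
* `H_OB = delta_OB * OB0 * B0 / OC0`
* `d_OC = delta_OC * OC0 / (OB0 * M0)` under a3 and
  `delta_OC * OC0 / M0` under a1; under a2 the osteoblast-dependent
  inhibition terms are nonzero at baseline, so the full balance
  `d_OC = delta_OC * (1 + Inhib_OC2*OB0) * (1 + Inhib_OC*OB0) * OC0 / M0`
  is used (anything else leaves a residual drift at baseline)
* `H_M = delta_M * M0 + delta_OC_eff * OC0` (replenishment covers death plus
  the macrophage-to-osteoclast outflux)

During fitting the derived parameters are recomputed from the dataset's own
day-0 means at every candidate, so the baseline stays a fixed point
throughout the search. The two derived rates with published reference values
(`d_OC ≈ 5.35e-5`, `Pi_B ≈ 6.018e-7`) are reproduced within 1 % (the
discrepancy is rounding of the printed inputs).

## Numerics

The right-hand side and the integrators are numba-compiled; model selection
needs tens of thousands of 14-day solves, which rules out a Python-level
solver loop in the hot path. Two integrators are provided:

* **Dormand–Prince 4(5)** (explicit, embedded error estimate, FSAL) — the
  default for simulation.
* **Rosenbrock 2(3)** (linearly implicit, L-stable, finite-difference
  Jacobian) — for stiff regimes. The a2 family multiplies the osteoclast
  clearance by `(1 + Inhib_OC2*OB)`, which reaches 10³–10⁷ per day for
  plausible (and especially for randomly drawn) parameter values and
  stability-limits any explicit method.

Both use a scaled per-variable error norm (`atol` scaled by each variable's
initial magnitude — the state spans ~10⁻¹ mm³ to ~10⁵ cells). They are
cross-validated against each other, against a literal transcription of the
model equations, against a fixed-step RK4 oracle (dt = 10⁻³ d) and against
`scipy.integrate.solve_ivp` in the test suite.

The fitting engine defaults to `method="auto"`: each candidate is integrated
with Dormand–Prince under a step cap (`max_steps`, default 50 000) and falls
back to Rosenbrock when the cap trips; candidates that defeat both solvers
score an infinite objective. The fallback runs at a looser tolerance
(`fallback_rtol`, default 10⁻⁴) because the low-order method is
accuracy-limited rather than stability-limited — its job is to score stiff
candidates approximately, not to produce reference trajectories. Failing
pathological candidates fast rather than grinding a stability-limited
explicit solver is standard practice when wrapping ODE solvers in a
derivative-free optimizer. An optional `maxfev` bound caps objective
evaluations per optimizer start; adaptive Nelder–Mead shrink steps cost about
one evaluation per free parameter per iteration, so `maxiter` alone
under-bounds the evaluation count on high-dimensional fits.

## Fitting objectives and ranking

Residuals are standardized per cell, `r_ij = (f_j(t_i) - mean_ij) / sd_ij`,
over the post-baseline time points only (8 variables × 5 times = 40 cells
under the default design). Two objectives:

* `J2 = max_j Σ_i r_ij²` — the *worst variable's* weighted sum of squares,
  forcing every variable to be fitted equally well;
* `J∞ = max_ij r_ij²` — the Chebyshev (minimax) criterion.

`J2 ≥ J∞` always (a sum of non-negative terms dominates its largest term).
Models are ranked by `AIC = 2p + 2J` with ties broken by the count of
residual cells with `r² < 1` (model inside the error bar).

Optimization is multi-start Nelder–Mead in log10 parameter space with a
quadratic exterior penalty for bound violations. The first start is the
default parameter vector; the rest are log-uniform draws within the bounds.
Bounds default to three decades around each positive default; effectively
zero defaults (< 10⁻¹²) get a wide near-zero band (10⁻¹⁶, 10⁻¹), reflecting
that those pathways were effectively switched off in the reference
parameterization.

## Synthetic data generator

`synth.generate_replicates` emulates the study design: 8 observed variables
(`OB, OC, B, Mo, M, Mo1, M1, M2`) at days 0, 1, 2, 3, 7 and 14 with 5
replicates per cell. Noise is multiplicative Gaussian,
`value = max(0, truth * (1 + cv * eps))` with `eps ~ N(0,1)` — a constant
coefficient of variation, the usual first-order model for cell-count
measurements. Summaries use sample means and SDs (n−1). Cells whose
replicates have zero spread (e.g. variables identically zero at day 0) get a
small SD floor with a warning; such cells sit at baseline and never enter
the residual set.

Realism limits: the generator draws independent noise per cell (no
within-animal correlation across variables or serial correlation across
days, even though the study followed cohorts), normal rather than log-normal
noise (so large CVs can truncate at zero), and a shared CV across variables.
These are deliberate simplifications; the generator's purpose is recovery
testing, not bio-realistic simulation.

## In-silico OSM depletion

`perturb.apply_osm_depletion` scales the oncostatin-M-dependent channels:
osteoblast expansion ×0.5, bone mineralization (`beta`) ×0.5, and the
M2-mediated osteoclast inhibition constants (`Inhib_OC`, `Inhib_OC2`) ×0.2.
Under b1 the expansion channel is `gamma_OB`; under b2 expansion is driven by
the injury signal, which is not OSM-dependent, so the default mode leaves it
untouched (`b2_expansion_mode="noop"`). Note the direction of the osteoblast
response under the reference model `a3b2c2` then depends on the channel: the
literal three-factor scaling *raises* the osteoblast peak (weaker osteoclast
inhibition → more osteoclasts → more coupled osteoblast replenishment) while
still halving the woven-bone peak. Mapping the knockout's reduced bone
formation onto the expansion rate itself (`b2_expansion_mode="scale_gamma"`)
lowers both the osteoblast and bone peaks; the acceptance suite uses that
mode for the osteoblast-peak direction.

## Scaled-down acceptance settings

The recovery acceptance suites are stochastic and budget-limited, so they run
scaled down; the settings were chosen for runtime, not tuned toward the
thresholds:

* parameter recovery (`gamma_OB`, `delta_D`; CV = 0.05, seeds 1–5):
  3 restarts × 300 iterations — recovery lands within ~2 % against a 25 %
  criterion;
* model-selection recovery (all 18 combos, CV = 0.1, seeds 1–5): 2 restarts ×
  150 iterations, 400 evaluations per start, 10 000-step solver cap — the
  generating combination wins by several orders of magnitude in J2 in
  prototypes (e.g. 7.1 versus ≥ 2.5 × 10³ for every competitor).

## Known limitations

* The Rosenbrock solver is second order; at `rtol = 1e-6` its global error is
  ~10⁻² relative (consistent with order-2 convergence), adequate for fitting
  noisy data but not for reference trajectories — use the default
  Dormand–Prince solver for those.
* The published summary statistics behind the original study exist only as
  figure plots, so absolute AIC values and residual counts from that study
  are not reproducible here; the pipeline is validated on synthetic data.
* `derive_homeostatic_parameters` requires strictly positive baseline cell
  counts and bone volume; datasets with a zero baseline mean cannot use
  derived replenishment (set `homeostatic_replenishment="free"` instead).
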