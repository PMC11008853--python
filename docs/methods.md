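# Methods

## Model and assumptions

The chamber is modelled as three well-mixed compartments in series —
upper skin, lower skin, receptor perfusate — with linear exchange:

```
x₁' = k_in + k_d·x₂ − (k_d + k_c)·x₁
x₂' = (k_d + k_c)·x₁ + k_d·x₃ − (2k_d + k_c)·x₂
x₃' = (k_d + k_c)·x₂ − (k_d + k_out)·x₃
```

Assumptions built into this form:

* **Infinite dose.** The donor cream is never depleted; k_in is constant
  for the whole run.  Appropriate for thick cream layers over hours-long
  experiments.
* **Constant rates.** Skin hydration, temperature and barrier state are
  constant within a run; condition changes (temperature, disease) enter
  as different rate values, not as time dependence.
* **Units.** Time is hours, rates 1/h.  The states inherit the data's
  units (cumulative mass per area, μg/cm² or ng/cm²): the observable
  y = x₃ is fitted directly to the measured series with no separate gain
  parameter, so k_in carries (observable unit)/h.  A
  `cumulative_outflow` observation mode (trapezoidal ∫k_out·x₃) is
  provided for users who prefer explicit collected-mass bookkeeping, but
  the calibration workflow uses the direct mode throughout.
* **Initial state.** (0, 0, 0) — drug-free skin and fresh perfusate.  An
  experimental option co-estimates x₁(0), x₂(0).

Summing the equations gives d(x₁+x₂+x₃)/dt = k_in − k_out·x₃, so any
equilibrium has x₃* = k_in/k_out; with all rates positive the rate matrix
is Metzler and Hurwitz, trajectories from nonnegative states stay
nonnegative and converge to the unique steady state.

Simulation is exact: x(t) = e^{At}(x₀ + A⁻¹b) − A⁻¹b when A is
invertible, with an augmented-matrix exponential
(d/dt (x,1) = [[A,b],[0,0]](x,1)) as the degenerate-parameter fallback.
An LSODA integration (`simulate_numeric`) exists solely as an
independent cross-check; fitting always uses the closed form.  On
uniform grids the optimizer path uses a single-step propagator (one 4×4
matrix exponential per curve).

## Identifiability: what the elimination actually shows

Eliminating x₁, x₂ yields y''' + θ₁y'' + θ₂y' + θ₃y + θ₄ = 0 with

```
θ₁ = 2k_c + 4k_d + k_out
θ₂ = k_c² + 3k_c·k_d + 2k_out·k_c + 3k_d² + 3k_out·k_d
θ₃ = k_out (k_c + k_d)²
θ₄ = −k_in (k_c + k_d)²
```

θ₁…θ₃ are exactly the characteristic-polynomial coefficients of A
(Cayley–Hamilton makes the state terms vanish; the input constant gives
θ₄), so the observable determines the rates **only through θ** — for any
initial state, since the initial conditions of y and its derivatives are
data, not parameters.

Inverting θ reduces to one scalar equation.  With s = k_c + k_d the last
two coefficients give k_out = θ₃/s² and k_in = −θ₄/s²; the θ₁ equation is
linear in k_d given s; substituting into the θ₂ equation and clearing
denominators leaves the sextic

```
P(s) = 4s⁶ − 2θ₁s⁵ + (θ₁² − 4θ₂)s⁴ + 6θ₃s³ − θ₃² = 0 .
```

`theta_preimages` finds all roots (`numpy.roots` + Newton polish),
filters for nonnegative rates and exact forward-map agreement, and
returns the full equivalence class.  **The class is generically not a
singleton**: (1,1,1,1) shares its θ — and, verified numerically, its
output to machine precision — with (3.74527, 0.59392, 0.43953, 3.74527)
and (0.68203, 0.73724, 1.68450, 0.68203).  Over log-uniform draws in
[10⁻², 10²] roughly 55–62% of rate vectors have a unique positive
preimage; the rest have two or three.  The model is therefore *locally*
identifiable (finitely many candidates, the truth always among them —
the tests assert this at < 10⁻⁶ relative error) but **not globally
structurally identifiable**, contrary to the claim attached to it in the
source study.  Uniqueness holds empirically in the convection-dominated
regime (k_c ≫ k_d with moderate k_out/k_d); all shipped scenario truths
and the recovery reference truth are placed there, and the acceptance
test that asserts 100/100 unique recovery is expected to fail — it
documents the gap between the published claim and the model as written.

Design choices: derivatives of y for the eliminated-ODE residual are
computed analytically from powers of A (never finite differences), so
the residual isolates model error from discretization error.
`params_from_theta` returns the class member with the smallest s — a
deterministic tie-break among observationally indistinguishable
candidates, not a claim of truth.

## Calibration

The objective is V = ‖y_m − y_c‖₂/‖y_m‖₂ (dimensionless,
scale-invariant).  Each of the (default 200, log-uniformly seeded over
[10⁻³, 10³]) starts runs a three-stage deterministic local solve inside
the physiological box [10⁻³, 10³] per rate:

1. **Hybrid descent.** Trust-region least squares first in log
   coordinates (traverses decades cheaply from arbitrary starts), then a
   polish in the raw bounded space — noise can push the maximum
   likelihood k_d to exactly the lower bound, which raw coordinates
   reach as an ordinary boundary point while log coordinates crawl
   toward −∞.
2. **Variable-projection scan** (only if stage 1 stalls above rounding
   level): from x₀ = 0 the observable is exactly linear in k_in, so on a
   log grid of the three shape rates the optimal inflow is a closed-form
   projection; descents are restarted from the best few mutually distant
   grid points.
3. **Split-redistribution ladder.** The stiff direction of the landscape
   is the diffusion/convection split at nearly fixed s = k_d + k_c, with
   a genuine inferior local minimum on the k_c = 0 (pure-diffusion)
   boundary; the ladder retries complementary splits of s (role swap,
   95/5 and 5/95) and re-centers boundary-pinned rates.

Within a multi-start run, stalled points landing in the same basin share
one memoized refinement, and refinement is skipped for starts that
already reach the best objective level known for the dataset; per-start
results are unchanged, only duplicate work is avoided.  Convergence uses
tolerance 10⁻¹⁰ with at most 2000 evaluations per start; ties in V go to
the earliest start index.  On noise-free scenario data ≥ 99% of 200
starts end within 10⁻⁶ of V_min (the acceptance bar is 95%).

## Synthetic data

The generator emulates the chamber protocol: grids of 15- or 30-min
samples over 5, 6 or 12 h (plus the drug-free t = 0 point), three
replicates per condition, and the collection arithmetic (4 μL/min × 
interval → sample volume; mass/0.5 cm² accumulates).

**Noise model.** Two components, both multiplicative: a mean-one
lognormal replicate factor (CV 0.15; skin punch-to-punch variability)
and per-sample Gaussian noise (CV 0.10) applied to the **collected
increments**, not to the cumulative values — each timed aliquot is
measured independently, so its error enters once and the running sum
self-averages.  Negative increments are clipped, keeping every synthetic
replicate monotone like the real curves.  The CVs were chosen to
reproduce SEM bands of the magnitude the published mean-of-three figures
show.  What the generator does *not* emulate: assay detection limits,
within-run drift, occasional non-monotone artifacts from chamber
bubbles, or biological time dependence of the barrier — so passing tests
demonstrate correctness of the pipeline under the stated noise model,
not robustness to every failure mode of real data.

**Scenario calibration.** Each of the 13 scenarios ships a frozen shape
(k_d, k_c, k_out) and a frozen noise-free endpoint target; k_in follows
exactly from the linearity of the zero-state response, so endpoints hit
their targets to rounding.  Targets are the midpoints of the published
exclusion windows where one exists; the disease scenarios encode the
published statements as endpoint ratios — 4.5× control at 24 h
(published: more than 4×), 4.0× at 96 h (more than 3.5×), +30% for the
allergic ear — and the 32 °C caffeine endpoint (57.5 μg/cm²) exceeds the
ambient one (35 μg/cm²).  Shapes were chosen for the curve characters
reported per condition (pronounced lag for the anti-inflammatory creams,
near-linear profiles for diseased skin) subject to lying in the uniquely
identifiable regime, so the shipped truths are recoverable from their own
noise-free data (< 0.1% in the round-trip test).  The diclofenac window
is shipped as published (50–100 μg/cm²) although its units are
inconsistent with the drug's reported lowest-penetration rank; the
scenario carries a `window_inconsistent` flag and is excluded from
cross-drug ratio assertions.

## Parameter recovery

`parameter_recovery_experiment` simulates the reference truth
(k_in = 10, k_d = 0.05, k_c = 2.0, k_out = 0.5), draws three noisy
replicates per repeat, fits their mean curve (the study's own analysis
object), and reports per-rate bias, RMSE and median absolute relative
error.  The default grid is the 12 h/30 min schedule — of the chip
designs it is the most informative for k_out, because the curve
approaches saturation within the window.  The reference truth lies in
the uniquely identifiable regime with the cascade and outflow timescales
both resolvable on the grid.  At 10% sampling noise the medians for k_in
and k_out are a few percent; k_d is essentially unrecoverable from a
single monotone curve (the estimate collapses to the box edge) and k_c
absorbs the transport total — this is the practical-identifiability
sloppiness expected of catenary models observed at one end, and the
report quantifies it rather than hiding it.  The estimator is heavy
tailed: occasional repeats land on a distant near-equivalent ridge
(inflated k_in and k_out at nearly fixed ratio); medians are the robust
summary.

## Two-phase kinetics

The descriptive slow/rapid regression fits y = β₀ + β₁t + β₂(t − t_b)₊
by least squares for every admissible breakpoint t_b (observed interior
sample times with ≥ 3 points per side; continuity is built into the
hinge) and keeps the global best.  Perfectly linear data degenerate
gracefully (equal slopes, breakpoint reported but meaningless); fewer
than six samples is an error.

## Numerical choices and degenerate inputs

* Condition-number guard (10¹²) decides between the affine-shift and
  augmented-matrix simulation paths; both are exact in exact arithmetic.
* `steady_state` and θ-inversion require the rates that make them well
  posed (k_out > 0, k_d + k_c > 0; θ₁…θ₃ > 0 > θ₄) and name the
  offending quantity otherwise.
* Sextic roots are Newton-polished to |Δs| < 10⁻¹⁵s and deduplicated at
  10⁻⁸ relative; preimages must reproduce θ to 10⁻⁸ relative.
* The objective is undefined for an identically zero measured series and
  raises immediately rather than returning a misleading number.
* All stochastic components (starts, noise, draws) flow through
  `numpy.random.default_rng` seeds; identical seeds give bit-identical
  datasets and fits.

## Known limitations

* Three compartments are fixed; no spatial refinement or
  donor-depletion physics.
* No confidence intervals or profile likelihood — point estimates and
  V_min only, matching the source analysis; the recovery experiment is
  the package's uncertainty surrogate.
* Joint recovery of rates and unknown initial conditions is exposed but
  experimental; all validated workflows assume the drug-free start.
* Absolute levels of the disease scenarios (and everything about their
  biology) are synthetic constructions constrained only by the published
  ratios and windows.
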