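# Methods

## The model

`glucodyn` describes a monolayer tumor-cell culture after a medium change as
three coupled ordinary differential equations for live-cell abundance N(t),
dead-cell abundance D(t) (both measured as confluence, the percentage of the
well floor covered), and the glucose concentration G(t) in mM, with time t in
days since the medium change:

    dN/dt = k_p N (1 - N/θ) S_p(G,t) - k_d N S_d(G,t) - k_bys N D/(D+N)
    dD/dt =                            k_d N S_d(G,t) + k_bys N D/(D+N)
    dG/dt = -v c N G/(G + G*)

    S_d(G,t) = (1 - G/(G + G_min)) tanh(t),   S_p = 1 - S_d

Live cells grow logistically toward the carrying capacity θ, die of
starvation at the maximum rate k_d, and die of a bystander effect (factors
released by, and competition with, accumulated dead cells) at the rate k_bys
scaled by the dead-cell fraction D/(D+N). The state functions S_p and S_d
partition the population's instantaneous fate between proliferation and
starvation death: they sum to one identically, S_d rises as glucose falls
(half-effect at G = G_min), and the tanh(t) factor delays glucose sensing —
at t = 0 the cells still respond to their pre-change medium, and the new
glucose level takes roughly two days to be felt fully, consistent with cells
already past the cell-cycle restriction point completing division
regardless of nutrient state. Death terms appear with opposite signs in
dN/dt and dD/dt, so death only transfers mass between compartments; total
abundance changes only through the logistic term.

Three variants form the selectable family: variant 1 drops the bystander
terms, variant 3 drops the starvation terms, variant 2 keeps everything.
At N = D = 0 the bystander fraction is defined as 0 (no cells, no effect).

### Units and the cell/confluence conversion

The observable is confluence, so N, D, and θ (default 100 %) are kept in
confluence percent. The consumption rate v and the surface-law amplitude
k_bys,0 (below) are per-cell rates, as is conventional for uptake constants;
an explicit conversion constant `cells_per_pct` (default 800 cells per
confluence percent, i.e. ~8×10⁴ cells in a fully confluent 96-well) links
the two scales in dG/dt and in the surface law. With the default global
rates (k_p ≈ 0.09–0.14 day⁻¹, k_d ≈ 0.04–0.13 day⁻¹, v ≈ 2.7–4.5×10⁻⁵
mM·cell⁻¹·day⁻¹) this conversion puts glucose depletion of sub-mM media on
a 1–2 day timescale and bystander rates at 0.2–1 day⁻¹, which is what
produces the observed dynamic range: strong declines (−70 % and worse) in
starved high-density wells, net growth above ~2 mM. Reading "cell⁻¹" as
"per confluence percent" instead makes both terms dynamically inert, so the
per-cell reading is used throughout. θ, G* (default 1 mM), and G_min
(default 0.1 mM) are assigned constants, configurable and recorded with
every output; they are stand-ins on the right order of magnitude, not
measured values.

### Bystander-rate laws

Per-well calibrated bystander rates correlate with the initial conditions,
and two empirical laws capture the dependence:

* surface (cluster-forming, gap-junction-coupled lines):
  k_bys = k_bys,0 · N₀ · exp(−α G₀), N₀ in cells;
* curve (dispersed lines with a soluble-factor component):
  k_bys = k_bys,0 · exp(−α G₀) + β.

Built-in profile values: surface k_bys,0 = 2.37×10⁻⁵ cell⁻¹day⁻¹,
α = 0.13 mM⁻¹ (BT-474-like); curve k_bys,0 = 0.71 day⁻¹, α = 0.98 mM⁻¹,
β = 0.22 day⁻¹ (MDA-MB-231-like). The curve parameters are read on the
day⁻¹ scale: an amplitude five orders of magnitude below its own baseline
would make the law's documented glucose dependence unobservable, so the
package treats the day⁻¹ reading as the physically coherent one. α is
scale-free either way. Law fitting is inverse-variance weighted (weights
1/ci² from each sample's 95 % CI half-width; zero half-widths capped at the
smallest nonzero one) and is performed on the mixed-scenario per-well
estimates only.

## Synthetic cohorts

The generator emulates a time-resolved live/dead confluence microscopy
design: 10 initial glucose levels (0–10 mM), three seeding tiers per line
(≈24/36/52 % and ≈37/56/72 %), 4 replicates, 33 frames every 3 h over 4
days. Per well it draws N₀ ~ Normal(tier, 0.5 %), D₀ ~ Normal(0.5 %,
0.05 %) (dead cells are nearly absent at seeding), k_bys from the line's
law with lognormal dispersion (σ = 0.1, biological well-to-well variation),
simulates variant 2, and applies i.i.d. multiplicative Gaussian noise
truncated at zero — live 6.88 %/5.17 %, dead 30.83 %/16.78 % for the two
profiles, matching the empirically reported fit uncertainties. What this
does **not** emulate: time-correlated segmentation error, plate-position
effects, detachment of dead cells (observed dead confluence here is purely
cumulative), or measured glucose (generated but never treated as an
observable). Passing tests therefore demonstrate estimator correctness
under the stated noise model, not robustness to structured real-world
artifacts.

## Calibration

Three scenarios: local (every well its own parameters), global (one vector
for the cohort), mixed (shared k_p, k_d, v; per-well k_bys). All use
bounded trust-region-reflective least squares (rates in [0, 2] day⁻¹, v in
[0, 10⁻³]), 10 multistarts with log-uniform initial guesses (rates
10⁻³–2, v 10⁻⁷–10⁻³), convergence tolerances 10⁻¹⁰ (cost) and 10⁻⁸ (step),
and forward simulation by adaptive RK45 at rtol 10⁻⁸/atol 10⁻¹⁰ with tiny
negative excursions clipped. Joint fits integrate all wells as one stacked
ODE system and exploit the block structure of per-well parameters through a
sparse Jacobian pattern. 95 % CIs are linearized Gauss–Newton intervals,
t(n−p) · sqrt(s²[(JᵀJ)⁻¹]kk); a rank-deficient Jacobian raises an error
naming the degenerate directions.

Three numerical/statistical choices matter and were made after explicit
Monte-Carlo characterization (all three are config-switchable):

1. **GLS weighting (default).** Confluence noise is multiplicative, so
   residuals are scaled by an estimated per-point noise sd: a 7-frame
   moving-average smooth approximates the signal, the per-channel relative
   noise level is estimated from the smooth residuals, and σᵢⱼ = level ×
   max(smooth, 0.5 %). Unweighted least squares (`weighting="none"`)
   remains available but is markedly less efficient here: the large noisy
   dead values dominate the sum and the consumption rate v collapses onto a
   ridge with the per-well bystander rates (observed v estimates ranged
   over 0–2× truth on 24-well designs; the Fisher bound at the same design
   is 3–14 %).

2. **Anchored initial conditions with measurement error.** Initial
   abundances are estimated as the mean of the first three frames. That
   average approximates the trajectory at the middle frame, so fits anchor
   there (with a second-order curvature correction and backward integration
   for frame 0), and the known G₀ is advanced to the anchor time with the
   consumption ODE. The anchor itself is noisy (sd ≈ per-point sd/√3), so
   each well's (N₀, D₀) enters the fit as a bounded nuisance parameter with
   a prior residual tying it to the three-frame mean at that sd. Without
   this, the anchor error leaves a per-well misfit that only per-well rate
   parameters can absorb, inflating recovery error ~3× and systematically
   tilting model comparison toward the all-local scenario. Nuisance initial
   conditions are prior-penalized and not counted as free parameters.

3. **Model comparison on the weighted objective.** AICc
   (n ln RSS + 2p + 2p(p+1)/(n−p−1)) is computed on the minimized
   least-squares objective with one cohort-wide weight set shared by every
   candidate, n counting all live and dead residuals identically across
   candidates and p the scenario's free kinetic parameters (local: per-well
   parameters × wells, pooled; mixed: shared + one k_bys per well). On the
   plain RSS under heteroscedastic noise, per-well parameters harvest the
   high-variance dead values and the criterion drifts toward the
   parameter-richest scenario. Ties break toward smaller p, then
   declaration order.

## Training and validation

Each round splits the cohort 75/25 uniformly at random, runs the mixed
calibration on the training wells, fits the line's bystander law to the
training per-well estimates, and estimates measurement uncertainty as the
mean absolute fit–data deviation relative to the data mean (live and dead
separately). Validation wells are predicted by Monte Carlo (default 1,000
draws; fewer than 100 is refused): (k_p, k_d, v) from independent truncated
normals given the global estimates and CI half-widths, initial abundances
from the training uncertainty, k_bys by drawing the law's parameters from
their CIs and evaluating at the well's initial conditions; the band is the
pointwise 2.5/97.5 percentile envelope. How to combine parameter and
initial-condition uncertainty into one band is genuinely open; independent
truncated-normal draws are the simplest scheme consistent with a 95 %
envelope, and the propagation mechanism is isolated in `validate.predict`.
Prediction accuracy is the fraction of measured points inside the band.
Error metrics are signed: mean % error and its end-of-experiment value
(zero-denominator points excluded and counted), mean error and its
end-of-experiment value in confluence %, and an RSS convention of summed
squared error on fractional confluence per well, averaged over wells.

## Benchmark problem sizes

The self-validation experiments (`glucodyn.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) use reduced designs
chosen for identifiability per compute: 24-well recovery cohorts (glucose
panel 0.1/0.5/1/2/5/10 mM spanning depletion, starvation, and saturation;
low/high tiers; 2 replicates), recovered rates averaged over 3 replicate
cohorts (2 in the test suite) to control the small design's sampling
variance; a 12-well law-driven cohort for the 9-candidate selection grid;
and 200-replicate coverage studies on the weighted law fits. Multistart
depth in tests is reduced to 3–4 starts after verifying the winning optimum
is unchanged from 10 on these designs.

## Known limitations

* θ, G*, G_min, and cells_per_pct are assigned stand-ins; absolute values
  of v and k_bys,0 (surface) are only meaningful relative to the chosen
  conversion, and cross-study comparison requires harmonizing it.
* The noise model is i.i.d. multiplicative; real segmentation noise is
  time-correlated, which would shrink the effective information content and
  widen honest uncertainty relative to what these benchmarks show.
* Unweighted fitting reproduces the documented convention but is
  statistically inefficient under this noise; the GLS default departs from
  that convention deliberately (see above).
* The bystander laws are phenomenological; no mechanism (gap-junction
  coupling vs soluble factors) is modeled.
* Dead-cell confluence is treated as cumulative; lysis/detachment would
  break the mass-transfer invariant the model assumes.
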