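# glucodyn

Mechanistic modeling of tumor-cell growth under glucose limitation, for
quantitative cell biologists working with time-resolved live/dead confluence
microscopy (e.g. IncuCyte-style plate imaging).

When breast-cancer monolayers are switched to media with defined glucose,
their fate over the following days depends jointly on the initial glucose
concentration and the seeding density: well-fed sparse wells grow, starved
dense wells collapse, and accumulated dead cells accelerate the death of
their neighbors. `glucodyn` models this with three coupled ODEs for live
confluence N(t), dead confluence D(t), and glucose G(t):

```
dN/dt = k_p N (1 - N/θ) S_p(G,t) - k_d N S_d(G,t) - k_bys N D/(D+N)
dD/dt =                            k_d N S_d(G,t) + k_bys N D/(D+N)
dG/dt = -v c N G/(G + G*)
S_d(G,t) = (1 - G/(G + G_min)) tanh(t),   S_p + S_d = 1
```

with proliferation rate k_p, starvation death rate k_d, bystander death
rate k_bys, per-cell glucose consumption v, carrying capacity θ, and the
fate state functions S_p/S_d partitioning growth against starvation death
(delayed by tanh(t) while cells still respond to the pre-change medium).

The package provides, as composable library modules:

* `model` — the three-variant ODE family (no-bystander / complete /
  no-starvation), forward simulation, per-term contribution decomposition;
* `synth` — a synthetic cohort generator emulating the plate design
  (10 glucose levels × 3 seeding tiers × 4 replicates, 33 frames / 4 days)
  with realistic multiplicative noise — the test bed for everything else;
* `calibrate` — multistart bounded least squares under three
  parameter-sharing scenarios (local / global / mixed), GLS residual
  weighting, measurement-error initial conditions, linearized 95% CIs;
* `selection` — small-sample AICc over the variant × scenario grid;
* `bystander` — partial correlations of per-well k_bys with initial
  conditions and the two empirical laws
  k_bys = k_bys,0·N₀·exp(−αG₀) (surface) and
  k_bys = k_bys,0·exp(−αG₀)+β (curve);
* `validate` — repeated 75/25 train/validate rounds with Monte-Carlo
  prediction bands, accuracy, and signed error metrics;
* `benchmarks` — canned parameter-recovery and model-selection experiments;
* a `glucodyn` CLI (`generate`, `simulate`, `calibrate`, `select-model`,
  `fit-bystander`, `validate`, `report`) over YAML configs.

See `docs/methods.md` for the model assumptions, units (including the
cell ↔ confluence-percent conversion), noise model, and the statistical
choices behind calibration and model comparison.

## Worked example

Generate a noisy 24-well recovery cohort for the fast-growing mesenchymal
profile, calibrate the complete model with shared rates plus per-well
bystander rates, and inspect the recovered parameters:

```python
from glucodyn import (CalibrationConfig, fit_mixed, generate_cohort,
                      mda_mb_231_like_profile)
from glucodyn.benchmarks import reduced_design

profile = mda_mb_231_like_profile()     # k_p=0.14, k_d=0.041, v=4.48e-5
cohort = generate_cohort(profile, reduced_design(profile), seed=7)

fit = fit_mixed(cohort, variant=2, config=CalibrationConfig(n_starts=4, seed=1))
for name, est in fit.shared.estimates.items():
    print(f"{name}: {est:.4g} +/- {fit.shared.ci95[name]:.2g}")
print(fit.k_bys_table().head(3).to_string(index=False))
```

prints

```
k_p: 0.1439 +/- 0.0092
k_d: 0.03461 +/- 0.0055
v: 4.687e-05 +/- 3.3e-06
                   well_id    k_bys     ci95
MDA-MB-231-like_G0.1_T1_R1 0.914123 0.048344
MDA-MB-231-like_G0.1_T1_R2 0.906898 0.049030
MDA-MB-231-like_G0.1_T2_R1 0.944672 0.059922
```

k_p and v land within a few percent of the generating values (0.14 and
4.48×10⁻⁵); k_d comes back ~16% low on this particular 24-well draw, which
is why the recovery benchmarks average several replicate cohorts. The
per-well bystander rates in the starved 0.1 mM wells sit near the
generating law's value there (0.71·e^(−0.098) + 0.22 ≈ 0.86 day⁻¹) — the
structure the bystander laws then condense into two or three parameters.

The same pipeline from the shell:

```
glucodyn generate --config config/example.yaml --seed 7
glucodyn select-model --config config/example.yaml \
    --cohort runs/cohort_BT-474-like.csv
glucodyn validate --config config/example.yaml --auto-train --rounds 5
```

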