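"""Synthetic recovery benchmarks: canned experiments that generate data from
the built-in cell-line profiles and measure how well the pipeline recovers
the generating quantities.

These are the package's self-validation protocols:

* ``recovery_experiment`` -- reduced-cohort mixed calibration; reports the
  recovered shared rates averaged over a few replicate cohorts (averaging
  controls the sampling variance of the small design).
* ``law_recovery_surface`` / ``law_recovery_curve`` -- refit the bystander
  laws from noisy samples of themselves.
* ``selection_experiment`` -- AICc selection over the full variant/scenario
  grid on a reduced law-driven cohort.

The reduced design uses 6 glucose levels spanning the full experimental
range (depleting mid-levels time-stamp consumption, the near-zero level
isolates starvation death, 10 mM pins proliferation), the low and high
confluence tiers, and 2 replicates: 24 wells, 33 time points each.
"""

from __future__ import annotations

import numpy as np

from .bystander import fit_curve, fit_surface
from .calibrate import CalibrationConfig, fit_mixed
from .selection import DEFAULT_CANDIDATES, select_model
from .synth import (
    CellLineProfile,
    CohortDesign,
    bt474_like_profile,
    generate_cohort,
    generate_law_samples,
    mda_mb_231_like_profile,
)

__all__ = [
    "REDUCED_GLUCOSE_PANEL_MM",
    "reduced_design",
    "recovery_experiment",
    "law_recovery_surface",
    "law_recovery_curve",
    "selection_experiment",
    "state_function_checks",
]

REDUCED_GLUCOSE_PANEL_MM = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)


def _child_seeds(seed: int, n: int) -> list:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31 - 1) for s in state]


def reduced_design(profile: CellLineProfile) -> CohortDesign:
    """24-well recovery design: 6 glucose levels x low/high tier x 2 reps.

    Per-well bystander rates come exactly from the profile's law (no
    well-to-well jitter): the experiment probes the estimator, not the
    biological dispersion the default generator adds on top.
    """
    return CohortDesign(
        glucose_levels_mm=REDUCED_GLUCOSE_PANEL_MM,
        tiers_pct=(profile.tiers_pct[0], profile.tiers_pct[2]),
        replicates=2,
        n0_jitter_sd_pct=0.0,
        d0_jitter_sd_pct=0.0,
        k_bys_lognorm_sigma=0.0,
    )


def recovery_experiment(
    profile: CellLineProfile,
    seed: int = 0,
    n_cohorts: int = 3,
    n_starts: int = 10,
) -> dict:
    """Generate replicate reduced cohorts and recover the shared rates.

    Returns the across-cohort mean of each shared estimate, the generating
    truth, and the total number of wells fitted.
    """
    design = reduced_design(profile)
    seeds = _child_seeds(seed, 2 * n_cohorts)
    estimates = {"k_p": [], "k_d": [], "v": []}
    wells = 0
    for i in range(n_cohorts):
        cohort = generate_cohort(profile, design, seed=seeds[2 * i])
        config = CalibrationConfig(n_starts=n_starts, seed=seeds[2 * i + 1])
        fit = fit_mixed(cohort, 2, config)
        for k in estimates:
            estimates[k].append(fit.shared.estimates[k])
        wells += len(cohort)
    mean = {k: float(np.mean(v)) for k, v in estimates.items()}
    truth = {
        "k_p": profile.globals_.k_p,
        "k_d": profile.globals_.k_d,
        "v": profile.globals_.v,
    }
    return {"estimates": mean, "per_cohort": estimates, "truth": truth,
            "n_wells": wells}


def law_recovery_surface(seed: int = 0, noise_rel: float = 0.10):
    """Refit the confluence-dependent bystander surface from noisy samples.

    Samples the built-in surface law on the 8 sub-saturating glucose levels
    x 3 confluence tiers, perturbs them with relative Gaussian noise, and
    refits by inverse-variance-weighted least squares.
    """
    law = bt474_like_profile().bystander_law
    conds = [(n, g) for g in (0.0, 0.1, 0.2, 0.5, 0.8, 1.0, 2.0, 5.0)
             for n in (24.0, 36.0, 52.0)]
    n0, g0, k, ci = generate_law_samples(law, conds, noise_sd=noise_rel,
                                         seed=seed, relative=True)
    fitted = fit_surface(n0, g0, k, ci)
    return fitted, law, len(conds)


def law_recovery_curve(seed: int = 0, noise_rel: float = 0.10,
                       samples_per_level: int = 12):
    """Refit the confluence-independent bystander curve from noisy samples
    at the 10 experimental glucose levels."""
    law = mda_mb_231_like_profile().bystander_law
    conds = [(0.0, g) for g in (0.0, 0.1, 0.2, 0.5, 0.8, 1.0, 2.0, 5.0, 8.0, 10.0)
             for _ in range(samples_per_level)]
    n0, g0, k, ci = generate_law_samples(law, conds, noise_sd=noise_rel,
                                         seed=seed, relative=True)
    fitted = fit_curve(g0, k, ci)
    return fitted, law, len(conds)


def selection_experiment(seed: int = 0, n_starts: int = 3,
                         glucose_levels_mm=(0.1, 0.5, 2.0, 10.0)):
    """AICc selection on a reduced law-driven cohort (complete-model truth).

    Default 12 wells: 4 glucose levels x 3 confluence tiers x 1 replicate,
    per-well bystander rates from the surface law (with the generator's
    default lognormal dispersion), full 9-candidate grid.
    """
    profile = bt474_like_profile()
    design = CohortDesign(
        glucose_levels_mm=glucose_levels_mm,
        tiers_pct=profile.tiers_pct,
        replicates=1,
    )
    s1, s2 = _child_seeds(seed, 2)
    cohort = generate_cohort(profile, design, seed=s1)
    config = CalibrationConfig(n_starts=n_starts, seed=s2)
    table = select_model(cohort, DEFAULT_CANDIDATES, config)
    winner = table[table["selected"]].iloc[0]
    return table, (int(winner["variant"]), str(winner["scenario"]))


def state_function_checks(seed: int = 0, n: int = 1000):
    """Analytic identities of the fate state functions on random inputs.

    Returns (max of S_p + S_d over random (G, t, G_min), max |S_d at t=0|
    over representative glucose levels).
    """
    from .model import state_death, state_prolif

    rng = np.random.default_rng(seed)
    g = rng.uniform(0.0, 10.0, n)
    t = rng.uniform(0.0, 4.0, n)
    g_min = float(rng.uniform(0.01, 1.0))
    sums = state_prolif(g, t, g_min) + state_death(g, t, g_min)
    at_zero = np.array([state_death(gg, 0.0, g_min) for gg in (0.0, 0.1, 1.0, 10.0)])
    return float(np.max(sums)), float(np.max(np.abs(at_zero)))
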