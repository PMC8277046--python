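import numpy as np
import pytest

from glucodyn import (
    CalibrationConfig,
    CellLineProfile,
    CohortDesign,
    bt474_like_profile,
    generate_cohort,
    mda_mb_231_like_profile,
)


@pytest.fixture(scope="session")
def bt_profile():
    return bt474_like_profile()


@pytest.fixture(scope="session")
def mda_profile():
    return mda_mb_231_like_profile()


def quiet_profile(profile, level=1e-9):
    """Copy of a profile with (effectively) noise-free series."""
    return CellLineProfile(
        name=profile.name,
        globals_=profile.globals_,
        bystander_law=profile.bystander_law,
        noise_live_pct=level,
        noise_dead_pct=level,
        tiers_pct=profile.tiers_pct,
        n0_in_cells=profile.n0_in_cells,
    )


@pytest.fixture(scope="session")
def tiny_design():
    """Small deterministic design: 3 glucose levels x 2 tiers x 1 replicate."""
    return CohortDesign(
        glucose_levels_mm=(0.2, 1.0, 5.0),
        tiers_pct=(24.0, 52.0),
        replicates=1,
        n0_jitter_sd_pct=0.0,
        d0_jitter_sd_pct=0.0,
        k_bys_lognorm_sigma=0.0,
    )


@pytest.fixture(scope="session")
def bt_cohort_noisefree(bt_profile, tiny_design):
    return generate_cohort(quiet_profile(bt_profile), tiny_design, seed=101)


@pytest.fixture(scope="session")
def bt_cohort_noisy(bt_profile, tiny_design):
    return generate_cohort(bt_profile, tiny_design, seed=101)


@pytest.fixture(scope="session")
def fast_config():
    return CalibrationConfig(n_starts=3, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2021)
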