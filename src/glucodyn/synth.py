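"""Synthetic live/dead confluence cohorts emulating the time-resolved
microscopy study design.

A cohort is a plate of wells: 10 initial glucose levels x 3 initial-confluence
tiers x 4 replicates (120 wells), each observed every 3 hours for 4 days
(33 time points).  For each well the generator draws a bystander death rate
from the cell line's law at that well's initial conditions, simulates the
complete model, and corrupts the live and dead series with multiplicative
Gaussian noise at the line's empirical uncertainty levels.  Glucose is never
observed, matching the experiment.

Two built-in cell-line profiles mimic a HER2+ mass-forming line (BT-474-like:
slower growth, strong starvation death, confluence-dependent bystander
surface) and a triple-negative mesenchymal line (MDA-MB-231-like: faster
growth and consumption, confluence-independent bystander curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bystander import BystanderLaw, evaluate_law
from .model import KineticParameters, SystemState, default_grid, simulate

__all__ = [
    "GLUCOSE_LEVELS_MM",
    "CellLineProfile",
    "TimeCoursePair",
    "Cohort",
    "CohortDesign",
    "bt474_like_profile",
    "mda_mb_231_like_profile",
    "generate_cohort",
    "generate_law_samples",
]

#: Initial glucose concentrations of the experimental design, mM.
GLUCOSE_LEVELS_MM = (0.0, 0.1, 0.2, 0.5, 0.8, 1.0, 2.0, 5.0, 8.0, 10.0)

#: Initial-confluence tier anchors (%), low/intermediate/high.
BT474_TIERS_PCT = (23.8, 35.9, 51.7)
MDA_MB_231_TIERS_PCT = (36.9, 56.2, 71.9)


@dataclass(frozen=True)
class CellLineProfile:
    """Generating truth for one cell line.

    ``globals_`` carries the shared rates (its k_bys field is a placeholder;
    per-well rates come from ``bystander_law``).  Noise levels are relative
    (percent of signal) for the live and dead series.  ``n0_in_cells`` says
    whether the law's N0 argument is a cell count (converted from confluence
    with ``globals_.cells_per_pct``) or a plain confluence percent.
    """

    name: str
    globals_: KineticParameters
    bystander_law: BystanderLaw
    noise_live_pct: float
    noise_dead_pct: float
    tiers_pct: tuple = BT474_TIERS_PCT
    n0_in_cells: bool = True

    def __post_init__(self) -> None:
        if self.noise_live_pct <= 0 or self.noise_dead_pct <= 0:
            raise ValueError("noise levels must be > 0")

    def k_bys_at(self, n0_pct: float, g0_mm: float) -> float:
        n0 = n0_pct * self.globals_.cells_per_pct if self.n0_in_cells else n0_pct
        return float(evaluate_law(self.bystander_law, n0=n0, g0=g0_mm))


def bt474_like_profile() -> CellLineProfile:
    """Slow-growing, cluster-forming line: confluence-dependent bystander surface."""
    return CellLineProfile(
        name="BT-474-like",
        globals_=KineticParameters(k_p=0.092, k_d=0.13, k_bys=0.0, v=2.68e-5),
        bystander_law=BystanderLaw(form="surface", k_bys0=2.37e-5, alpha=0.13),
        noise_live_pct=6.88,
        noise_dead_pct=30.83,
        tiers_pct=BT474_TIERS_PCT,
        n0_in_cells=True,
    )


def mda_mb_231_like_profile() -> CellLineProfile:
    """Fast-growing mesenchymal line: confluence-independent bystander curve."""
    return CellLineProfile(
        name="MDA-MB-231-like",
        globals_=KineticParameters(k_p=0.14, k_d=0.041, k_bys=0.0, v=4.48e-5),
        bystander_law=BystanderLaw(form="curve", k_bys0=0.71, alpha=0.98, beta=0.22),
        noise_live_pct=5.17,
        noise_dead_pct=16.78,
        tiers_pct=MDA_MB_231_TIERS_PCT,
        n0_in_cells=False,
    )


@dataclass
class TimeCoursePair:
    """One well's paired live and dead confluence series with its metadata."""

    well_id: str
    n0_pct: float
    g0_mm: float
    times: np.ndarray
    live: np.ndarray
    dead: np.ndarray
    replicate: int = 1
    k_bys_true: float | None = None
    d0_pct: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.live = np.asarray(self.live, dtype=float)
        self.dead = np.asarray(self.dead, dtype=float)
        if not (len(self.times) == len(self.live) == len(self.dead)):
            raise ValueError(f"well {self.well_id}: series lengths differ")
        if np.any(self.live < 0) or np.any(self.dead < 0):
            raise ValueError(f"well {self.well_id}: negative confluence")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"well {self.well_id}: times not strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Cohort:
    """All wells of one cell line."""

    cell_line: str
    pairs: list

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("a cohort must contain at least one well")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort(cell_line=self.cell_line, pairs=[self.pairs[i] for i in indices])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                pd.DataFrame(
                    {
                        "well_id": p.well_id,
                        "replicate": p.replicate,
                        "n0_pct": p.n0_pct,
                        "g0_mM": p.g0_mm,
                        "time_days": p.times,
                        "live_pct": p.live,
                        "dead_pct": p.dead,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class CohortDesign:
    """Experimental design of a generated cohort."""

    glucose_levels_mm: tuple = GLUCOSE_LEVELS_MM
    tiers_pct: tuple | None = None  # default: the profile's tiers
    replicates: int = 4
    grid: tuple | None = None  # default: 33 points, every 3 h over 4 days
    n0_jitter_sd_pct: float = 0.5
    d0_pct: float = 0.5
    d0_jitter_sd_pct: float = 0.05
    k_bys_lognorm_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.glucose_levels_mm:
            raise ValueError("design with zero wells: no glucose levels")


def generate_cohort(
    profile: CellLineProfile,
    design: CohortDesign | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate one noisy cohort under a profile and design; fully seeded.

    For each well: N0 ~ Normal(tier, jitter), D0 ~ Normal(d0, jitter)
    truncated at 0; k_bys = law(N0, G0) with lognormal jitter; the complete
    model (variant 2) is simulated; i.i.d. multiplicative Gaussian noise at
    the profile's live/dead levels is applied and truncated at 0.
    """
    design = design or CohortDesign()
    tiers = design.tiers_pct if design.tiers_pct is not None else profile.tiers_pct
    if not tiers:
        raise ValueError("design with zero wells: no confluence tiers")
    grid = np.asarray(design.grid, dtype=float) if design.grid is not None else default_grid()
    rng = np.random.default_rng(seed)
    pairs = []
    for g0 in design.glucose_levels_mm:
        for tier_idx, tier in enumerate(tiers):
            for rep in range(1, design.replicates + 1):
                n0 = max(float(rng.normal(tier, design.n0_jitter_sd_pct)), 0.1)
                d0 = max(float(rng.normal(design.d0_pct, design.d0_jitter_sd_pct)), 0.0)
                k_bys = profile.k_bys_at(n0, g0)
                if design.k_bys_lognorm_sigma > 0 and k_bys > 0:
                    k_bys *= float(
                        np.exp(rng.normal(0.0, design.k_bys_lognorm_sigma))
                    )
                params = replace(profile.globals_, k_bys=k_bys)
                traj = simulate(
                    SystemState(n_live=n0, n_dead=d0, glucose=g0, time=grid[0]),
                    params,
                    variant=2,
                    grid=grid,
                )
                live = traj.live * (
                    1.0 + rng.normal(0.0, profile.noise_live_pct / 100.0, size=len(grid))
                )
                dead = traj.dead * (
                    1.0 + rng.normal(0.0, profile.noise_dead_pct / 100.0, size=len(grid))
                )
                pairs.append(
                    TimeCoursePair(
                        well_id=f"{profile.name}_G{g0:g}_T{tier_idx + 1}_R{rep}",
                        n0_pct=n0,
                        g0_mm=g0,
                        times=grid,
                        live=np.maximum(live, 0.0),
                        dead=np.maximum(dead, 0.0),
                        replicate=rep,
                        k_bys_true=k_bys,
                        d0_pct=d0,
                    )
                )
    return Cohort(cell_line=profile.name, pairs=pairs)


def generate_law_samples(
    law: BystanderLaw,
    initial_conditions: Sequence,
    noise_sd: float = 0.0,
    seed: int = 0,
    relative: bool = False,
):
    """Noisy k_bys samples from a law on a list of (N0, G0) conditions.

    Returns (n0, g0, k_bys, ci) arrays, where each sample is
    law(N0, G0) + Gaussian noise truncated at 0 and ci is a synthetic 95% CI
    half-width of 1.96 * sd.  With ``relative=True`` the noise sd (and CI)
    scale with the noise-free value -- the multiplicative-noise regime used
    when emulating per-well calibration scatter.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conditions = list(initial_conditions)
    if not conditions:
        raise ValueError("empty condition list")
    rng = np.random.default_rng(seed)
    n0 = np.array([c[0] for c in conditions], dtype=float)
    g0 = np.array([c[1] for c in conditions], dtype=float)
    truth = evaluate_law(law, n0=n0 if law.form == "surface" else None, g0=g0)
    truth = np.atleast_1d(np.asarray(truth, dtype=float))
    sd = noise_sd * truth if relative else np.full_like(truth, noise_sd)
    samples = np.maximum(truth + rng.normal(0.0, 1.0, size=truth.shape) * sd, 0.0)
    ci = 1.96 * sd
    return n0, g0, samples, ci
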