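"""Readers, writers, and run configuration binding the pipeline together.

Cohorts travel as long-format CSV (one row per well and time point); run
configuration is YAML with every default explicit, and each artifact written
by the CLI embeds the seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Cohort, CohortDesign, TimeCoursePair, GLUCOSE_LEVELS_MM

__all__ = ["COHORT_COLUMNS", "CohortSchemaError", "read_cohort", "write_cohort",
           "RunConfig", "config_hash", "write_manifest"]

COHORT_COLUMNS = ("well_id", "replicate", "n0_pct", "g0_mM", "time_days",
                  "live_pct", "dead_pct")


class CohortSchemaError(ValueError):
    """Malformed cohort file; message cites the offending well/rows."""


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path, cell_line: str | None = None) -> Cohort:
    """Read a long-format cohort CSV, validating the schema.

    Raises :class:`CohortSchemaError` naming the offending column, well, and
    row numbers on missing columns, negative confluences, or non-monotone
    times within a well.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("live_pct", "dead_pct"):
        bad = df.index[df[col] < 0]
        if len(bad):
            row = int(bad[0])
            raise CohortSchemaError(
                f"{path}: negative {col} at row {row + 2} "
                f"(well {df.loc[row, 'well_id']})"
            )
    pairs = []
    for well_id, g in df.groupby("well_id", sort=False):
        times = g["time_days"].to_numpy(dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise CohortSchemaError(
                f"{path}: non-monotone time_days within well {well_id}"
            )
        pairs.append(
            TimeCoursePair(
                well_id=str(well_id),
                n0_pct=float(g["n0_pct"].iloc[0]),
                g0_mm=float(g["g0_mM"].iloc[0]),
                times=times,
                live=g["live_pct"].to_numpy(dtype=float),
                dead=g["dead_pct"].to_numpy(dtype=float),
                replicate=int(g["replicate"].iloc[0]),
            )
        )
    if cell_line is None:
        cell_line = Path(path).stem
    return Cohort(cell_line=cell_line, pairs=pairs)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    cell_line: str = "BT-474-like"
    # fixed model constants
    theta: float = 100.0
    g_star: float = 1.0
    g_min: float = 0.1
    cells_per_pct: float = 800.0
    # design
    glucose_levels_mm: tuple = GLUCOSE_LEVELS_MM
    tiers_pct: tuple | None = None
    replicates: int = 4
    # calibration
    n_starts: int = 10
    weighting: str = "gls"
    # validation
    n_rounds: int = 50
    fraction: float = 0.75
    n_draws: int = 1000
    # seeds
    seed: int = 0
    # output
    out_dir: str = "runs"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["glucose_levels_mm"] = list(self.glucose_levels_mm)
        d["tiers_pct"] = list(self.tiers_pct) if self.tiers_pct is not None else None
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "glucose_levels_mm" in raw:
            raw["glucose_levels_mm"] = tuple(raw["glucose_levels_mm"])
        if raw.get("tiers_pct") is not None:
            raw["tiers_pct"] = tuple(raw["tiers_pct"])
        return cls(**raw)

    def design(self) -> CohortDesign:
        return CohortDesign(
            glucose_levels_mm=self.glucose_levels_mm,
            tiers_pct=self.tiers_pct,
            replicates=self.replicates,
        )


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(path, config: RunConfig, seed: int, extra: dict | None = None) -> None:
    """JSON manifest recording provenance next to each artifact."""
    payload = {"config_hash": config_hash(config), "seed": seed,
               "config": config.as_dict()}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
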