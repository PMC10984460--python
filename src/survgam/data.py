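"""Survey data containers.

A :class:`SurveyDataset` holds one row per trawl tow — location (planar km
and lon/lat), year, depth, bottom temperature, swept area, occurrence and
biomass — plus the depth-stratum table used by the design-based index and
the projection that links lon/lat to planar km.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import LocalProjection

#: required columns of the tow table
TOW_COLUMNS = [
    "tow_id",
    "x",
    "y",
    "lon",
    "lat",
    "year",
    "depth_m",
    "temp_c",
    "swept_km2",
    "z",
    "biomass_kg",
    "stratum",
]

STRATA_COLUMNS = ["stratum", "depth_min_m", "depth_max_m", "area_km2"]


class ValidationError(ValueError):
    """Aggregated row-level validation failures."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        msg = "\n  ".join(problems[:20])
        extra = "" if len(problems) <= 20 else f"\n  ... and {len(problems) - 20} more"
        super().__init__(f"survey table validation failed:\n  {msg}{extra}")


@dataclass
class SurveyDataset:
    """Tow-level survey observations with strata and projection metadata."""

    tows: pd.DataFrame
    strata: pd.DataFrame
    projection: LocalProjection

    def __post_init__(self):
        self.validate()

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.tows["year"].unique())

    @property
    def n(self) -> int:
        return len(self.tows)

    def validate(self) -> None:
        problems: list[str] = []
        missing = [c for c in TOW_COLUMNS if c not in self.tows.columns]
        if missing:
            raise ValidationError([f"missing column(s): {missing}"])
        t = self.tows
        for idx in t.index[~(np.isclose(t["biomass_kg"], 0.0) == (t["z"] == 0))]:
            problems.append(
                f"row {idx}: occurrence/biomass mismatch "
                f"(z={t.at[idx, 'z']}, biomass={t.at[idx, 'biomass_kg']})"
            )
        for idx in t.index[t["swept_km2"] <= 0]:
            problems.append(f"row {idx}: swept_km2 must be > 0")
        for idx in t.index[t["depth_m"] <= 0]:
            problems.append(f"row {idx}: depth_m must be > 0")
        for idx in t.index[t["biomass_kg"] < 0]:
            problems.append(f"row {idx}: biomass_kg must be >= 0")
        if not self.strata.empty:
            smissing = [c for c in STRATA_COLUMNS if c not in self.strata.columns]
            if smissing:
                problems.append(f"strata table missing column(s): {smissing}")
            elif (self.strata["area_km2"] <= 0).any():
                problems.append("strata areas must be > 0")
        if problems:
            raise ValidationError(problems)

    def subset(self, mask) -> "SurveyDataset":
        return SurveyDataset(
            tows=self.tows[mask].reset_index(drop=True),
            strata=self.strata,
            projection=self.projection,
        )

    def positive(self) -> "SurveyDataset":
        """Rows with strictly positive biomass (the Gamma sub-model's data)."""
        return self.subset(self.tows["biomass_kg"] > 0)
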