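"""Plain-text file formats and pipeline configuration.

All tables are comma-delimited text with documented headers; the projection
reference is carried in ``# key=value`` comment lines so a survey table
round-trips without side files.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import STRATA_COLUMNS, TOW_COLUMNS, SurveyDataset, ValidationError
from .geo import LocalProjection


def write_survey(dataset: SurveyDataset, tows_path, strata_path) -> None:
    """Write the tow table (with projection header) and the strata table."""
    tows_path = Path(tows_path)
    with open(tows_path, "w") as fh:
        fh.write(f"# lon0={dataset.projection.lon0} lat0={dataset.projection.lat0}\n")
        dataset.tows[TOW_COLUMNS].to_csv(fh, index=False)
    dataset.strata[STRATA_COLUMNS].to_csv(strata_path, index=False)


def read_survey_table(tows_path, strata_path=None) -> SurveyDataset:
    """Read a survey table, enforcing the dataset invariants.

    Row-level problems (Y/Z mismatch, non-positive swept area or depth,
    non-numeric fields) are collected and raised together as a single
    :class:`ValidationError`.
    """
    tows_path = Path(tows_path)
    header = {}
    with open(tows_path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header[k] = float(v)
        else:
            break
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    try:
        tows = pd.read_csv(_io.StringIO(body))
    except Exception as exc:
        raise ValidationError([f"cannot parse {tows_path}: {exc}"]) from exc
    problems = []
    missing = [c for c in TOW_COLUMNS if c not in tows.columns]
    if missing:
        raise ValidationError([f"missing column(s): {missing}"])
    for col in ("x", "y", "lon", "lat", "depth_m", "temp_c", "swept_km2", "biomass_kg"):
        coerced = pd.to_numeric(tows[col], errors="coerce")
        for idx in tows.index[coerced.isna() & tows[col].notna()]:
            problems.append(f"row {idx}: non-numeric {col} = {tows.at[idx, col]!r}")
        tows[col] = coerced
    if problems:
        raise ValidationError(problems)
    proj = LocalProjection(header.get("lon0", 0.0), header.get("lat0", 0.0))
    if strata_path is not None:
        strata = pd.read_csv(strata_path)
    else:
        strata = pd.DataFrame(columns=STRATA_COLUMNS)
    return SurveyDataset(tows=tows, strata=strata, projection=proj)


def write_grid(grid_df: pd.DataFrame, path) -> None:
    grid_df.to_csv(path, index=False)


def read_grid(path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_precision_triplets(q, path) -> None:
    """Write a sparse precision in coordinate (row, col, value) text form."""
    coo = q.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# sparse symmetric precision {coo.shape[0]}x{coo.shape[1]}\n")
        fh.write("row,col,value\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r},{c},{v:.17g}\n")


# ---------------------------------------------------------------------------
# pipeline configuration


_CONFIG_KEYS = {
    "survey": str,
    "strata": str,
    "grid": str,
    "outdir": str,
    "formulas": list,
    "formula": str,
    "mesh_cutoff_km": float,
    "hull_buffer_km": float,
    "n_knots": int,
    "k_folds": int,
    "seed": int,
    "sim_seed": int,
    "survey_seed": int,
    "catchability": float,
    "n_draws": int,
    "ref_swept_km2": float,
    "n_per_year": int,
    "n_years": int,
    "extent_km": float,
    "grid_res_km": float,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML file + CLI overrides)."""

    values: dict = field(default_factory=dict)

    DEFAULTS = {
        "outdir": "survgam_out",
        "formula": "year + temp + depth + spatial + AR1",
        "formulas": [
            "year + temp + depth + spatial + AR1",
            "year + temp + depth + spatial + RW",
            "year + temp + depth + spatial + iid",
            "year + depth + spatial + iid",
            "year + spatial + iid",
        ],
        "mesh_cutoff_km": 20.0,
        "n_knots": 8,
        "k_folds": 4,
        "seed": 1,
        "catchability": 1.0,
        "n_draws": 500,
        "ref_swept_km2": 0.025,
        "n_per_year": 150,
        "n_years": 10,
        "extent_km": 300.0,
        "grid_res_km": 5.0,
    }

    @classmethod
    def load(cls, path=None, **overrides) -> "PipelineConfig":
        values = dict(cls.DEFAULTS)
        if path is not None:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
            unknown = set(raw) - set(_CONFIG_KEYS)
            if unknown:
                raise ValueError(f"unknown config key(s): {sorted(unknown)}")
            values.update(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(values=values)

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)


def write_manifest(path, **entries) -> None:
    """Machine-readable record of a pipeline stage (inputs, seeds, results)."""
    import survgam

    entries.setdefault("survgam_version", survgam.__version__)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
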