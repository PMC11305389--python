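"""CSV/JSON interchange for cohorts, geometries and results.

All length-like columns are micron-denominated and carry a ``_um`` (or
``_um3``) suffix; readers validate the schema and reject tables that do not
declare these units in their headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import SpineGeometry

GEOMETRY_COLUMNS = ["case_id", "region", "neuron_id", "segment_id",
                    "spine_id", "point_index", "x_um", "y_um", "z_um",
                    "diameter_um", "voxel_count", "voxel_x_um", "voxel_y_um",
                    "voxel_z_um"]
SEGMENT_COLUMNS = ["case_id", "region", "neuron_id", "segment_id",
                   "length_um", "n_spines"]
MEASURED_COLUMNS = ["case_id", "region", "neuron_id", "segment_id",
                    "spine_id", "length_um", "head_diameter_um",
                    "neck_diameter_um", "volume_um3"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} is missing required micron-unit columns: {missing}")


def write_geometry_csv(geometries: list[dict], path) -> None:
    """Long per-backbone-point geometry table."""
    rows = []
    for rec in geometries:
        g: SpineGeometry = rec["geometry"]
        for k, (pt, d) in enumerate(zip(g.backbone, g.diameter_profile)):
            rows.append((rec["case_id"], rec["region"], rec["neuron_id"],
                         rec["segment_id"], rec["spine_id"], k,
                         pt[0], pt[1], pt[2], d, g.voxel_count,
                         *g.voxel_dims))
    pd.DataFrame(rows, columns=GEOMETRY_COLUMNS).to_csv(path, index=False)


def read_geometry_csv(path) -> list[dict]:
    df = pd.read_csv(path)
    _require(df, GEOMETRY_COLUMNS, "geometry CSV")
    out = []
    keys = ["case_id", "region", "neuron_id", "segment_id", "spine_id"]
    for key, sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("point_index")
        g = SpineGeometry(
            backbone=sub[["x_um", "y_um", "z_um"]].to_numpy(float),
            diameter_profile=sub["diameter_um"].to_numpy(float),
            voxel_count=int(sub["voxel_count"].iloc[0]),
            voxel_dims=tuple(sub[["voxel_x_um", "voxel_y_um",
                                  "voxel_z_um"]].iloc[0]))
        out.append(dict(zip(keys, key), geometry=g))
    return out


def write_segments_csv(segments: pd.DataFrame, path) -> None:
    _require(segments, SEGMENT_COLUMNS[:5], "segment table")
    segments.to_csv(path, index=False)


def read_segments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SEGMENT_COLUMNS[:5], "segment CSV")
    return df


def write_cases_csv(cases: pd.DataFrame, path) -> None:
    cases.to_csv(path, index=False)


def read_cases_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["case_id"], "case CSV")
    return df


def read_measured_spines_csv(path) -> pd.DataFrame:
    """Pre-measured spine table (bypasses the geometry stage)."""
    df = pd.read_csv(path)
    _require(df, MEASURED_COLUMNS, "measured spine CSV")
    return df


def write_truth_json(truth: dict, path) -> None:
    out = {k: v for k, v in truth.items() if k != "per_case"}
    out["per_case"] = truth["per_case"].to_dict(orient="records")
    Path(path).write_text(json.dumps(out, indent=2))


def read_truth_json(path) -> dict:
    out = json.loads(Path(path).read_text())
    out["per_case"] = pd.DataFrame(out["per_case"])
    return out
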