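"""Per-case feature aggregation, complete-case filtering and the
discovery/validation split.

Aggregation maps the spine-level table to one row per (case, region):

* density (spines per 10 µm) is computed per segment and averaged over the
  case's segments — this weights every dendritic segment equally regardless
  of its length;
* morphology means (length, head diameter, volume) are pooled over all of
  the case-region's spines by default; a per-neuron two-stage mean is
  available via ``aggregation="per_neuron"``;
* the same quantities are produced per morphology class; a class absent
  from a case yields missing values for its means (excluded pairwise
  downstream), and a per-segment density of zero.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometry import SPINE_CLASSES, segment_density

log = logging.getLogger(__name__)

OVERALL_TRAITS = ("mean_density", "mean_length", "mean_head_diameter",
                  "mean_volume")

SPINE_COLS = {"length": "length_um", "head_diameter": "head_diameter_um",
              "volume": "volume_um3"}


def _means(sub: pd.DataFrame, aggregation: str) -> dict[str, float]:
    out = {}
    for trait, col in SPINE_COLS.items():
        if len(sub) == 0:
            out[f"mean_{trait}"] = np.nan
        elif aggregation == "per_neuron":
            out[f"mean_{trait}"] = float(
                sub.groupby("neuron_id")[col].mean().mean())
        else:
            out[f"mean_{trait}"] = float(sub[col].mean())
    return out


def aggregate_case(spines: pd.DataFrame, segments: pd.DataFrame,
                   case_id: str, region: str,
                   aggregation: str = "pooled") -> dict | None:
    """One FeatureTable row for a (case, region); None if it has no segments."""
    seg = segments[(segments.case_id == case_id) & (segments.region == region)]
    if len(seg) == 0:
        warnings.warn(f"case {case_id} region {region}: no segments, row omitted")
        return None
    sp = spines[(spines.case_id == case_id) & (spines.region == region)]
    counts = sp.groupby("segment_id").size()
    row: dict = dict(case_id=case_id, region=region,
                     n_neurons=seg.neuron_id.nunique(),
                     n_spines=int(len(sp)),
                     total_dendrite_um=float(seg.length_um.sum()))
    dens = [segment_density(int(counts.get(s, 0)), float(l))
            for s, l in zip(seg.segment_id, seg.length_um)]
    row["mean_density"] = float(np.mean(dens))
    row.update(_means(sp, aggregation))
    for cls in SPINE_CLASSES:
        sub = sp[sp.spine_class == cls]
        ccounts = sub.groupby("segment_id").size()
        cdens = [segment_density(int(ccounts.get(s, 0)), float(l))
                 for s, l in zip(seg.segment_id, seg.length_um)]
        row[f"{cls}_density"] = float(np.mean(cdens))
        row.update({f"{cls}_{k}": v for k, v in _means(sub, aggregation).items()})
    return row


def aggregate_features(spines: pd.DataFrame, segments: pd.DataFrame,
                       aggregation: str = "pooled") -> pd.DataFrame:
    """FeatureTable: one row per (case, region) present in the segment table.

    Vectorised equivalent of calling :func:`aggregate_case` per case-region
    (the tests assert the equivalence against that brute-force path).
    """
    if aggregation not in ("pooled", "per_neuron"):
        raise ValueError("aggregation must be 'pooled' or 'per_neuron'")
    key = ["case_id", "region"]
    seg_key = key + ["segment_id"]
    seg = segments.set_index(seg_key).sort_index()
    out = pd.DataFrame(index=seg.groupby(key).size().index)
    out["n_neurons"] = segments.groupby(key)["neuron_id"].nunique()
    counts = spines.groupby(seg_key).size().reindex(seg.index, fill_value=0)
    out["n_spines"] = counts.groupby(key).sum().astype(int)
    out["total_dendrite_um"] = seg.groupby(key)["length_um"].sum()
    dens = 10.0 * counts / seg["length_um"]
    out["mean_density"] = dens.groupby(key).mean()

    def _mean_block(sub: pd.DataFrame, prefix: str) -> None:
        for trait, col in SPINE_COLS.items():
            if aggregation == "per_neuron":
                m = (sub.groupby(key + ["neuron_id"])[col].mean()
                     .groupby(key).mean())
            else:
                m = sub.groupby(key)[col].mean()
            out[f"{prefix}mean_{trait}"] = m

    _mean_block(spines, "")
    for cls in SPINE_CLASSES:
        sub = spines[spines.spine_class == cls]
        ccounts = (sub.groupby(seg_key).size()
                   .reindex(seg.index, fill_value=0))
        out[f"{cls}_density"] = (10.0 * ccounts / seg["length_um"]) \
            .groupby(key).mean()
        _mean_block(sub, f"{cls}_")
    return out.reset_index()


def filter_complete_cases(cases: pd.DataFrame,
                          required: Sequence[str]) -> pd.DataFrame:
    """Drop rows with any missing value in the required columns."""
    missing_cols = [c for c in required if c not in cases.columns]
    if missing_cols:
        raise KeyError(f"required columns absent: {missing_cols}")
    mask = cases[list(required)].notna().all(axis=1)
    dropped = cases.loc[~mask, "case_id"].tolist() if "case_id" in cases else \
        cases.index[~mask].tolist()
    if dropped:
        log.info("removed %d cases with missing data: %s", len(dropped), dropped)
    if mask.sum() == 0:
        warnings.warn("all cases removed by complete-case filter")
    return cases.loc[mask].reset_index(drop=True)


def split_discovery_validation(cases: pd.DataFrame, seed: int
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random half split: discovery gets ceil(n/2) cases, validation the rest.

    Deterministic for a given seed; with the post-filter n = 125 this yields
    the 63/62 discovery/validation sizes.  Membership under *this* seed
    stream is the contract (the original analysis' R permutation stream is
    not portable).
    """
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 cases to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_disc = (n + 1) // 2
    disc = cases.iloc[np.sort(perm[:n_disc])].reset_index(drop=True)
    val = cases.iloc[np.sort(perm[n_disc:])].reset_index(drop=True)
    return disc, val


def analysis_table(features: pd.DataFrame, cases: pd.DataFrame,
                   region: str) -> pd.DataFrame:
    """Merge one region's feature rows with the case covariates."""
    feat = features[features.region == region].drop(columns=["region"])
    return cases.merge(feat, on="case_id", how="inner")
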