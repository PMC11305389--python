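"""Per-spine morphometry: measurement of reconstructed spine geometry and
classification into the four canonical morphology classes.

A spine is represented by its reconstructed backbone (an ordered polyline in
µm from the insertion point on the dendrite to the most distal point of the
head), a per-point diameter profile, and the voxel count of the reconstructed
spine object.  From these we derive:

* **length** — curvilinear backbone length (sum of consecutive point-to-point
  Euclidean distances);
* **head diameter** — breadth of the spine head at its widest cross-sectional
  point, taken as the maximum of the diameter profile distal to the profile
  minimum;
* **neck diameter** — the profile minimum strictly between insertion and tip;
* **volume** — voxel count × volume of a single voxel.

Classification uses the standard threshold set (head-to-neck ratio 1.1,
length-to-head ratio 2.5, mushroom head 0.35 µm, filopodium length 3.0 µm):

1. head/neck > 1.1 and head > 0.35 µm  → mushroom;
2. head/neck < 1.1 and (length/head > 2.5 or head < 0.35 µm)
   → filopodia if length > 3.0 µm, else thin;
3. anything else → stubby.

The published rules use strict inequalities on both sides of the 1.1 ratio,
so a spine sitting exactly on a threshold — or a wide-necked spine with a
small head — matches neither rule; such spines fall through to stubby and are
flagged ``residual`` rather than silently absorbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SPINE_CLASSES = ("thin", "stubby", "mushroom", "filopodia")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Classification thresholds; all strictly positive."""

    head_neck_ratio: float = 1.1
    length_head_ratio: float = 2.5
    mushroom_head: float = 0.35      # µm
    filopodium_length: float = 3.0   # µm

    def __post_init__(self) -> None:
        for name in ("head_neck_ratio", "length_head_ratio",
                     "mushroom_head", "filopodium_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_THRESHOLDS = ClassifierThresholds()


@dataclass
class SpineGeometry:
    """Raw reconstructed geometry of a single spine (all lengths in µm)."""

    backbone: np.ndarray          # (k, 3) points, insertion -> distal tip
    diameter_profile: np.ndarray  # (k,) per-point diameter
    voxel_count: int
    voxel_dims: tuple[float, float, float] = (0.1, 0.1, 0.1)

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.diameter_profile = np.asarray(self.diameter_profile, dtype=float)
        if self.backbone.ndim != 2 or self.backbone.shape[1] != 3:
            raise ValueError("backbone must be an (k, 3) array")
        if self.backbone.shape[0] < 2:
            raise ValueError("backbone needs at least 2 points")
        if self.diameter_profile.shape[0] != self.backbone.shape[0]:
            raise ValueError("diameter profile must match backbone length")
        if np.any(self.diameter_profile <= 0):
            raise ValueError("diameters must be positive")
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")


@dataclass
class SpineMeasure:
    """Derived per-spine measurements plus the assigned class."""

    length: float
    head_diameter: float
    neck_diameter: float
    volume: float
    spine_class: str = ""
    rule_flag: str = ""
    head_neck_ratio: float = field(init=False)
    length_head_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.head_neck_ratio = self.head_diameter / self.neck_diameter
        self.length_head_ratio = self.length / self.head_diameter


def spine_length(g: SpineGeometry) -> float:
    """Curvilinear backbone length: sum of consecutive Euclidean distances."""
    steps = g.backbone[1:] - g.backbone[:-1]
    return float(np.sqrt(np.einsum("ij,ij->i", steps, steps)).sum())


def head_and_neck(g: SpineGeometry) -> tuple[float, float, str]:
    """Split the diameter profile into neck and head.

    The neck diameter is the profile minimum strictly between insertion and
    tip; the head diameter is the profile maximum from that minimum outward.
    Profiles with fewer than three points, or whose true minimum sits at an
    endpoint (monotone-degenerate), fall back to the global max/min and are
    flagged ``degenerate``.

    Returns ``(head_diameter, neck_diameter, flag)``.
    """
    d = g.diameter_profile
    if d.shape[0] < 3:
        return float(d.max()), float(d.min()), "degenerate"
    k = 1 + int(np.argmin(d[1:-1]))
    if d[k] > min(d[0], d[-1]):
        # profile is monotone towards an endpoint; no interior neck exists
        return float(d.max()), float(d.min()), "degenerate"
    head = float(d[k:].max())
    neck = float(d[k])
    return head, neck, ""


def spine_volume(g: SpineGeometry) -> float:
    """Voxel count times the volume of one voxel (µm³)."""
    vx, vy, vz = g.voxel_dims
    if vx <= 0 or vy <= 0 or vz <= 0:
        raise ValueError("voxel dimensions must be positive")
    return g.voxel_count * vx * vy * vz


def classify(head: float, neck: float, length: float,
             thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
             ) -> tuple[str, str]:
    """Assign one of the four classes from (head, neck, length).

    Returns ``(class, flag)`` where flag is ``"residual"`` for spines the
    strict published rules leave unmatched (routed to stubby).
    """
    if head <= 0 or neck <= 0 or length <= 0:
        raise ValueError("head, neck and length must be positive")
    hnr = head / neck
    lhr = length / head
    if not (math.isfinite(hnr) and math.isfinite(lhr)):
        raise ValueError("non-finite classifier ratios")
    t = thresholds
    if hnr > t.head_neck_ratio and head > t.mushroom_head:
        return "mushroom", ""
    if hnr < t.head_neck_ratio and (lhr > t.length_head_ratio
                                    or head < t.mushroom_head):
        if length > t.filopodium_length:
            return "filopodia", ""
        return "thin", ""
    # natural stubby: hnr < 1.1, head >= 0.35, lhr <= 2.5.  Everything else
    # (hnr exactly at threshold, or hnr > 1.1 with a small head) is unmatched
    # by the strict rules and flagged.
    if hnr < t.head_neck_ratio:
        return "stubby", ""
    return "stubby", "residual"


def classify_spine(m: SpineMeasure,
                   thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                   ) -> SpineMeasure:
    """Classify a measured spine in place and return it."""
    m.spine_class, flag = classify(m.head_diameter, m.neck_diameter,
                                   m.length, thresholds)
    if flag:
        m.rule_flag = (m.rule_flag + "+" + flag) if m.rule_flag else flag
    return m


def measure_spine(g: SpineGeometry,
                  thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                  ) -> SpineMeasure:
    """Measure and classify a spine geometry."""
    head, neck, flag = head_and_neck(g)
    m = SpineMeasure(
        length=spine_length(g),
        head_diameter=head,
        neck_diameter=neck,
        volume=spine_volume(g),
        rule_flag=flag,
    )
    return classify_spine(m, thresholds)


def segment_density(spine_count: int, segment_length: float) -> float:
    """Spines per 10 µm of dendrite length."""
    if segment_length <= 0:
        raise ValueError("segment length must be positive")
    return 10.0 * spine_count / segment_length


def measure_geometries(records,
                       thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS):
    """Measure + classify a list of keyed geometry records into a table.

    ``records`` are dicts with case/region/neuron/segment/spine ids and a
    ``geometry`` entry; the result is the measured-and-classified spine
    table used by the aggregation stage.
    """
    import pandas as pd

    rows = []
    for rec in records:
        m = measure_spine(rec["geometry"], thresholds)
        rows.append((rec["case_id"], rec["region"], rec["neuron_id"],
                     rec["segment_id"], rec["spine_id"], m.length,
                     m.head_diameter, m.neck_diameter, m.volume,
                     m.spine_class, m.rule_flag))
    return pd.DataFrame(rows, columns=[
        "case_id", "region", "neuron_id", "segment_id", "spine_id",
        "length_um", "head_diameter_um", "neck_diameter_um", "volume_um3",
        "spine_class", "rule_flag"])
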