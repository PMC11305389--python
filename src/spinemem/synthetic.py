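"""Synthetic neuropathology–cognition cohorts with per-spine geometry.

The generator emulates the statistical structure of a postmortem cohort of
very old adults sampled in two cortical regions (a temporal-cortex-like
region, ``BA37``, and a premotor-like region, ``BA6``): per case, 8–12
neurons with one ≥20 µm dendritic segment each; per segment, a Poisson
number of spines drawn from the four morphology classes; per spine, a small
backbone polyline plus diameter profile that measures and classifies back to
the intended class.  Case covariates comprise age (~90.5 ± 6.1 y), sex
(0 = female, 1 = male), semiquantitative amyloid-plaque (NP) and
neurofibrillary-tangle (NFT) burdens — males carry systematically lower
pathology — and an episodic-memory composite generated linearly:

    memory = β_hd · meanHD_region + β_np · NP + β_nft · NFT + β_sex · sex + ε

where meanHD is the case's measured mean spine head diameter in the
memory-relevant region (temporal-like by default; the premotor-like effect
is zero).  A configurable number of cases (default 3) receive missing
pathology and/or memory values, mimicking incomplete records.

Randomness: one seed per cohort; each case and each (case, neuron) pair gets
its own child stream derived from stable integer keys, so enlarging the
cohort never perturbs earlier cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometry import (
    DEFAULT_THRESHOLDS,
    ClassifierThresholds,
    SpineGeometry,
    measure_spine,
    SPINE_CLASSES,
)

# Per-class sampling priors for (head diameter, head/neck ratio, length).
# The published classification rules give only thresholds; these truncated
# distributions are the package's own stand-ins, chosen so each class sits
# well inside its rule region while straddling realistic micron scales.
# "length_ratio" draws length as a multiple of head diameter (keeps stubby
# spines inside the length-to-head <= 2.5 region for any head size).
DEFAULT_CLASS_PRIORS: dict[str, dict] = {
    "thin": dict(head=(0.26, 0.05, 0.15, 0.345), hnr=(1.00, 1.08),
                 length=(1.6, 0.5, 0.6, 2.95)),
    "stubby": dict(head=(0.50, 0.08, 0.36, 1.10), hnr=(1.00, 1.08),
                   length_ratio=(1.0, 2.4)),
    "mushroom": dict(head=(0.55, 0.08, 0.36, 1.20), hnr=(1.15, 1.90),
                     length=(1.4, 0.4, 0.5, 2.9)),
    "filopodia": dict(head=(0.22, 0.04, 0.12, 0.345), hnr=(1.00, 1.08),
                      length=(3.9, 0.6, 3.05, 8.0)),
}


@dataclass
class CohortParams:
    """Generative settings for one synthetic cohort.

    Effect sizes are in memory-composite units: per µm of mean head diameter
    (``beta_hd``), per pathology unit (``beta_np``, ``beta_nft``) and for the
    male-vs-female contrast (``beta_sex``).  ``sex_pathology_shift`` moves
    male pathology means down (pathology units).
    """

    n_cases: int = 128
    neurons_per_case: tuple[int, int] = (8, 12)
    segment_length: tuple[float, float] = (20.0, 40.0)   # µm
    class_mix: tuple[float, float, float, float] = (0.45, 0.30, 0.20, 0.05)
    spines_per_10um: float = 5.0
    regions: tuple[str, ...] = ("BA37", "BA6")
    hd_region: str = "BA37"          # region whose mean head diameter drives memory
    beta_hd: float = 10.0            # memory units per µm of mean head diameter
    beta_np: float = -0.4
    beta_nft: float = -0.3
    beta_sex: float = 0.2
    sex_pathology_shift: float = -0.35
    noise_sd: float = 0.25
    n_missing: int = 3
    seed: int = 0
    # cohort demographics / pathology scales
    age_mean: float = 90.53
    age_sd: float = 6.06
    p_male: float = 0.35
    np_mean: float = 1.0
    np_sd: float = 0.5
    nft_mean: float = 1.0
    nft_sd: float = 0.5
    # between-case heterogeneity of spine traits
    hd_between_sd: float = 0.03      # µm shift of all class head-diameter means
    length_between_sd: float = 0.12  # µm shift of class length means
    mix_concentration: float = 60.0  # Dirichlet concentration around class_mix
    density_between_sd: float = 0.15 # log-scale SD of per-case density multiplier
    class_priors: dict = field(default_factory=lambda: DEFAULT_CLASS_PRIORS)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must be 4 non-negative probabilities summing to 1")
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        lo, hi = self.neurons_per_case
        if lo < 1 or hi < lo:
            raise ValueError("invalid neurons_per_case range")
        slo, shi = self.segment_length
        if slo <= 0 or shi < slo:
            raise ValueError("segment_length range must be positive")
        if self.spines_per_10um <= 0:
            raise ValueError("spines_per_10um must be positive")
        if not (0 <= self.n_missing < self.n_cases):
            raise ValueError("n_missing must be in [0, n_cases)")
        if self.hd_region not in self.regions and self.beta_hd != 0.0:
            raise ValueError("hd_region must be one of regions when beta_hd != 0")


@dataclass
class SyntheticCohort:
    """A generated cohort: geometries, per-spine measures, tables, truth."""

    params: CohortParams
    geometries: list                 # records with keys + SpineGeometry
    spines: pd.DataFrame             # measured + classified spine table
    segments: pd.DataFrame           # one row per (case, region, neuron, segment)
    cases: pd.DataFrame              # covariates incl. episodic memory
    truth: dict                      # generating coefficients + per-case latents


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    return float(np.clip(mean, lo + 1e-6, hi - 1e-6))


def _draw_spine(spine_class: str, rng: np.random.Generator,
                priors: dict | None,
                head_shift: float,
                length_shift: float,
                thresholds: ClassifierThresholds):
    """Rejection-sample one geometry plus its verified measure."""
    if spine_class not in SPINE_CLASSES:
        raise ValueError(f"unknown spine class {spine_class!r}")
    pri = (priors or DEFAULT_CLASS_PRIORS)[spine_class]
    voxel_dims = (0.1, 0.1, 0.1)
    vox_vol = voxel_dims[0] * voxel_dims[1] * voxel_dims[2]
    for _ in range(200):
        hm, hs, hlo, hhi = pri["head"]
        head = _trunc_normal(rng, hm + head_shift, hs, hlo, hhi)
        hnr = rng.uniform(*pri["hnr"])
        neck = head / hnr
        if "length_ratio" in pri:
            length = head * rng.uniform(*pri["length_ratio"])
        else:
            lm, ls, llo, lhi = pri["length"]
            length = _trunc_normal(rng, lm + length_shift, ls, llo, lhi)
        # two-segment backbone with exact curvilinear length
        u = rng.normal(size=3)
        u /= math.sqrt(u @ u)
        v = u + 0.5 * rng.normal(size=3)
        v /= math.sqrt(v @ v)
        backbone = np.empty((3, 3))
        backbone[0] = 0.0
        backbone[1] = 0.55 * length * u
        backbone[2] = backbone[1] + 0.45 * length * v
        profile = np.array([1.2 * neck, neck, head])
        approx = (math.pi / 4 * neck * neck * max(length - head, 0.2)
                  + math.pi / 6 * head ** 3)
        count = max(8, int(round(approx * rng.lognormal(0.0, 0.15) / vox_vol)))
        g = SpineGeometry(backbone=backbone, diameter_profile=profile,
                          voxel_count=count, voxel_dims=voxel_dims)
        m = measure_spine(g, thresholds)
        if m.spine_class == spine_class:
            return g, m
    raise RuntimeError(f"could not realise a {spine_class} spine (priors "
                       "inconsistent with classifier thresholds)")


def generate_spine(spine_class: str, rng: np.random.Generator,
                   priors: dict | None = None,
                   head_shift: float = 0.0,
                   length_shift: float = 0.0,
                   thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
                   ) -> SpineGeometry:
    """Draw one spine geometry whose measured class equals ``spine_class``.

    Rejection-samples (head, head/neck ratio, length) from the class priors,
    builds a two-segment backbone of the target curvilinear length with a
    three-point diameter profile (flared base, neck, head), and retries until
    the morphometry round-trip returns the requested class.
    """
    g, _ = _draw_spine(spine_class, rng, priors, head_shift, length_shift,
                       thresholds)
    return g


def _case_stream(seed: int, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, case_index]))


def _neuron_stream(seed: int, case_index: int, neuron_index: int
                   ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, 2, case_index, neuron_index]))


def generate_cohort(params: CohortParams | None = None) -> SyntheticCohort:
    """Generate a full cohort (geometry, spine, segment and case tables)."""
    p = params or CohortParams()
    mix = np.asarray(p.class_mix, dtype=float)

    geometries: list[dict] = []
    spine_rows: list[tuple] = []
    seg_rows: list[tuple] = []
    case_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(p.n_cases):
        case_id = f"case_{i:03d}"
        crng = _case_stream(p.seed, i)
        age = crng.normal(p.age_mean, p.age_sd)
        sex = int(crng.uniform() < p.p_male)
        np_score = max(0.0, crng.normal(
            p.np_mean + p.sex_pathology_shift * sex, p.np_sd))
        nft_burden = max(0.0, crng.normal(
            p.nft_mean + p.sex_pathology_shift * sex, p.nft_sd))
        abeta_load = max(0.0, 0.7 * np_score + crng.normal(0.0, 0.3))

        region_hd_sum: dict[str, float] = {r: 0.0 for r in p.regions}
        region_hd_n: dict[str, int] = {r: 0 for r in p.regions}
        n_neurons = int(crng.integers(p.neurons_per_case[0],
                                      p.neurons_per_case[1] + 1))
        neuron_index = 0
        for region in p.regions:
            # between-case trait heterogeneity is region-specific: a case
            # with wide temporal-cortex spine heads need not have wide
            # premotor ones, which keeps the memory effect regional
            head_shift = crng.normal(0.0, p.hd_between_sd)
            length_shift = crng.normal(0.0, p.length_between_sd)
            mix_c = crng.dirichlet(mix * p.mix_concentration)
            density_mult = crng.lognormal(0.0, p.density_between_sd)
            for j in range(n_neurons):
                nrng = _neuron_stream(p.seed, i, neuron_index)
                neuron_index += 1
                neuron_id = f"{region}_n{j:02d}"
                segment_id = f"{neuron_id}_s0"
                seg_len = nrng.uniform(*p.segment_length)
                k = int(nrng.poisson(
                    density_mult * p.spines_per_10um * seg_len / 10.0))
                seg_rows.append((case_id, region, neuron_id, segment_id,
                                 seg_len, k))
                if k == 0:
                    continue
                classes = nrng.choice(4, size=k, p=mix_c)
                for s in range(k):
                    cls = SPINE_CLASSES[classes[s]]
                    g, m = _draw_spine(cls, nrng, p.class_priors,
                                       head_shift, length_shift, p.thresholds)
                    spine_id = f"{segment_id}_sp{s:03d}"
                    geometries.append(dict(case_id=case_id, region=region,
                                           neuron_id=neuron_id,
                                           segment_id=segment_id,
                                           spine_id=spine_id, geometry=g))
                    spine_rows.append((case_id, region, neuron_id, segment_id,
                                       spine_id, m.length, m.head_diameter,
                                       m.neck_diameter, m.volume,
                                       m.spine_class, m.rule_flag))
                    region_hd_sum[region] += m.head_diameter
                    region_hd_n[region] += 1

        mean_hd = (region_hd_sum[p.hd_region] / region_hd_n[p.hd_region]
                   if p.hd_region in region_hd_n and region_hd_n[p.hd_region]
                   else 0.0)
        linear_pred = (p.beta_hd * mean_hd + p.beta_np * np_score
                       + p.beta_nft * nft_burden + p.beta_sex * sex)
        noise = crng.normal(0.0, p.noise_sd) if p.noise_sd > 0 else 0.0
        episodic_memory = linear_pred + noise
        global_cognition = 0.8 * linear_pred + crng.normal(0.0, 0.3)
        perceptual_speed = (-0.02 * (age - p.age_mean)
                            + crng.normal(0.0, 0.5))
        case_rows.append(dict(case_id=case_id, age=age, sex=sex,
                              np_score=np_score, nft_burden=nft_burden,
                              abeta_load=abeta_load,
                              episodic_memory=episodic_memory,
                              global_cognition=global_cognition,
                              perceptual_speed=perceptual_speed))
        truth_rows.append(dict(case_id=case_id, mean_hd=mean_hd,
                               linear_pred=linear_pred, noise=noise,
                               episodic_memory=episodic_memory))

    cases = pd.DataFrame(case_rows)
    # missing-at-random injection over pathology and/or memory scores
    mrng = np.random.default_rng(np.random.SeedSequence([p.seed, 3]))
    if p.n_missing:
        victims = mrng.choice(p.n_cases, size=p.n_missing, replace=False)
        missable = ["np_score", "nft_burden", "episodic_memory"]
        for v in victims:
            cols = [c for c in missable if mrng.uniform() < 0.5]
            if not cols:
                cols = [missable[int(mrng.integers(3))]]
            cases.loc[v, cols] = np.nan

    spines = pd.DataFrame(spine_rows, columns=[
        "case_id", "region", "neuron_id", "segment_id", "spine_id",
        "length_um", "head_diameter_um", "neck_diameter_um", "volume_um3",
        "spine_class", "rule_flag"])
    segments = pd.DataFrame(seg_rows, columns=[
        "case_id", "region", "neuron_id", "segment_id", "length_um",
        "n_spines"])
    truth = dict(
        coefficients=dict(beta_hd=p.beta_hd, beta_np=p.beta_np,
                          beta_nft=p.beta_nft, beta_sex=p.beta_sex),
        hd_region=p.hd_region,
        sex_coding="0=female, 1=male",
        noise_sd=p.noise_sd,
        per_case=pd.DataFrame(truth_rows),
    )
    return SyntheticCohort(params=p, geometries=geometries, spines=spines,
                           segments=segments, cases=cases, truth=truth)


def draw_case_covariates(params: CohortParams) -> pd.DataFrame:
    """Covariates only (no spines) — fast path for demographic checks.

    Uses the same per-case streams as :func:`generate_cohort`, so age, sex
    and pathology scores match the full generator draw-for-draw.
    """
    p = params
    rows = []
    for i in range(p.n_cases):
        crng = _case_stream(p.seed, i)
        age = crng.normal(p.age_mean, p.age_sd)
        sex = int(crng.uniform() < p.p_male)
        np_score = max(0.0, crng.normal(
            p.np_mean + p.sex_pathology_shift * sex, p.np_sd))
        nft_burden = max(0.0, crng.normal(
            p.nft_mean + p.sex_pathology_shift * sex, p.nft_sd))
        rows.append(dict(case_id=f"case_{i:03d}", age=age, sex=sex,
                         np_score=np_score, nft_burden=nft_burden))
    return pd.DataFrame(rows)
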