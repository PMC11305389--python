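"""End-to-end pipeline drivers and replicate experiments.

``run_region_pipeline`` executes the whole analysis for one region of one
cohort: aggregate spine traits per case, drop incomplete cases, split into
discovery/validation halves, run LASSO discovery on one half and the
nested-model LOOCV comparison on the other, then screen the full cohort's
correlations.  The replicate experiments rerun (parts of) that pipeline
over many seeded cohorts to measure recovery and error rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .correlations import correlation_matrix, feature_columns
from .features import (aggregate_features, analysis_table,
                       filter_complete_cases, split_discovery_validation)
from .lasso import SPINE_TRAITS, LassoConfig, rank_traits, select_lambda
from .synthetic import CohortParams, SyntheticCohort, generate_cohort
from .validation import ModelSpec, compare_models, default_model_specs

REQUIRED_CASE_COLUMNS = ("np_score", "nft_burden", "episodic_memory")
SCORE_COLUMNS = ("episodic_memory", "global_cognition", "perceptual_speed",
                 "np_score", "nft_burden", "abeta_load")
TRAIT_COLUMNS = {"density": "mean_density", "length": "mean_length",
                 "head_diameter": "mean_head_diameter",
                 "volume": "mean_volume"}


def _sub_seed(base: int, r: int) -> int:
    return int((base * 100_003 + r) % 2**31)


@dataclass
class RegionResult:
    region: str
    features: pd.DataFrame
    complete_cases: pd.DataFrame
    discovery: pd.DataFrame
    validation: pd.DataFrame
    lasso: object
    trait_ranking: list
    model_reports: list
    correlations: pd.DataFrame


def run_region_pipeline(cohort: SyntheticCohort, region: str,
                        split_seed: int = 0,
                        lasso_cfg: LassoConfig | None = None,
                        model_specs: list[ModelSpec] | None = None,
                        focal_trait: str = "head_diameter",
                        fdr_levels=(0.1, 0.05)) -> RegionResult:
    """Full split → LASSO → nested-LOOCV → correlation analysis of a region."""
    feats = aggregate_features(cohort.spines, cohort.segments)
    feats = feats[feats.region == region].reset_index(drop=True)
    feats_keyed = feats.assign(region=region)
    cases = filter_complete_cases(cohort.cases, REQUIRED_CASE_COLUMNS)
    disc, val = split_discovery_validation(cases, seed=split_seed)

    t_disc = analysis_table(feats_keyed, disc, region)
    X = t_disc[[TRAIT_COLUMNS[t] for t in SPINE_TRAITS]].to_numpy(float)
    y = t_disc["episodic_memory"].to_numpy(float)
    cfg = lasso_cfg or LassoConfig(seed=split_seed)
    las = select_lambda(X, y, cfg)
    ranking = rank_traits(las)

    t_val = analysis_table(feats_keyed, val, region)
    specs = model_specs or default_model_specs(focal_trait)
    reports = compare_models(t_val, specs)

    grid = correlation_matrix(feats_keyed, cases, SCORE_COLUMNS,
                              fdr_levels=fdr_levels)
    return RegionResult(region=region, features=feats_keyed,
                        complete_cases=cases, discovery=disc, validation=val,
                        lasso=las, trait_ranking=ranking,
                        model_reports=reports, correlations=grid)


def recovery_experiment(n_rep: int = 100, base_seed: int = 0,
                        beta_hd: float | None = None,
                        cv_repeats: int = 100,
                        region: str = "BA37") -> pd.DataFrame:
    """Parameter-recovery replicates of the discovery + validation stages.

    Each replicate generates a fresh single-region cohort (temporal-like
    defaults, or ``beta_hd=0`` for the premotor-like null), runs LASSO on
    the discovery half and the head-diameter nested-model contrast on the
    validation half.  Returns one row per replicate with the top-ranked
    trait, the number of selected traits, and the LOOCV MSEs of the
    pathology+sex+head-diameter vs pathology+sex models.
    """
    rows = []
    for r in range(n_rep):
        seed = _sub_seed(base_seed, r)
        params = CohortParams(seed=seed, regions=(region,), hd_region=region)
        if beta_hd is not None:
            params = replace(params, beta_hd=beta_hd)
        cohort = generate_cohort(params)
        specs = [ModelSpec("pathology_sex_hd",
                           ("np_score", "nft_burden", "sex", "head_diameter")),
                 ModelSpec("pathology_sex", ("np_score", "nft_burden", "sex"))]
        res = run_region_pipeline(
            cohort, region, split_seed=seed,
            lasso_cfg=LassoConfig(cv_repeats=cv_repeats, seed=seed),
            model_specs=specs)
        by_name = {rep.spec.name: rep for rep in res.model_reports}
        mse_hd = by_name["pathology_sex_hd"].loocv_mse
        mse_ps = by_name["pathology_sex"].loocv_mse
        hd_cell = res.correlations.query(
            "feature == 'mean_head_diameter' and score == 'episodic_memory'"
        ).iloc[0]
        rows.append(dict(
            seed=seed,
            top_trait=res.trait_ranking[0][0] if res.trait_ranking else "",
            n_selected=len(res.trait_ranking),
            mse_pathology_sex_hd=mse_hd,
            mse_pathology_sex=mse_ps,
            hd_improves=bool(mse_hd < mse_ps),
            hd_rho=float(hd_cell.rho),
            hd_q05=bool(hd_cell.sig_q05),
        ))
    return pd.DataFrame(rows)


def null_fdr_experiment(n_rep: int = 200, base_seed: int = 0,
                        n_cases: int = 60,
                        fdr_levels=(0.1, 0.05)) -> pd.DataFrame:
    """False-flag fractions of the correlation screen on all-null cohorts.

    Every generative effect is zeroed, so each feature × score cell is a
    true null; the returned per-replicate flagged fractions should stay
    near (below) the nominal FDR levels.
    """
    rows = []
    for r in range(n_rep):
        seed = _sub_seed(base_seed, r)
        params = CohortParams(seed=seed, n_cases=n_cases, regions=("BA37",),
                              hd_region="BA37", beta_hd=0.0, beta_np=0.0,
                              beta_nft=0.0, beta_sex=0.0,
                              sex_pathology_shift=0.0)
        cohort = generate_cohort(params)
        feats = aggregate_features(cohort.spines, cohort.segments)
        cases = filter_complete_cases(cohort.cases, REQUIRED_CASE_COLUMNS)
        grid = correlation_matrix(feats, cases, SCORE_COLUMNS,
                                  fdr_levels=fdr_levels)
        defined = grid.q_value.notna()
        rows.append(dict(seed=seed,
                         n_cells=int(defined.sum()),
                         frac_q10=float(grid.loc[defined, "sig_q10"].mean()),
                         frac_q05=float(grid.loc[defined, "sig_q05"].mean()),
                         frac_p05=float((grid.loc[defined, "p_value"] < 0.05)
                                        .mean())))
    return pd.DataFrame(rows)
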