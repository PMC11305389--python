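"""Nested linear-model comparison by leave-one-out cross-validation.

Candidate models for episodic memory combine pathology scores (NP, NFT),
sex, age and region-specific spine traits.  Each model is scored by its
LOOCV mean squared prediction error; because ordinary least squares admits
the hat-matrix identity e⁽⁻ⁱ⁾ = eᵢ / (1 − hᵢᵢ), the n leave-one-out refits
reduce to a single fit.  Alongside the MSE we report R² of the pooled LOOCV
predictions (1 − SSE_pred / SST about the observed mean) and the Pearson
correlation between observed and predicted scores.  Percentile bootstrap
intervals for the LOOCV MSE resample whole cases with replacement and rerun
the complete LOOCV per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical predictor names -> analysis-table columns
PREDICTOR_COLUMNS = {
    "age": "age",
    "sex": "sex",
    "np_score": "np_score",
    "nft_burden": "nft_burden",
    "density": "mean_density",
    "length": "mean_length",
    "head_diameter": "mean_head_diameter",
    "volume": "mean_volume",
    "apoe4": "apoe4",
}

RESPONSE = "episodic_memory"


@dataclass(frozen=True)
class ModelSpec:
    name: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("a model needs at least one predictor")
        unknown = [p for p in self.predictors if p not in PREDICTOR_COLUMNS]
        if unknown:
            raise ValueError(f"unknown predictors: {unknown}")

    def columns(self) -> list[str]:
        return [PREDICTOR_COLUMNS[p] for p in self.predictors]


def default_model_specs(spine_trait: str = "head_diameter") -> list[ModelSpec]:
    """The standard nested-model ladder around one focal spine trait."""
    path = ("np_score", "nft_burden")
    return [
        ModelSpec("full", ("age", "sex") + path +
                  ("density", "length", "head_diameter", "volume")),
        ModelSpec("full_minus_age", ("sex",) + path +
                  ("density", "length", "head_diameter", "volume")),
        ModelSpec(f"pathology_sex_{spine_trait}", path + ("sex", spine_trait)),
        ModelSpec("pathology_sex", path + ("sex",)),
        ModelSpec(f"pathology_{spine_trait}", path + (spine_trait,)),
    ]


@dataclass
class ModelReport:
    spec: ModelSpec
    loocv_mse: float
    r_squared: float
    pearson_observed_vs_predicted: float
    n_used: int
    predictions: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    bootstrap_mse_ci: tuple[float, float] | None = None
    bootstrap_B: int | None = None
    bootstrap_level: float | None = None


class SingularModelError(ValueError):
    pass


def _design(table: pd.DataFrame, spec: ModelSpec):
    cols = spec.columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns absent from analysis table: {missing}")
    sub = table[cols + [RESPONSE]].dropna()
    X = np.column_stack([np.ones(len(sub)), sub[cols].to_numpy(float)])
    y = sub[RESPONSE].to_numpy(float)
    return X, y


def _loocv_errors(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out prediction errors via the hat-matrix identity."""
    n, p = X.shape
    if n < p + 2:
        raise SingularModelError("too few rows for the model")
    q, r = np.linalg.qr(X)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(r))):
        raise SingularModelError("singular design matrix")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    h = np.sum(q * q, axis=1)
    if np.any(h >= 1 - 1e-12):
        raise SingularModelError("leverage 1: a row determines its own fit")
    return resid / (1.0 - h)


def loocv_evaluate(table: pd.DataFrame, spec: ModelSpec) -> ModelReport:
    """LOOCV report for one model on the (complete-case) analysis table."""
    X, y = _design(table, spec)
    e = _loocv_errors(X, y)
    pred = y - e
    sst = float(np.sum((y - y.mean()) ** 2))
    mse = float(np.mean(e ** 2))
    r2 = 1.0 - float(np.sum(e ** 2)) / sst
    r = float(np.corrcoef(y, pred)[0, 1]) if np.std(pred) > 0 else np.nan
    return ModelReport(spec=spec, loocv_mse=mse, r_squared=r2,
                       pearson_observed_vs_predicted=r, n_used=len(y),
                       predictions=pred, observed=y)


def compare_models(table: pd.DataFrame, specs: list[ModelSpec]
                   ) -> list[ModelReport]:
    """Evaluate all models and rank ascending by LOOCV MSE (best first)."""
    if len(specs) < 2:
        raise ValueError("need at least two models to compare")
    reports = []
    skipped = []
    for spec in specs:
        try:
            reports.append(loocv_evaluate(table, spec))
        except SingularModelError as exc:
            skipped.append((spec.name, str(exc)))
    if not reports:
        raise SingularModelError(f"all models singular: {skipped}")
    reports.sort(key=lambda rep: rep.loocv_mse)
    return reports


def bootstrap_mse_ci(table: pd.DataFrame, spec: ModelSpec,
                     B: int = 1000, level: float = 0.90,
                     seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for the LOOCV MSE.

    Cases are resampled with replacement; each replicate reruns the full
    LOOCV on the resampled table.  Replicates with a singular design are
    redrawn (their count is capped at 10·B).  ``level=0`` degenerates to the
    median replicate.
    """
    if B < 100:
        raise ValueError("need B >= 100 bootstrap replicates")
    if not (0 <= level < 1):
        raise ValueError("level must be in [0, 1)")
    X, y = _design(table, spec)
    n = len(y)
    rng = np.random.default_rng(seed)
    mses = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            try:
                e = _loocv_errors(X[idx], y[idx])
            except SingularModelError:
                redraws += 1
                if redraws > 10 * B:
                    raise
                continue
            mses[b] = np.mean(e ** 2)
            break
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(mses, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def attach_bootstrap(report: ModelReport, table: pd.DataFrame,
                     B: int = 1000, level: float = 0.90,
                     seed: int = 0) -> ModelReport:
    report.bootstrap_mse_ci = bootstrap_mse_ci(table, report.spec, B, level, seed)
    report.bootstrap_B = B
    report.bootstrap_level = level
    return report


def reports_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Flatten reports to the model-comparison table written by the drivers."""
    rows = []
    for rep in reports:
        row = dict(model=rep.spec.name,
                   predictors="+".join(rep.spec.predictors),
                   loocv_mse=rep.loocv_mse, r_squared=rep.r_squared,
                   pearson=rep.pearson_observed_vs_predicted, n=rep.n_used)
        if rep.bootstrap_mse_ci is not None:
            row["mse_ci_lo"], row["mse_ci_hi"] = rep.bootstrap_mse_ci
        rows.append(row)
    return pd.DataFrame(rows)
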