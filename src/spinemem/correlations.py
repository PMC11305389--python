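"""Full-cohort Spearman correlation screen with Storey q-value FDR.

Every spine-feature × cognition/pathology-score cell gets a Spearman rho
(mid-rank Pearson, average ranks on ties, pairwise deletion of missing
values), a p-value (t approximation on n − 2 df; exact permutation below
n = 10), and a q-value computed over the whole grid with Storey's π₀
estimate.  Cells are flagged at FDR 10% and 5%, matching the single/double
asterisk annotation convention of correlation heatmaps.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationCell:
    feature: str
    score: str
    rho: float
    n_pairs: int
    p_value: float
    q_value: float = np.nan
    sig_q10: bool = False
    sig_q05: bool = False
    flag: str = ""


def spearman(x, y, exact_below: int = 10) -> tuple[float, float, int]:
    """Spearman rho and p on complete pairs; returns (rho, p, n_pairs).

    p comes from the usual t approximation with n − 2 df; when the number of
    complete pairs is below ``exact_below`` the exact permutation null of
    the mid-rank correlation is enumerated instead.  A constant vector
    (after deletion) yields (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < exact_below:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p, n


def estimate_pi0(p, lambdas=None) -> float:
    """Storey's estimate of the null proportion π₀.

    For m ≥ 20 p-values: π̂₀(λ) = #{p > λ} / (m (1 − λ)) over
    λ ∈ {0.05, …, 0.95}, smoothed by a cubic polynomial and read off at the
    largest λ.  Shorter lists fall back to the fixed-λ = 0.5 estimate, and
    lists below 4 entries to π₀ = 1.  The result is clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 4:
        return 1.0
    if m < 20:
        pi0 = np.mean(p > 0.5) / 0.5
        return float(min(1.0, max(pi0, 1.0 / m)))
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_lam, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(min(1.0, max(pi0, 1.0 / m)))


def storey_qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: qᵢ = min_{p₍ⱼ₎ ≥ p₍ᵢ₎} π̂₀ · m · p₍ⱼ₎ / rank(j).

    With ``pi0=1`` this reproduces Benjamini–Hochberg adjusted p-values
    exactly.  Output is monotone non-decreasing in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


DEFAULT_FEATURE_COLUMNS = None  # resolved per feature table


def feature_columns(features: pd.DataFrame) -> list[str]:
    """All aggregated spine-trait columns present in a feature table."""
    skip = {"case_id", "region", "n_neurons", "n_spines", "total_dendrite_um"}
    return [c for c in features.columns if c not in skip]


def correlation_matrix(features: pd.DataFrame, scores: pd.DataFrame,
                       score_columns, feature_cols=None,
                       fdr_levels=(0.1, 0.05),
                       exact_below: int = 10) -> pd.DataFrame:
    """Long-format grid of all feature × score Spearman cells with q-values.

    q-values are computed over the full grid of defined p-values (one
    multiplicity family per call, i.e. per region).
    """
    if feature_cols is None:
        feature_cols = feature_columns(features)
    merged = features.merge(scores, on="case_id", how="inner",
                            suffixes=("", "_score"))
    if len(merged) == 0:
        raise ValueError("no overlapping cases between features and scores")
    cells: list[CorrelationCell] = []
    for feat in feature_cols:
        for sc in score_columns:
            col_sc = sc if sc in merged.columns else f"{sc}_score"
            x = merged[feat].to_numpy(float)
            y = merged[col_sc].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4:
                cells.append(CorrelationCell(feat, sc, np.nan, int(ok.sum()),
                                             np.nan, flag="too_few_pairs"))
                continue
            rho, p, npairs = spearman(x, y, exact_below=exact_below)
            flag = "constant" if not np.isfinite(rho) else ""
            cells.append(CorrelationCell(feat, sc, rho, npairs, p, flag=flag))
    pvals = np.array([c.p_value for c in cells])
    defined = np.isfinite(pvals)
    if defined.any():
        q = storey_qvalues(pvals[defined])
        for c, qi in zip([c for i, c in enumerate(cells) if defined[i]], q):
            c.q_value = float(qi)
            c.sig_q10 = qi < fdr_levels[0]
            c.sig_q05 = qi < fdr_levels[1]
    rows = []
    for c in cells:
        annot = "**" if c.sig_q05 else ("*" if c.sig_q10 and c.p_value < 0.05
                                        else "")
        rows.append(dict(feature=c.feature, score=c.score, rho=c.rho,
                         n_pairs=c.n_pairs, p_value=c.p_value,
                         q_value=c.q_value, sig_q10=c.sig_q10,
                         sig_q05=c.sig_q05, annotation=annot, flag=c.flag))
    return pd.DataFrame(rows)


def heatmap_matrix(grid: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long grid to a feature × score rho matrix."""
    return grid.pivot(index="feature", columns="score", values="rho")
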