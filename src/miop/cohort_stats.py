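"""Cohort-level validation statistics.

Univariate regression with the extra-sum-of-squares F test (slope model vs
horizontal intercept-only line), Bland-Altman agreement, paired pre/post
change summaries, and the candidate-screening scan that ranks waveform
features by the performance score.

Degenerate-variance conventions: when y has zero variance the Pearson r is
defined as 0 and the slope p value as 1; Bland-Altman with exactly constant
differences reports its tests as degenerate rather than claiming infinite
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .deformation_features import performance_score
from .errors import ConfigError, DegenerateDesign, ShapeError

__all__ = [
    "RegressionResult",
    "BlandAltman",
    "PairedChange",
    "univariate_fit",
    "bland_altman",
    "paired_change",
    "screen_candidates",
]

SCREEN_COVARIATES = ("iop_corvis", "iop_pach", "age", "radius_mm", "cct_um")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p_slope: float  # extra-sum-of-squares F test vs the horizontal line
    n: int


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float  # first minus second
    sd_diff: float
    loa_low: float
    loa_high: float
    p_fixed_bias: float
    proportional_slope: float
    p_proportional: float
    n: int
    degenerate: bool = False  # exactly constant differences


@dataclass(frozen=True)
class PairedChange:
    mean_change: float  # post minus pre
    ci95: Tuple[float, float]
    p_paired: float
    n: int


def _as_pair(a, b, min_n: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("inputs must be 1-D vectors of equal length")
    if len(a) < min_n:
        raise ShapeError(f"need at least {min_n} pairs, got {len(a)}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ShapeError("inputs must be finite")
    return a, b


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.var(x) == 0 or np.var(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def univariate_fit(x, y) -> RegressionResult:
    """OLS of y on x; the slope p value is the nested-model F test.

    The F test compares the slope model against the horizontal line at
    mean(y) with (1, n-2) degrees of freedom; it coincides algebraically
    with the squared-t test of the slope.
    """
    x, y = _as_pair(x, y)
    if np.var(x) == 0:
        raise DegenerateDesign("covariate has zero variance")
    if np.var(y) == 0:
        # A horizontal line fits exactly; the slope adds nothing.
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), pearson_r=0.0, p_slope=1.0, n=len(y)
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    p = float(model.f_pvalue)
    if not np.isfinite(p):  # perfect fit: F is infinite
        p = 0.0
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        pearson_r=_safe_pearson(x, y),
        p_slope=p,
        n=len(y),
    )


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltman:
    """Agreement between two paired measurement methods (differences a - b)."""
    a, b = _as_pair(a, b)
    d = a - b
    mean = (a + b) / 2.0
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        p_fixed = np.nan
    else:
        p_fixed = float(stats.ttest_1samp(d, 0.0).pvalue)
    if np.var(mean) == 0 or degenerate:
        prop_slope, p_prop = 0.0, np.nan if degenerate else 1.0
        if np.var(mean) == 0:
            p_prop = np.nan
    else:
        fit = univariate_fit(mean, d)
        prop_slope, p_prop = fit.slope, fit.p_slope
    return BlandAltman(
        mean_diff=md,
        sd_diff=sd,
        loa_low=md - loa_multiplier * sd,
        loa_high=md + loa_multiplier * sd,
        p_fixed_bias=p_fixed,
        proportional_slope=prop_slope,
        p_proportional=p_prop,
        n=len(d),
        degenerate=degenerate,
    )


def paired_change(pre, post) -> PairedChange:
    """Mean post-minus-pre change with a t-based 95% CI and paired test."""
    pre, post = _as_pair(pre, post)
    d = post - pre
    n = len(d)
    m = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return PairedChange(mean_change=m, ci95=(m, m),
                            p_paired=1.0 if m == 0 else 0.0, n=n)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    p = float(stats.ttest_rel(post, pre).pvalue)
    return PairedChange(mean_change=m, ci95=(m - half, m + half), p_paired=p, n=n)


def screen_candidates(
    feature_table: pd.DataFrame,
    covariate_table: pd.DataFrame,
    feature_columns: Optional[List[str]] = None,
) -> pd.DataFrame:
    """Rank candidate features by the performance score.

    Both tables must carry an ``id`` column (or index); covariates must
    include iop_corvis, iop_pach, age, radius_mm and cct_um.  Returns one row
    per feature with the five Pearson correlations and the score, sorted by
    descending score with a stable order on ties.
    """
    feats = feature_table.set_index("id") if "id" in feature_table.columns else feature_table
    covs = covariate_table.set_index("id") if "id" in covariate_table.columns else covariate_table
    missing = [c for c in SCREEN_COVARIATES if c not in covs.columns]
    if missing:
        raise ConfigError(f"covariate table missing column(s): {', '.join(missing)}")
    merged = feats.join(covs[list(SCREEN_COVARIATES)], how="inner")
    if len(merged) < 3:
        raise ConfigError(
            "fewer than 3 aligned rows between features and covariates"
        )
    if feature_columns is None:
        feature_columns = [c for c in feats.columns if c not in SCREEN_COVARIATES]
    rows = []
    for col in feature_columns:
        f = merged[col].to_numpy(dtype=float)
        rs = {c: _safe_pearson(f, merged[c].to_numpy(dtype=float))
              for c in SCREEN_COVARIATES}
        rows.append(
            {"feature": col,
             **{f"r_{c}": rs[c] for c in SCREEN_COVARIATES},
             "score": performance_score(
                 rs["iop_corvis"], rs["iop_pach"], rs["age"],
                 rs["radius_mm"], rs["cct_um"])}
        )
    out = pd.DataFrame(rows)
    return out.sort_values("score", ascending=False, kind="stable").reset_index(
        drop=True
    )
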