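"""Cohort-level statistics for boundary-evoked activity.

One-sample tests of adjusted betas against zero, Pearson age correlations,
equal-size age-tertile group comparisons (one-way ANOVA with Tukey HSD and
eta-squared), pooled-variance sex checks, OLS multiple regression for
brain-behavior prediction, and Benjamini-Hochberg FDR for voxelwise grids.

Standard inferential machinery is delegated to scipy.stats and statsmodels;
this module fixes the contracts (two-sided tests, strict input validation,
deterministic tie-breaking for the tertile split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrStat",
    "GroupStats",
    "TukeyPair",
    "one_sample_t",
    "pearson_corr",
    "age_tertiles",
    "anova_tukey",
    "ols_regression",
    "bh_fdr",
    "sex_difference_check",
]

AGE_GROUP_LABELS = ("young", "middle", "older")


@dataclass(frozen=True)
class CorrStat:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    difference: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class GroupStats:
    """One-way ANOVA with effect size and Tukey HSD post hoc contrasts."""

    F: float
    df: tuple[int, int]
    p: float
    eta_squared: float
    tukey: list[TukeyPair]


def one_sample_t(values) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of the mean against zero."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(values, 0.0)
    return float(res.statistic), values.size - 1, float(res.pvalue)


def pearson_corr(x, y) -> CorrStat:
    """Pearson product-moment correlation with a two-sided t-based p."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrStat(r=float(r), p=float(p), n=x.size)


def age_tertiles(cohort: pd.DataFrame) -> pd.DataFrame:
    """Label a cohort with equal-size young / middle / older age groups.

    Subjects are sorted by age (ties broken by subject_id) and split into
    three contiguous blocks as equal as possible, remainders going to the
    younger groups.  Returns a copy with an ``age_group`` column.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects for a tertile split")
    for col in ("age", "subject_id"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    order = cohort.sort_values(["age", "subject_id"], kind="stable").index
    n = len(cohort)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.repeat(AGE_GROUP_LABELS, sizes)
    out = cohort.copy()
    out.loc[order, "age_group"] = labels
    return out


def anova_tukey(values, labels, alpha: float = 0.05) -> GroupStats:
    """One-way ANOVA with eta-squared and Tukey HSD post hoc comparisons."""
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if values.size != labels.size:
        raise ValueError("values and labels lengths differ")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")

    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(((values - grand) ** 2).sum())
    eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
    F, p = sps.f_oneway(*groups)
    df = (len(groups) - 1, values.size - len(groups))

    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = []
    k = 0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            pairs.append(
                TukeyPair(
                    group_a=str(uniq[i]),
                    group_b=str(uniq[j]),
                    difference=float(res.meandiffs[k]),
                    p_adj=float(res.pvalues[k]),
                    significant=bool(res.reject[k]),
                )
            )
            k += 1
    return GroupStats(F=float(F), df=df, p=float(p), eta_squared=float(eta_sq), tukey=pairs)


def ols_regression(outcome, predictors: pd.DataFrame) -> pd.DataFrame:
    """OLS multiple regression with per-coefficient t-tests.

    Returns a table with one row per predictor plus an intercept row:
    coefficient, std_error, t, p.  Predictors are unstandardized.  Raises on
    rank deficiency, naming the dependent columns.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = predictors.astype(float)
    if len(X) != y.size:
        raise ValueError("outcome and predictors have different lengths")
    if len(X) < X.shape[1] + 1:
        raise ValueError("need more rows than predictors")
    design = sm.add_constant(X, has_constant="add").rename(columns={"const": "intercept"})
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        qr_r = np.linalg.qr(design.to_numpy())[1]
        scale = np.abs(np.diag(qr_r)).max()
        dep = [
            design.columns[i]
            for i in np.flatnonzero(np.abs(np.diag(qr_r)) < 1e-10 * max(scale, 1.0))
        ]
        raise ValueError(f"rank-deficient predictors; dependent columns: {dep}")
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame(
        {
            "coefficient": fit.params,
            "std_error": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    table.attrs["df_model"] = float(fit.df_model)
    table.attrs["df_resid"] = float(fit.df_resid)
    table.attrs["r_squared"] = float(fit.rsquared)
    return table


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at FDR level q."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def sex_difference_check(values, sex_labels) -> tuple[float, float]:
    """Pooled-variance two-sample t-test between the two sexes.

    The statistic is (mean of the lexicographically first label) minus
    (mean of the second), so swapping labels negates t.
    """
    values = np.asarray(values, dtype=float).ravel()
    sex_labels = np.asarray(sex_labels).ravel()
    uniq = sorted(set(sex_labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two sexes present, got {uniq}")
    a = values[sex_labels == uniq[0]]
    b = values[sex_labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sex needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
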