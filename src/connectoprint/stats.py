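"""Shared statistical kernels: covariate-adjusted group tests, t-tests,
correlation p-values, and Benjamini-Hochberg FDR.

Conventions: all p-values are two-sided; FDR is the Benjamini-Hochberg
step-up procedure; the covariate-adjusted group comparison is an OLS fit of
``y ~ intercept + group + covariate`` reporting the group coefficient
(df = s - 3, matching the classical ANOVA table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str
    estimate: float | None = None
    p_adjusted: float | None = None


def group_effect_with_covariate(
    y: np.ndarray, group: np.ndarray, covariate: np.ndarray
) -> TestResult:
    """Effect of a binary group variable on y, adjusting for a scalar covariate.

    Fits ``y ~ 1 + group + covariate`` by ordinary least squares and returns
    the t statistic, df = s - 3, and two-sided p of the group coefficient.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if not (y.shape == group.shape == covariate.shape) or y.ndim != 1:
        raise ValueError("y, group, covariate must be equal-length 1-D vectors")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("group must be binary")
    if min(np.sum(group == levels[0]), np.sum(group == levels[1])) < 2:
        raise ValueError("need at least 2 subjects per group")
    X = sm.add_constant(np.column_stack([group, covariate]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate collinear with group indicator (rank-deficient design)")
    fit = sm.OLS(y, X).fit()
    return TestResult(
        statistic=float(fit.tvalues[1]),
        df=float(fit.df_resid),
        p=float(fit.pvalues[1]),
        kind="group_effect_with_covariate",
        estimate=float(fit.params[1]),
    )


def t_test(kind: str, a: np.ndarray, b: np.ndarray | float | None = None) -> TestResult:
    """Classical two-sided t-tests.

    kind='paired'     : paired t of a vs b (equal-length vectors).
    kind='one_sample' : one-sample t of a against the scalar mean b (default 0).
    kind='two_sample' : pooled-variance two-sample t of a vs b.

    A degenerate zero-variance case with a zero mean difference is reported as
    t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    if kind == "paired":
        bv = np.asarray(b, dtype=float)
        if a.shape != bv.shape or a.ndim != 1 or a.size < 2:
            raise ValueError("paired test needs two equal-length vectors (n >= 2)")
        d = a - bv
        if np.all(d == d[0]) and d[0] == 0:
            return TestResult(0.0, float(a.size - 1), 1.0, "paired", estimate=0.0)
        t, p = sps.ttest_rel(a, bv)
        return TestResult(float(t), float(a.size - 1), float(p), "paired",
                          estimate=float(d.mean()))
    if kind == "one_sample":
        popmean = 0.0 if b is None else float(b)
        if a.size < 2:
            raise ValueError("one-sample test needs n >= 2")
        if np.all(a == a[0]) and a[0] == popmean:
            return TestResult(0.0, float(a.size - 1), 1.0, "one_sample", estimate=0.0)
        t, p = sps.ttest_1samp(a, popmean)
        return TestResult(float(t), float(a.size - 1), float(p), "one_sample",
                          estimate=float(a.mean() - popmean))
    if kind == "two_sample":
        bv = np.asarray(b, dtype=float)
        if a.size < 2 or bv.size < 2:
            raise ValueError("two-sample test needs n >= 2 per group")
        t, p = sps.ttest_ind(a, bv, equal_var=True)
        return TestResult(float(t), float(a.size + bv.size - 2), float(p), "two_sample",
                          estimate=float(a.mean() - bv.mean()))
    raise ValueError(f"unknown t-test kind {kind!r}")


def pearson_with_p(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Pearson r with the two-sided p from t = r * sqrt((n-2)/(1-r^2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = sps.pearsonr(a, b)
    return TestResult(statistic=float(r), df=float(n - 2), p=float(p), kind="pearson",
                      estimate=float(r))


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj
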