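"""Group comparisons, correlations, and regression utilities.

The closed-form layer of the inferential chain: Welch t-tests, pooled one-way
ANOVA F recomputed from published-style group summaries (mean, SD, n),
two-by-two chi-square contrasts from proportions, partial correlations by the
residual method, standardized-beta multiple regression with variance-inflation
diagnostics, and covariate-adjusted (ANCOVA) group comparisons. Ordinary
least-squares fits go through statsmodels; the summary-statistic forms are
closed-form because only printed summaries, not raw data, are available for
published cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm


@dataclass(frozen=True)
class GroupSummary:
    """Published-style per-group summary of one variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


@dataclass
class RegressionResult:
    """Standardized-coefficient OLS fit with collinearity diagnostics."""

    standardized_betas: pd.Series
    coefficients: pd.Series
    p_values: pd.Series
    r_squared: float
    vif: pd.Series
    n_obs: int
    high_vif: tuple = field(default=())

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta_std": self.standardized_betas,
                "coef": self.coefficients,
                "p": self.p_values,
                "vif": self.vif,
            }
        )


def welch_t(x, y) -> tuple:
    """Welch's unequal-variance t-test with Satterthwaite degrees of freedom.

    Returns (t, df, p) for the two-sided test of equal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_f_from_summary(g1: GroupSummary, g2: GroupSummary) -> tuple:
    """Pooled-variance one-way ANOVA F for two groups from summary statistics.

    Equals the square of the pooled-variance t statistic, with df (1, n1+n2-2).
    This is the form that reproduces published two-group F columns computed
    from means and SDs.
    """
    n1, n2 = g1.n, g2.n
    sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled variance is zero; F is undefined")
    f = (g1.mean - g2.mean) ** 2 / (sp2 * (1 / n1 + 1 / n2))
    p = sps.f.sf(f, 1, n1 + n2 - 2)
    return float(f), float(p)


def chi2_from_proportions(p1: float, n1: int, p2: float, n2: int) -> tuple:
    """Pearson chi-square for a 2x2 table reconstructed from two proportions.

    Cell counts are the proportions times the group sizes rounded to the
    nearest integer; no continuity correction is applied (the convention that
    matches published values recomputed from percentages).
    """
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError("proportions must lie in [0, 1]")
    a, b = round(p1 * n1), round(p2 * n2)
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    expected = sps.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; chi-square approximation is poor",
                      stacklevel=2)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def partial_correlation(x, y, covariates=None) -> tuple:
    """Partial Pearson correlation of x and y given covariates.

    Residualizes x and y on [intercept | covariates] and correlates the
    residuals; p comes from the t distribution with n - k - 2 degrees of
    freedom (k covariates). With no covariates this is the plain bivariate
    Pearson correlation. Collinear covariate columns are dropped with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if n <= cov.shape[1] + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.hstack([np.ones((n, 1)), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("dropping collinear covariate columns", stacklevel=2)
        from .connectivity import _qr_drop_collinear

        q, _, _ = _qr_drop_collinear(design)
        design = q
        k = design.shape[1] - 1
    else:
        k = cov.shape[1]
    proj = design @ np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)[0]
    rx, ry = x - proj[:, 0], y - proj[:, 1]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    # a variable fully explained by the covariates has no residual variance
    # left to correlate: report 0 rather than 0/0
    r = float(rx @ ry / denom) if denom > 1e-12 * (np.linalg.norm(x) + 1) else 0.0
    df = n - k - 2
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(p)


def ols_standardized(
    outcome,
    regressors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    vif_threshold: float = 10.0,
) -> RegressionResult:
    """OLS with standardized (z-scored) variables and VIF diagnostics.

    All regressors, covariates and the outcome are z-scored, so the reported
    coefficients are standardized betas (invariant to linear rescaling of any
    variable). VIF_j = 1 / (1 - R^2_j) of regressor j on its peers; values
    above ``vif_threshold`` are flagged in ``high_vif``, not dropped.
    """
    X = pd.DataFrame(regressors).copy()
    if covariates is not None and len(pd.DataFrame(covariates).columns):
        X = pd.concat([X, pd.DataFrame(covariates)], axis=1)
    y = np.asarray(outcome, dtype=float)
    if X.columns.duplicated().any() or np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("rank-deficient design: duplicated or collinear regressors")

    def zscore(a):
        a = np.asarray(a, dtype=float)
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("constant variable cannot be standardized")
        return (a - a.mean()) / sd

    Xz = X.apply(zscore, axis=0)
    yz = zscore(y)
    design = sm.add_constant(Xz)
    fit_std = sm.OLS(yz, design).fit()
    fit_raw = sm.OLS(y, sm.add_constant(X.astype(float))).fit()

    vif = {}
    for j, col in enumerate(Xz.columns):
        others = Xz.drop(columns=[col])
        r2_j = sm.OLS(Xz[col], sm.add_constant(others)).fit().rsquared if len(
            others.columns
        ) else 0.0
        vif[col] = 1.0 / (1.0 - r2_j)
    vif = pd.Series(vif)
    high = tuple(vif.index[vif > vif_threshold])
    if high:
        warnings.warn(f"high variance inflation (>{vif_threshold}): {list(high)}",
                      stacklevel=2)
    return RegressionResult(
        standardized_betas=fit_std.params.drop("const"),
        coefficients=fit_raw.params.drop("const"),
        p_values=fit_std.pvalues.drop("const"),
        r_squared=float(fit_raw.rsquared),
        vif=vif,
        n_obs=len(y),
        high_vif=high,
    )


def ancova_group_compare(outcome, group, covariates=None) -> tuple:
    """Covariate-adjusted two-group comparison (ANCOVA partial F).

    Fits outcome ~ group + covariates and tests the group effect with the
    partial F from the nested-model residual-sum-of-squares comparison.
    Returns (F, p, adjusted_means) where adjusted means evaluate each group's
    prediction at the covariate means.
    """
    y = np.asarray(outcome, dtype=float)
    group = pd.Series(group).reset_index(drop=True)
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if (group.value_counts() < 1).any():
        raise ValueError("empty group")
    g = (group == levels[1]).astype(float).values
    if covariates is None:
        cov = np.empty((len(y), 0))
        cov_cols = []
    else:
        cov_df = pd.DataFrame(covariates).reset_index(drop=True)
        cov = cov_df.values.astype(float)
        cov_cols = list(cov_df.columns)
    X_full = sm.add_constant(np.column_stack([g, cov]) if cov.size else g[:, None])
    X_null = sm.add_constant(cov) if cov.size else np.ones((len(y), 1))
    fit_full = sm.OLS(y, X_full).fit()
    fit_null = sm.OLS(y, X_null).fit()
    df_resid = fit_full.df_resid
    num = fit_null.ssr - fit_full.ssr
    f = (num / 1.0) / (fit_full.ssr / df_resid) if fit_full.ssr > 0 else (
        0.0 if num <= 1e-300 else np.inf
    )
    f = max(f, 0.0)
    p = sps.f.sf(f, 1, df_resid)
    cov_means = cov.mean(axis=0) if cov.size else np.empty(0)
    adjusted = {}
    for val, lev in ((0.0, levels[0]), (1.0, levels[1])):
        row = np.concatenate([[1.0, val], cov_means])
        adjusted[lev] = float(row @ fit_full.params)
    _ = cov_cols
    return float(f), float(p), adjusted


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in the
    pipeline, which mirrors an uncorrected primary analysis)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
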