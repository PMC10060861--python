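"""Moderation (interaction) models with bootstrap CIs and Johnson-Neyman regions.

A moderation model regresses an outcome on a focal predictor, a moderator,
their product, and optional covariates:

    y = b0 + b1*f + b2*m + b3*(f*m) + c'x + e

The conditional effect of the focal predictor at moderator value w is
b1 + b3*w. The Johnson-Neyman boundaries are the moderator values where the
t statistic of that conditional effect crosses the critical value, i.e. the
real roots of

    (b1 + b3*w)^2 = t_crit^2 * [Var(b1) + 2*w*Cov(b1,b3) + w^2*Var(b3)],

a quadratic in w. The interaction coefficient's confidence interval comes
from a seeded case-resampling percentile bootstrap (BCa available as an
option). Focal and moderator are mean-centered before forming the product by
default, following the common social-science convention; centering changes
b1/b2 but not b3 or the Johnson-Neyman boundaries, which are always reported
on the original moderator scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm


@dataclass
class JohnsonNeymanRegion:
    """Roots and significance pattern of the conditional-effect t test."""

    boundaries: tuple
    moderator_range: tuple
    alpha: float
    #: one label per segment of the range split at the boundaries:
    #: "significant" or "not significant"
    segment_significance: tuple
    #: sign of the conditional effect (midpoint) per segment, 0 if n.s.
    segment_effect_sign: tuple

    @property
    def any_in_range(self) -> bool:
        return len(self.boundaries) > 0

    def describe(self) -> str:
        if not self.any_in_range:
            state = self.segment_significance[0]
            return f"conditional effect {state} across the whole moderator range"
        parts = []
        lo, hi = self.moderator_range
        edges = (lo, *self.boundaries, hi)
        for k, sig in enumerate(self.segment_significance):
            parts.append(f"[{edges[k]:.3g}, {edges[k + 1]:.3g}]: {sig}")
        return "; ".join(parts)


class ModerationModel:
    """Interaction regression of ``outcome`` on focal x moderator.

    Parameters
    ----------
    outcome, focal, moderator : array-like
        Observations; no missing values (drop beforehand).
    covariates : DataFrame or array-like, optional
    center : bool
        Mean-center focal and moderator before forming the product
        (default True).
    standardize : bool
        Additionally scale focal and moderator to unit variance. Useful when
        coefficients were planted on z-scored predictors.
    """

    def __init__(self, outcome, focal, moderator, covariates=None, *,
                 center: bool = True, standardize: bool = False):
        y = np.asarray(outcome, dtype=float)
        f = np.asarray(focal, dtype=float)
        m = np.asarray(moderator, dtype=float)
        if not (len(y) == len(f) == len(m)):
            raise ValueError("outcome, focal and moderator must have equal length")
        if covariates is None:
            cov = np.empty((len(y), 0))
            self.covariate_names = []
        else:
            cov_df = pd.DataFrame(covariates).reset_index(drop=True)
            cov = cov_df.values.astype(float)
            self.covariate_names = [str(c) for c in cov_df.columns]
        n_params = 4 + cov.shape[1]
        if len(y) <= n_params + 2:
            raise ValueError(f"need n > {n_params + 2} observations")
        self._moderator_raw = m.copy()
        self._f_shift = f.mean() if center or standardize else 0.0
        self._m_shift = m.mean() if center or standardize else 0.0
        self._f_scale = f.std(ddof=1) if standardize else 1.0
        self._m_scale = m.std(ddof=1) if standardize else 1.0
        if self._f_scale == 0 or self._m_scale == 0:
            raise ValueError("focal/moderator must not be constant")
        self.y = y
        self.f = (f - self._f_shift) / self._f_scale
        self.m = (m - self._m_shift) / self._m_scale
        self.cov = cov
        self.exog_names = ["const", "focal", "moderator", "interaction", *self.covariate_names]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, focal: str,
                       moderator: str, covariates=(), **kwargs) -> "ModerationModel":
        cols = [outcome, focal, moderator, *covariates]
        data = df[cols].dropna()
        return cls(
            data[outcome], data[focal], data[moderator],
            covariates=data[list(covariates)] if covariates else None, **kwargs,
        )

    # -- design -------------------------------------------------------------
    def _design(self, f=None, m=None, cov=None) -> np.ndarray:
        f = self.f if f is None else f
        m = self.m if m is None else m
        cov = self.cov if cov is None else cov
        cols = [np.ones(len(f)), f, m, f * m]
        return np.column_stack(cols + ([cov] if cov.size else []))

    def fit(self, n_boot: int = 5000, ci_level: float = 0.95, seed=None,
            boot_method: str = "percentile") -> "ModerationResults":
        """OLS fit plus a case-resampling bootstrap CI for the interaction.

        Degenerate bootstrap designs (rank-deficient resamples) are redrawn
        and counted. ``boot_method`` is ``"percentile"`` (default) or
        ``"bca"``.
        """
        X = self._design()
        fit = sm.OLS(self.y, X).fit()
        boot_b3, n_redrawn = self._bootstrap_interaction(n_boot, seed)
        alpha = 1 - ci_level
        if boot_method == "percentile":
            lo, hi = np.quantile(boot_b3, [alpha / 2, 1 - alpha / 2])
        elif boot_method == "bca":
            lo, hi = self._bca_interval(boot_b3, fit.params[3], alpha)
        else:
            raise ValueError(f"unknown boot_method {boot_method!r}")
        return ModerationResults(
            model=self,
            params=pd.Series(fit.params, index=self.exog_names),
            bse=pd.Series(fit.bse, index=self.exog_names),
            pvalues=pd.Series(fit.pvalues, index=self.exog_names),
            cov_params=pd.DataFrame(fit.cov_params(), index=self.exog_names,
                                    columns=self.exog_names),
            df_resid=int(fit.df_resid),
            r_squared=float(fit.rsquared),
            bootstrap_ci=(float(lo), float(hi)),
            bootstrap_samples=boot_b3,
            n_boot=n_boot,
            ci_level=ci_level,
            n_redrawn=n_redrawn,
            boot_method=boot_method,
        )

    def _bootstrap_interaction(self, n_boot: int, seed) -> tuple:
        """Vectorized case-resampling bootstrap of the interaction coefficient."""
        rng = np.random.default_rng(seed)
        X = self._design()
        n, p = X.shape
        out = np.empty(n_boot)
        pending = np.arange(n_boot)
        n_redrawn = 0
        while pending.size:
            idx = rng.integers(0, n, size=(pending.size, n))
            Xb = X[idx]                       # (reps, n, p)
            yb = self.y[idx]                  # (reps, n)
            xtx = np.einsum("rij,rik->rjk", Xb, Xb)
            xty = np.einsum("rij,ri->rj", Xb, yb)
            # guard against rank-deficient resamples before solving
            smallest = np.linalg.eigvalsh(xtx)[:, 0]
            ok = smallest > 1e-8 * np.linalg.eigvalsh(xtx)[:, -1]
            bad = ~ok
            if ok.any():
                beta = np.linalg.solve(xtx[ok], xty[ok][..., None])[..., 0]
                out[pending[ok]] = beta[:, 3]
            n_redrawn += int(bad.sum())
            pending = pending[bad]
        if n_redrawn:
            warnings.warn(f"redrew {n_redrawn} degenerate bootstrap resample(s)",
                          stacklevel=2)
        return out, n_redrawn

    def _bca_interval(self, boot: np.ndarray, theta_hat: float, alpha: float) -> tuple:
        """Bias-corrected and accelerated interval for the interaction."""
        z0 = sps.norm.ppf(np.clip(np.mean(boot < theta_hat), 1e-9, 1 - 1e-9))
        X = self._design()
        n = len(self.y)
        theta_jack = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            theta_jack[i] = np.linalg.lstsq(X[mask], self.y[mask], rcond=None)[0][3]
        d = theta_jack.mean() - theta_jack
        denom = 6.0 * (d**2).sum() ** 1.5
        a = (d**3).sum() / denom if denom > 0 else 0.0
        z = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
        adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        return tuple(np.quantile(boot, adj))


@dataclass
class ModerationResults:
    """Estimates, uncertainties and diagnostics of a fitted moderation model."""

    model: ModerationModel
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame = field(repr=False)
    df_resid: int
    r_squared: float
    bootstrap_ci: tuple
    bootstrap_samples: np.ndarray = field(repr=False)
    n_boot: int
    ci_level: float
    n_redrawn: int
    boot_method: str

    @property
    def interaction(self) -> float:
        return float(self.params["interaction"])

    def conditional_effect(self, moderator_value) -> np.ndarray:
        """b1 + b3*w at moderator values on the *original* scale."""
        w = (np.asarray(moderator_value, dtype=float) - self.model._m_shift) / self.model._m_scale
        return self.params["focal"] + self.interaction * w

    def conditional_effect_se(self, moderator_value) -> np.ndarray:
        w = (np.asarray(moderator_value, dtype=float) - self.model._m_shift) / self.model._m_scale
        v11 = self.cov_params.loc["focal", "focal"]
        v13 = self.cov_params.loc["focal", "interaction"]
        v33 = self.cov_params.loc["interaction", "interaction"]
        return np.sqrt(v11 + 2 * w * v13 + w**2 * v33)

    def johnson_neyman(self, moderator_range=None, alpha: float = 0.05) -> JohnsonNeymanRegion:
        """Johnson-Neyman boundaries of the conditional-effect significance.

        Solves the boundary quadratic and reports real roots inside
        ``moderator_range`` (default: observed moderator range), with the
        significance and effect sign on each segment. With a zero interaction
        the conditional effect's significance cannot change, so no boundary
        is returned.
        """
        if moderator_range is None:
            raw = self.model._moderator_raw
            moderator_range = (float(raw.min()), float(raw.max()))
        lo, hi = moderator_range
        if not lo < hi:
            raise ValueError("moderator_range must be an increasing pair")
        v11 = float(self.cov_params.loc["focal", "focal"])
        v13 = float(self.cov_params.loc["focal", "interaction"])
        v33 = float(self.cov_params.loc["interaction", "interaction"])
        cov33 = np.array([[v11, v13], [v13, v33]])
        # semidefinite is allowed: a known-zero interaction has Var(b3) = 0
        if np.linalg.eigvalsh(cov33)[0] < -1e-10 * max(v11, v33, 1e-300):
            raise ValueError("coefficient covariance is not positive definite")
        b1, b3 = float(self.params["focal"]), self.interaction
        t_crit = sps.t.ppf(1 - alpha / 2, self.df_resid)
        # quadratic in centered/scaled moderator w: A w^2 + B w + C = 0
        A = b3**2 - t_crit**2 * v33
        B = 2 * (b1 * b3 - t_crit**2 * v13)
        C = b1**2 - t_crit**2 * v11
        roots = []
        if abs(A) > 1e-300:
            disc = B**2 - 4 * A * C
            if disc >= 0:
                sq = np.sqrt(disc)
                roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
        elif abs(B) > 1e-300:
            roots = [-C / B]
        # back to the original moderator scale
        roots = sorted(r * self.model._m_scale + self.model._m_shift for r in roots)
        in_range = tuple(r for r in roots if lo < r < hi)
        edges = (lo, *in_range, hi)
        sigs, signs = [], []
        for k in range(len(edges) - 1):
            mid = (edges[k] + edges[k + 1]) / 2.0
            eff = float(self.conditional_effect(mid))
            t = eff / float(self.conditional_effect_se(mid))
            sig = abs(t) > t_crit
            sigs.append("significant" if sig else "not significant")
            signs.append(int(np.sign(eff)) if sig else 0)
        return JohnsonNeymanRegion(
            boundaries=in_range,
            moderator_range=(lo, hi),
            alpha=alpha,
            segment_significance=tuple(sigs),
            segment_effect_sign=tuple(signs),
        )

    def summary(self) -> str:
        lines = [
            "Moderation model (OLS with focal x moderator interaction)",
            f"n = {len(self.model.y)}, R^2 = {self.r_squared:.4f}, "
            f"df_resid = {self.df_resid}",
            "",
            f"{'term':<22}{'coef':>12}{'se':>12}{'p':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{self.pvalues[name]:>12.4g}"
            )
        lo, hi = self.bootstrap_ci
        lines += [
            "",
            f"interaction {int(self.ci_level * 100)}% {self.boot_method} bootstrap CI "
            f"({self.n_boot} resamples): [{lo:.4f}, {hi:.4f}]",
        ]
        jn = self.johnson_neyman()
        lines.append(f"Johnson-Neyman: {jn.describe()}")
        return "\n".join(lines)

    def plot_johnson_neyman(self, ax=None, alpha: float = 0.05, n_grid: int = 200):
        """Conditional effect of the focal predictor vs the moderator, with
        pointwise confidence band and Johnson-Neyman boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        raw = self.model._moderator_raw
        grid = np.linspace(raw.min(), raw.max(), n_grid)
        eff = self.conditional_effect(grid)
        se = self.conditional_effect_se(grid)
        t_crit = sps.t.ppf(1 - alpha / 2, self.df_resid)
        ax.plot(grid, eff, label="conditional effect")
        ax.fill_between(grid, eff - t_crit * se, eff + t_crit * se, alpha=0.25)
        ax.axhline(0.0, color="k", lw=0.8)
        for b in self.johnson_neyman(alpha=alpha).boundaries:
            ax.axvline(b, ls="--", color="r")
        ax.set_xlabel("moderator")
        ax.set_ylabel("conditional effect of focal predictor")
        ax.legend()
        return ax


def fit_moderation(outcome, focal, moderator, covariates=None, n_boot: int = 5000,
                   ci_level: float = 0.95, seed=None, **kwargs) -> ModerationResults:
    """Functional shorthand for ``ModerationModel(...).fit(...)``."""
    model = ModerationModel(outcome, focal, moderator, covariates=covariates, **kwargs)
    return model.fit(n_boot=n_boot, ci_level=ci_level, seed=seed)
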