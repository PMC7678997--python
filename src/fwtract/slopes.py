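"""Subject-specific verbal-fluency slopes from a linear mixed model.

The trajectory model is

    score_ij = (mu0 + b0_i) + (mu1 + b1_i) * t_ij + eps_ij

with correlated random intercept b0_i and random slope b1_i per subject and
Gaussian residuals, fitted by restricted maximum likelihood. A subject's
annual slope is the fixed slope plus the best linear unbiased prediction
(BLUP) of their random slope. Two-stage per-subject ordinary least squares
slopes are carried alongside as a cross-check.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["IstSlopeModel", "SlopeResults", "fit_lmm_slopes", "ols_slopes"]

SCORE_COLUMNS = ("ist15", "ist30", "ist60")


def ols_slopes(data: pd.DataFrame, score: str, time_col: str = "time_years") -> pd.Series:
    """Per-subject ordinary least squares slope of one score (two-stage
    estimator, no pooling). Subjects with < 2 visits come back NaN."""
    def _slope(g):
        if g[time_col].nunique() < 2:
            return np.nan
        t = g[time_col].to_numpy()
        y = g[score].to_numpy()
        return np.polyfit(t, y, 1)[0]

    return data.groupby("subject").apply(_slope, include_groups=False)


class SlopeResults:
    """Fitted slopes for one or more scores.

    Attributes
    ----------
    subject_slopes : DataFrame indexed by subject, one column per score;
        each entry is fixed slope + BLUP of the subject's random slope.
    ols_slopes : same layout, two-stage per-subject OLS cross-check.
    fixed : dict score -> (intercept, slope) fixed effects.
    variance_components : dict score -> dict with intercept_sd, slope_sd,
        correlation, resid_sd.
    converged, fallback_independent : dict score -> bool; a singular joint
        random-effect covariance triggers a refit with independent random
        effects rather than an exception.
    llf : dict score -> restricted log-likelihood.
    """

    def __init__(self):
        self.subject_slopes = pd.DataFrame()
        self.ols_slopes = pd.DataFrame()
        self.fixed = {}
        self.variance_components = {}
        self.converged = {}
        self.fallback_independent = {}
        self.llf = {}
        self.dropped_subjects = {}

    def summary(self) -> str:
        lines = ["Linear mixed model: score ~ time, random intercept + slope (REML)"]
        for score, (b0, b1) in self.fixed.items():
            vc = self.variance_components[score]
            lines.append(
                f"{score}: fixed intercept {b0:.3f}, fixed slope {b1:.4f} /year; "
                f"sd(intercept) {vc['intercept_sd']:.3f}, sd(slope) {vc['slope_sd']:.3f}, "
                f"corr {vc['correlation']:.2f}, sd(resid) {vc['resid_sd']:.3f}"
                + ("" if self.converged[score] else "  [not converged]")
                + ("  [independent RE fallback]" if self.fallback_independent[score] else "")
            )
        return "\n".join(lines)


class IstSlopeModel:
    """Mixed model for long-format fluency data.

    Parameters
    ----------
    data : DataFrame with columns ``subject``, ``time_years`` and one or
        more score columns (default ist15/ist30/ist60). Missing visits are
        allowed; rows with a missing score are dropped per score, and a
        subject with no usable rows is excluded and logged in the results.
    """

    def __init__(self, data: pd.DataFrame, scores: tuple = SCORE_COLUMNS, time_col: str = "time_years"):
        required = {"subject", time_col}
        if not required <= set(data.columns):
            raise ValueError(f"data needs columns {sorted(required)}")
        self.scores = tuple(s for s in scores if s in data.columns)
        if not self.scores:
            raise ValueError("no score columns present")
        if data["subject"].nunique() < 10:
            raise ValueError("need at least 10 subjects for the mixed model")
        self.data = data
        self.time_col = time_col

    @classmethod
    def from_csv(cls, path, **kwargs) -> "IstSlopeModel":
        return cls(pd.read_csv(path), **kwargs)

    def _fit_one(self, score: str, res: SlopeResults) -> pd.Series:
        cols = ["subject", self.time_col, score]
        d = self.data[cols].dropna().rename(columns={self.time_col: "time"})
        usable = d.groupby("subject").size()
        res.dropped_subjects[score] = sorted(
            set(self.data["subject"].unique()) - set(usable.index)
        )

        # degenerate zero-residual data (every trajectory exactly linear)
        # makes the REML problem singular; the per-subject OLS solution is
        # then exact and is returned directly
        sse = 0.0
        ints, slps = [], []
        for _, g in d.groupby("subject"):
            if g["time"].nunique() < 2:
                sse = np.inf
                break
            coef = np.polyfit(g["time"], g[score], 1)
            slps.append(coef[0])
            ints.append(coef[1])
            sse += float(((np.polyval(coef, g["time"]) - g[score]) ** 2).sum())
        yscale = max(float(d[score].var()), 1e-30)
        if np.isfinite(sse) and sse < 1e-18 * yscale * len(d):
            ints, slps = np.asarray(ints), np.asarray(slps)
            res.fallback_independent[score] = False
            res.converged[score] = True
            res.llf[score] = np.inf
            res.fixed[score] = (float(ints.mean()), float(slps.mean()))
            corr = float(np.corrcoef(ints, slps)[0, 1]) if ints.std() > 0 and slps.std() > 0 else 0.0
            res.variance_components[score] = {
                "intercept_sd": float(ints.std(ddof=1)),
                "slope_sd": float(slps.std(ddof=1)),
                "correlation": corr,
                "resid_sd": 0.0,
            }
            groups = [g for g, _ in d.groupby("subject")]
            return pd.Series(dict(zip(groups, slps)), name=score)

        def run(free):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = smf.mixedlm(f"{score} ~ time", d, groups=d["subject"], re_formula="~time")
                return m, m.fit(reml=True, method=["lbfgs", "powell"], free=free)

        model, fit = run(None)
        fallback = False
        cov = fit.cov_re.to_numpy()
        # near-singular joint covariance: refit with independent effects
        if not np.all(np.linalg.eigvalsh(cov) > 1e-10 * max(cov.max(), 1e-12)):
            free = sm.regression.mixed_linear_model.MixedLMParams.from_components(
                fe_params=np.ones(2), cov_re=np.eye(2)
            )
            model, fit = run(free)
            fallback = True
        res.fallback_independent[score] = fallback
        res.converged[score] = bool(fit.converged)
        res.llf[score] = float(fit.llf)
        res.fixed[score] = (float(fit.fe_params.iloc[0]), float(fit.fe_params.iloc[1]))

        cov = fit.cov_re.to_numpy() * fit.scale
        sd_i, sd_s = np.sqrt(max(cov[0, 0], 0.0)), np.sqrt(max(cov[1, 1], 0.0))
        corr = cov[0, 1] / (sd_i * sd_s) if sd_i > 0 and sd_s > 0 else 0.0
        res.variance_components[score] = {
            "intercept_sd": sd_i,
            "slope_sd": sd_s,
            "correlation": float(np.clip(corr, -1.0, 1.0)),
            "resid_sd": float(np.sqrt(fit.scale)),
        }
        blup = {g: re.iloc[1] for g, re in fit.random_effects.items()}
        fixed_slope = fit.fe_params.iloc[1]
        return pd.Series({g: fixed_slope + b for g, b in blup.items()}, name=score)

    def fit(self) -> SlopeResults:
        res = SlopeResults()
        slope_cols, ols_cols = [], []
        for score in self.scores:
            slope_cols.append(self._fit_one(score, res))
            ols_cols.append(ols_slopes(self.data, score, self.time_col).rename(score))
        res.subject_slopes = pd.concat(slope_cols, axis=1).sort_index()
        res.subject_slopes.index.name = "subject"
        res.ols_slopes = pd.concat(ols_cols, axis=1).sort_index()
        res.ols_slopes.index.name = "subject"
        return res


def fit_lmm_slopes(data: pd.DataFrame, scores: tuple = SCORE_COLUMNS) -> SlopeResults:
    """Convenience wrapper: ``IstSlopeModel(data, scores).fit()``."""
    return IstSlopeModel(data, scores=scores).fit()
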