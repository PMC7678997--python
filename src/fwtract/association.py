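"""Association layer: bivariate screens, paired comparisons, adjusted
standardized-coefficient regressions and false-discovery-rate control.

This mirrors a common observational-neuroimaging analysis: nonparametric
screens (Spearman, Mann-Whitney) of covariates, a paired t-test contrasting
conventional against free-water-corrected tract measures, ordinary least
squares of fluency slopes on standardized diffusion measures adjusted for
age and bundle volume (optionally lesion load, optionally a joint model with
two simultaneous predictors), with Benjamini-Hochberg correction per results
family.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tractometry import percent_change

__all__ = [
    "TestResult",
    "RegressionResult",
    "bivariate_screen",
    "paired_compare",
    "adjusted_regression",
    "fdr_adjust",
    "measure_contrast_table",
    "slope_association_table",
]

# maximum sample size for exhaustive-permutation Spearman p-values; above
# this the t-approximation is used (n! explodes quickly)
_SPEARMAN_EXACT_N = 7


@dataclasses.dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple | int
    direction: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclasses.dataclass
class RegressionResult:
    """OLS of a standardized outcome on standardized predictors of interest
    plus unstandardized covariates."""

    outcome: str
    predictors: list
    covariates: list
    beta: dict  # predictor -> standardized coefficient
    raw_coef: dict
    std_err: dict
    p_value: dict
    r_squared: float
    adj_r_squared: float
    n: int

    def summary(self) -> str:
        rows = [
            f"OLS: z({self.outcome}) ~ "
            + " + ".join(f"z({p})" for p in self.predictors)
            + ("" if not self.covariates else " + " + " + ".join(self.covariates)),
            f"n = {self.n}   R^2 = {self.r_squared:.3f}   adj R^2 = {self.adj_r_squared:.3f}",
        ]
        for p in self.predictors:
            rows.append(
                f"  {p}: beta = {self.beta[p]:+.3f}  se = {self.std_err[p]:.3f}  "
                f"p = {self.p_value[p]:.4g}"
            )
        return "\n".join(rows)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by exhaustive enumeration of all n! rank orderings of y
    against the observed ranks of x."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = stats.pearsonr(rx, ry[list(perm)]).statistic
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def bivariate_screen(x, y, kind: str = "spearman") -> TestResult:
    """Nonparametric bivariate screen.

    kind="spearman": rank correlation of two numeric vectors; ties get
    average ranks; the two-sided p comes from exhaustive permutation for
    n <= 7 and from the t-approximation above that.

    kind="mannwhitney": x is split by binary group labels y; the U of the
    first group is returned with an exact p for small untied samples and a
    tie-corrected continuity-corrected normal approximation otherwise.
    """
    if kind == "spearman":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 4:
            raise ValueError("spearman needs two equal-length vectors, n >= 4")
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValueError("spearman correlation undefined for a constant input")
        rho = float(stats.spearmanr(x, y).statistic)
        if x.size <= _SPEARMAN_EXACT_N:
            p = _spearman_exact_p(x, y, rho)
        else:
            p = float(stats.spearmanr(x, y).pvalue)
        return TestResult("spearman", rho, p, int(x.size), "positive" if rho >= 0 else "negative")

    if kind == "mannwhitney":
        x = np.asarray(x, dtype=float)
        labels = np.asarray(y)
        groups = np.unique(labels)
        if groups.size != 2:
            raise ValueError("mannwhitney needs exactly two groups")
        a = x[labels == groups[0]]
        b = x[labels == groups[1]]
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be nonempty")
        has_ties = np.unique(x).size < x.size
        method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
        direction = "first-higher" if res.statistic > a.size * b.size / 2 else "first-lower"
        return TestResult("mannwhitney", float(res.statistic), float(res.pvalue), (int(a.size), int(b.size)), direction)

    raise ValueError(f"unknown screen kind {kind!r}")


def paired_compare(before, after) -> TestResult:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)) on d = after - before,
    two-sided p on n - 1 degrees of freedom."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size < 3:
        raise ValueError("paired test needs equal-length vectors, n >= 3")
    d = after - before
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if np.all(d == 0):  # identical vectors: null difference, no evidence
            return TestResult("paired-t", 0.0, 1.0, int(n), "none")
        raise ValueError("degenerate paired test: nonzero differences with zero variance")
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return TestResult("paired-t", float(t), p, int(n), "increase" if t > 0 else "decrease")


def adjusted_regression(
    data: pd.DataFrame,
    outcome: str,
    predictors: str | list,
    covariates: list = (),
) -> RegressionResult:
    """OLS of the z-scored outcome on z-scored predictors of interest with
    covariates entered on their raw scale, so the predictor coefficients are
    standardized (beta) coefficients "adjusted for" the covariates.

    Supports several simultaneous predictors (e.g. a joint free-water +
    corrected-MD model). An exactly collinear design raises and names the
    dependent columns.
    """
    predictors = [predictors] if isinstance(predictors, str) else list(predictors)
    covariates = list(covariates)
    cols = [outcome] + predictors + covariates
    d = data[cols].dropna()
    n = len(d)
    if n <= len(predictors) + len(covariates) + 2:
        raise ValueError("too few complete rows for the requested model")

    def z(s):
        sd = s.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {s.name!r} is constant; cannot standardize")
        return (s - s.mean()) / sd

    X = pd.concat([z(d[p]) for p in predictors] + [d[c] for c in covariates], axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = []
        M = X.to_numpy()
        for j, name in enumerate(X.columns):
            rest = np.delete(M, j, axis=1)
            resid = M[:, j] - rest @ np.linalg.lstsq(rest, M[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(M[:, j]), 1.0):
                bad.append(str(name))
        raise ValueError(f"collinear design; dependent columns: {bad}")

    fit = sm.OLS(z(d[outcome]).to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    sd_y = d[outcome].std(ddof=1)
    beta, raw, se, pv = {}, {}, {}, {}
    for p in predictors:
        j = names.index(p)
        beta[p] = float(fit.params[j])
        raw[p] = float(fit.params[j] * sd_y / d[p].std(ddof=1))
        se[p] = float(fit.bse[j])
        pv[p] = float(fit.pvalues[j])
    return RegressionResult(
        outcome=outcome,
        predictors=predictors,
        covariates=covariates,
        beta=beta,
        raw_coef=raw,
        std_err=se,
        p_value=pv,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=n,
    )


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q.

    Returns (reject flags, monotone adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

MEASURE_PAIRS = (("fa", "fat"), ("md", "mdt"), ("rd", "rdt"), ("ad", "adt"))


def measure_contrast_table(cohort: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Conventional vs FW-corrected tract measures: means, paired t, FDR p
    over the four paired tests, and the cohort mean and SD of per-subject
    percent change."""
    rows = []
    for conv, corr in MEASURE_PAIRS:
        t = paired_compare(cohort[conv], cohort[corr])
        pc = np.array([percent_change(c, k) for c, k in zip(cohort[conv], cohort[corr])])
        rows.append(
            {
                "measure": conv.upper(),
                "dti_mean": cohort[conv].mean(),
                "dti_sd": cohort[conv].std(ddof=1),
                "fw_corrected_mean": cohort[corr].mean(),
                "fw_corrected_sd": cohort[corr].std(ddof=1),
                "paired_t": t.statistic,
                "p_raw": t.p_value,
                "pct_change_mean": pc.mean(),
                "pct_change_sd": pc.std(ddof=1),
            }
        )
    out = pd.DataFrame(rows)
    out["reject_fdr"], out["p_fdr"] = fdr_adjust(out["p_raw"].to_numpy(), q)
    out.loc[len(out)] = {
        "measure": "FW",
        "fw_corrected_mean": cohort["fw"].mean(),
        "fw_corrected_sd": cohort["fw"].std(ddof=1),
    }
    return out


ASSOCIATION_FAMILIES = {
    "dti": ("fa", "md", "ad", "rd"),
    "fw_corrected": ("fat", "mdt", "adt", "rdt", "fw"),
}


def slope_association_table(
    cohort: pd.DataFrame,
    scores: tuple = ("slope_ist15", "slope_ist30", "slope_ist60"),
    covariates: tuple = ("age", "cingulum_volume_pct_tiv"),
    extra_covariates: tuple = (),
    families: dict | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Standardized-coefficient regressions of fluency slopes on each tract
    measure, adjusted for the covariates, FDR-corrected per family.

    ``extra_covariates`` allows the lesion-adjusted variants (total or
    bundle-specific lesion load added to every model).
    """
    families = ASSOCIATION_FAMILIES if families is None else families
    rows = []
    for family, measures in families.items():
        for m in measures:
            for score in scores:
                r = adjusted_regression(cohort, score, m, list(covariates) + list(extra_covariates))
                rows.append(
                    {
                        "family": family,
                        "measure": m,
                        "score": score,
                        "beta": r.beta[m],
                        "r_squared": r.r_squared,
                        "p_raw": r.p_value[m],
                        "n": r.n,
                    }
                )
    out = pd.DataFrame(rows)
    out["reject_fdr"] = False
    out["p_fdr"] = np.nan
    for family in out["family"].unique():
        mask = out["family"] == family
        rej, padj = fdr_adjust(out.loc[mask, "p_raw"].to_numpy(), q)
        out.loc[mask, "reject_fdr"] = rej
        out.loc[mask, "p_fdr"] = padj
    return out


def joint_fw_mdt(
    cohort: pd.DataFrame,
    scores: tuple = ("slope_ist15", "slope_ist30", "slope_ist60"),
    covariates: tuple = ("age", "cingulum_volume_pct_tiv"),
    extra_covariates: tuple = (),
) -> pd.DataFrame:
    """Joint model: free-water content and corrected mean diffusivity entered
    together, testing their independent contributions to each slope."""
    rows = []
    for score in scores:
        r = adjusted_regression(cohort, score, ["fw", "mdt"], list(covariates) + list(extra_covariates))
        for m in ("fw", "mdt"):
            rows.append(
                {
                    "score": score,
                    "predictor": m,
                    "beta": r.beta[m],
                    "p_raw": r.p_value[m],
                    "r_squared": r.r_squared,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)
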