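"""Descriptive statistics around the screening model.

CES cutoff grouping (high: CES > 20, low: CES < 10), Pearson correlation
matrices with significance and magnitude bands, OLS regression of CES on the
seven observed variables with multicollinearity diagnostics (VIF and
tolerance = 1/VIF), and two-sample t-tests (pooled and Welch) computable from
raw vectors or from printed summary statistics (mean, sd, n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import CollinearityError, UndefinedStatisticError, ValidationError
from .scoring import FEATURE_COLUMNS

__all__ = [
    "RegressionResult",
    "TTestResult",
    "assign_groups",
    "pearson_matrix",
    "ols_with_vif",
    "two_sample_t",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Significance markers: **** <1e-4, *** <1e-3, ** <0.01, * <0.05."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


def assign_groups(
    cohort: pd.DataFrame, high_cut: int = 20, low_cut: int = 10
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label participants by CES cutoffs: high (CES > high_cut), low (CES < low_cut).

    Scores between the cutoffs (inclusive) fall in neither group. Returns the
    labelled table (new ``ces_group`` column: "high"/"low"/"") and counts.
    """
    if low_cut >= high_cut:
        raise ValidationError("low cutoff must be below high cutoff")
    if "ces" not in cohort.columns:
        raise ValidationError("cohort table has no 'ces' column")
    out = cohort.copy()
    ces = out["ces"]
    out["ces_group"] = np.select([ces > high_cut, ces < low_cut], ["high", "low"], default="")
    counts = {
        "high": int((out["ces_group"] == "high").sum()),
        "low": int((out["ces_group"] == "low").sum()),
        "unassigned": int((out["ces_group"] == "").sum()),
    }
    return out, counts


def pearson_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p-values and magnitude bands.

    p-values use the t transform with n-2 df. Bands: |r| < 0.3 low,
    0.3 <= |r| < 0.6 medium, else high. Zero-variance columns yield NaN r
    with band "undefined".
    """
    cols = columns or [c for c in ["ces"] + FEATURE_COLUMNS if c in table.columns]
    data = table[cols].dropna()
    n = len(data)
    if n < 3:
        raise ValidationError("need at least 3 complete rows for correlations")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    band = pd.DataFrame("", index=cols, columns=cols)
    sds = data.std(ddof=1)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            if sds[a] == 0 or sds[b] == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(data[a], data[b])
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
            lab = (
                "undefined"
                if np.isnan(rij)
                else "low" if abs(rij) < 0.3 else "medium" if abs(rij) < 0.6 else "high"
            )
            band.loc[a, b] = band.loc[b, a] = lab
    return {"r": r, "p": p, "band": band, "n": n}


@dataclass
class RegressionResult:
    """OLS of CES on the seven predictors with multicollinearity diagnostics."""

    table: pd.DataFrame  # per predictor: beta_std, t, p, ci_low, ci_high, tolerance, vif
    f_statistic: float
    df_model: int
    df_resid: int
    r_squared: float
    p_value: float


def ols_with_vif(y: pd.Series | np.ndarray, X: pd.DataFrame) -> RegressionResult:
    """Least-squares regression with intercept, standardized betas, VIF/tolerance.

    t statistics and 95% CIs come from the raw-scale fit; standardized betas
    rescale the raw coefficients by sd(x)/sd(y). VIF_j = 1/(1 - R_j^2) from
    regressing predictor j on the others; tolerance = 1/VIF.
    """
    yv = np.asarray(y, dtype=float)
    Xd = X.astype(float)
    n, k = Xd.shape
    if n <= k + 1:
        raise ValidationError(f"need n > {k + 1} rows, got {n}")
    if np.isnan(yv).any() or Xd.isna().any().any():
        raise ValidationError("missing values in regression inputs")
    if np.linalg.matrix_rank(Xd.to_numpy()) < k:
        corr = np.corrcoef(Xd.to_numpy(), rowvar=False)
        dep = [Xd.columns[i] for i in range(k) if (np.abs(corr[i]) > 1 - 1e-10).sum() > 1]
        raise CollinearityError(f"design matrix is rank deficient; dependent columns {dep}")

    design = sm.add_constant(Xd)
    fit = sm.OLS(yv, design).fit()
    ci = fit.conf_int(alpha=0.05)
    sd_y = yv.std(ddof=1)
    sd_x = Xd.std(ddof=1)
    vifs = np.array([variance_inflation_factor(design.to_numpy(), i + 1) for i in range(k)])
    table = pd.DataFrame(
        {
            "beta_std": fit.params[Xd.columns] * sd_x / sd_y,
            "t": fit.tvalues[Xd.columns],
            "p": fit.pvalues[Xd.columns],
            "ci_low": ci.loc[Xd.columns, 0],
            "ci_high": ci.loc[Xd.columns, 1],
            "vif": vifs,
        }
    )
    table["tolerance"] = 1.0 / table["vif"]
    table["stars"] = table["p"].map(significance_stars)
    return RegressionResult(
        table=table,
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
    )


@dataclass
class TTestResult:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    variant: str  # "pooled" | "welch"


def _summaries(x: np.ndarray) -> tuple[float, float, int]:
    return float(np.mean(x)), float(np.std(x, ddof=1)), len(x)


def two_sample_t(
    group1: np.ndarray | tuple[float, float, int],
    group2: np.ndarray | tuple[float, float, int],
    variant: str = "auto",
    alpha: float = 0.05,
) -> TTestResult:
    """Independent two-sample t-test from raw vectors or (mean, sd, n) summaries.

    pooled: df = n1 + n2 - 2 with pooled variance. welch: Satterthwaite df.
    auto: Welch when a two-sided F-test of variance equality rejects at the
    5% level, else pooled (the convention of mainstream statistics software).
    The 95% CI is diff +/- t_{0.975, df} * SE.
    """
    m1, s1, n1 = group1 if isinstance(group1, tuple) else _summaries(np.asarray(group1, float))
    m2, s2, n2 = group2 if isinstance(group2, tuple) else _summaries(np.asarray(group2, float))
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValidationError("standard deviations must be nonnegative")
    if s1 == 0 and s2 == 0:
        raise UndefinedStatisticError("both groups have zero variance; t undefined")

    if variant == "auto":
        f = (s1**2) / (s2**2) if s2 > 0 else np.inf
        p_var = 2.0 * min(
            sps.f.cdf(f, n1 - 1, n2 - 1), sps.f.sf(f, n1 - 1, n2 - 1)
        )
        variant = "welch" if p_var < alpha else "pooled"
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")

    diff = m1 - m2
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if se == 0:
        raise UndefinedStatisticError("zero standard error; t undefined")
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return TTestResult(
        mean1=m1, sd1=s1, n1=n1, mean2=m2, sd2=s2, n2=n2,
        t=float(t), df=float(df), p=float(p),
        ci_low=float(diff - tcrit * se), ci_high=float(diff + tcrit * se),
        variant=variant,
    )


def group_ttest_table(
    cohort: pd.DataFrame,
    group_col: str,
    group_a: str,
    group_b: str,
    variables: list[str] | None = None,
    variant: str = "auto",
) -> pd.DataFrame:
    """Per-variable two-sample t-tests between two labelled groups."""
    variables = variables or ["ces"] + FEATURE_COLUMNS
    a = cohort[cohort[group_col] == group_a]
    b = cohort[cohort[group_col] == group_b]
    rows = []
    for var in variables:
        res = two_sample_t(a[var].dropna().to_numpy(), b[var].dropna().to_numpy(), variant=variant)
        rows.append(
            {
                "var": var,
                f"mean_{group_a}": res.mean1, f"sd_{group_a}": res.sd1, f"n_{group_a}": res.n1,
                f"mean_{group_b}": res.mean2, f"sd_{group_b}": res.sd2, f"n_{group_b}": res.n2,
                "t": res.t, "df": res.df, "p": res.p,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "variant": res.variant,
            }
        )
    return pd.DataFrame(rows)
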