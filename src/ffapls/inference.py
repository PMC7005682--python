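"""Downstream statistics: partial correlations, dependent-correlation tests,
haplotype x hemisphere ANOVA with Tukey post hocs, ICC, FDR, normal tails."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float                       # two-tailed
    ci: tuple[float, float]        # 95% CI via Fisher z
    n_covariates: int = 0


def partial_correlation(x, y, covariates=None) -> CorrelationResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    With no covariates this is the plain Pearson correlation.  p and CI come
    from the t / Fisher-z machinery with degrees of freedom reduced by the
    number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        k = 0
        xr, yr = x, y
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        if n <= k + 3:
            raise ValueError("too few observations for the covariate count")
        X = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear covariates")
        beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
        beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
        xr, yr = x - X @ beta_x, y - X @ beta_y
    r = float(np.corrcoef(xr, yr)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    se = 1.0 / np.sqrt(n - k - 3)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    ci = (float(np.tanh(z - 1.959963984540054 * se)), float(np.tanh(z + 1.959963984540054 * se)))
    return CorrelationResult(r=r, n=n, p=p, ci=ci, n_covariates=k)


def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int, overlapping: bool = True
) -> tuple[float, float]:
    """Steiger's test for the difference between two dependent correlations.

    Overlapping case: compares r(j,k) with r(j,h) sharing variable j, with
    r(k,h) the correlation of the non-shared variables (Steiger's Z1*, using
    the pooled correlation in the covariance term).  Returns (z, two-tailed p).
    """
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise ValueError("correlations must be strictly inside (-1, 1)")
    if n <= 10:
        raise ValueError("n must exceed 10")
    z_jk, z_jh = np.arctanh(r_jk), np.arctanh(r_jh)
    if overlapping:
        rbar = (r_jk + r_jh) / 2.0
        num = r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_kh**2)
        cov = num / (1 - rbar**2) ** 2
    else:
        # non-overlapping four-variable case is not needed here; treat r_kh
        # as the cross-correlation of the two non-shared pairs
        cov = r_kh
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2 - 2 * cov))
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p


@dataclass
class AnovaResult:
    table: pd.DataFrame            # effect x (F, df, p, partial_eta2)
    tukey: pd.DataFrame            # pairwise group contrasts + BH-FDR p
    error_df: int


def haplotype_anova(long_table: pd.DataFrame, score: str = "score",
                    group: str = "group", hemisphere: str = "hemisphere") -> AnovaResult:
    """Two-way factorial ANOVA (with interaction) on stacked observations.

    Hemispheres enter as a crossed factor over the stacked subject x
    hemisphere rows (each subject contributes one row per hemisphere), which
    treats within-subject hemisphere measures as independent; partial eta^2
    per effect; Tukey HSD (Tukey-Kramer under unequal n) across haplotype
    groups pooled over hemispheres, BH-FDR over the post hoc p-values.
    Type-II sums of squares are used (the design may be unbalanced).
    """
    df = long_table.rename(columns={score: "y", group: "grp", hemisphere: "hemi"})
    full = pd.MultiIndex.from_product([sorted(df.grp.unique()),
                                       sorted(df.hemi.unique())])
    cells = df.groupby(["grp", "hemi"], observed=True).size().reindex(full, fill_value=0)
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValueError(f"cells with <2 observations: {bad}")
    model = smf.ols("y ~ C(grp) * C(hemi)", data=df).fit()
    an = anova_lm(model, typ=2)
    ss_err = an.loc["Residual", "sum_sq"]
    rows = []
    for eff in an.index:
        if eff == "Residual":
            continue
        rows.append(dict(
            effect=eff,
            F=an.loc[eff, "F"],
            df_num=int(an.loc[eff, "df"]),
            df_den=int(an.loc["Residual", "df"]),
            p=an.loc[eff, "PR(>F)"],
            partial_eta2=an.loc[eff, "sum_sq"] / (an.loc[eff, "sum_sq"] + ss_err),
        ))
    tuk = pairwise_tukeyhsd(df["y"], df["grp"])
    tuk_df = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    tuk_df["p-adj"] = tuk.pvalues
    tuk_df["p_fdr"] = multipletests(tuk.pvalues, method="fdr_bh")[1]
    return AnovaResult(
        table=pd.DataFrame(rows).set_index("effect"),
        tukey=tuk_df,
        error_df=int(an.loc["Residual", "df"]),
    )


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    variant: str
    n: int


def icc(measure_1, measure_2, variant: str = "ICC2") -> ICCResult:
    """Intraclass correlation for two paired measurements per target.

    Default ICC2: two-way random effects, absolute agreement, single
    measures; ICC3 (consistency) is also available.  CI by the F-distribution
    method (as implemented in pingouin).
    """
    import pingouin as pg

    m1 = np.asarray(measure_1, dtype=float)
    m2 = np.asarray(measure_2, dtype=float)
    if len(m1) != len(m2) or len(m1) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.var(np.concatenate([m1, m2])) < 1e-14:
        raise ValueError("zero total variance")
    n = len(m1)
    long = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([m1, m2]),
    })
    res = pg.intraclass_corr(long, targets="target", raters="rater", ratings="score")
    aliases = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}
    labels = set(res["Type"])
    key = variant if variant in labels else aliases.get(variant, variant)
    row = res.set_index("Type").loc[key]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    return ICCResult(icc=float(row["ICC"]), ci=tuple(row[ci_col]), variant=variant, n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normal_tail_p(z: float, tails: int = 2) -> float:
    """Standard-normal tail probability for a z statistic (1- or 2-tailed)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if tails == 1:
        return float(stats.norm.sf(z))
    if tails == 2:
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError("tails must be 1 or 2")
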