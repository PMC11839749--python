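"""Group-comparison and prediction statistics for motor-inconsistency cohorts.

Implements the statistical battery applied to participant-level data once the
per-participant inconsistency statistic (IIV, a T-score SD) has been computed:
two-sample t tests (pooled or Welch, optionally gated on a Levene test of
variance equality), Cohen's d from pooled SD, a 2 Group x 2 Sex fixed-effects
ANOVA with Type III sums of squares and partial eta squared, ordinary
multiple regression with standardized coefficients, Benjamini-Hochberg FDR
adjustment, and a chi-square test on 2x2 category counts.

Summary-based entry points (:func:`t_test_from_summaries`,
:func:`cohens_d_from_summaries`) accept published group means/SDs/n directly,
so comparison statistics can be recomputed from printed tables without raw
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


@dataclass(frozen=True)
class SummaryStats:
    """Per-group summary of one continuous variable: n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")

    @classmethod
    def from_values(cls, label: str, values) -> "SummaryStats":
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        return cls(label, int(x.size), float(x.mean()), float(x.std(ddof=1)))


@dataclass
class TestResult:
    """One hypothesis test: statistic, df (scalar or tuple), p, effect size."""

    name: str
    value: float
    df: float | tuple
    p_raw: float
    p_fdr: float | None = None
    effect_size: float | None = None
    effect_label: str | None = None


@dataclass
class RegressionResult:
    """OLS fit summary: per-coefficient table plus overall F and R^2.

    ``coef`` is indexed by predictor name (plus ``const``) with columns
    ``b`` (raw coefficient), ``se_b``, ``beta`` (standardized coefficient,
    NaN for the intercept), ``t`` and ``p``.
    """

    coef: pd.DataFrame
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    n: int
    p_model: float = field(default=np.nan)


def pooled_sd(s1: SummaryStats, s2: SummaryStats) -> float:
    """Pooled SD: sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))."""
    num = (s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2
    return float(np.sqrt(num / (s1.n + s2.n - 2)))


def welch_df(s1: SummaryStats, s2: SummaryStats) -> float:
    """Welch-Satterthwaite degrees of freedom."""
    v1 = s1.sd**2 / s1.n
    v2 = s2.sd**2 / s2.n
    return float((v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1)))


def t_test_from_summaries(
    s1: SummaryStats, s2: SummaryStats, variant: str = "pooled"
) -> TestResult:
    """Independent two-sample t test computed from group summaries.

    The statistic is signed as (mean2 - mean1) / SE, i.e. the second group
    minus the first: pass the reference/control group second to reproduce
    the sign convention of a stroke-vs-healthy comparison table.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if s1.sd == 0 and s2.sd == 0 and s1.mean == s2.mean:
        raise ValueError("degenerate: both SDs zero with equal means")
    # scipy signs the statistic mean_a - mean_b, so feed s2 first.
    res = sps.ttest_ind_from_stats(
        mean1=s2.mean, std1=s2.sd, nobs1=s2.n,
        mean2=s1.mean, std2=s1.sd, nobs2=s1.n,
        equal_var=(variant == "pooled"),
    )
    df = s1.n + s2.n - 2 if variant == "pooled" else welch_df(s1, s2)
    return TestResult(
        name=f"t_{variant}", value=float(res.statistic), df=df,
        p_raw=float(res.pvalue),
    )


def cohens_d_from_summaries(s1: SummaryStats, s2: SummaryStats) -> float:
    """Cohen's d: absolute mean difference over the pooled SD."""
    sp = pooled_sd(s1, s2)
    if sp == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float(abs(s1.mean - s2.mean) / sp)


def levene_test(values_by_group: Mapping[str, Sequence[float]]) -> TestResult:
    """Levene's test of variance equality (mean-centered deviations)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.allclose(g, g.mean()) for g in groups):
        raise ValueError("zero within-group deviation everywhere; W undefined")
    w, p = sps.levene(*groups, center="mean")
    k = len(groups)
    n_tot = sum(g.size for g in groups)
    return TestResult(name="levene_W", value=float(w), df=(k - 1, n_tot - k),
                      p_raw=float(p))


def _effects_design(g: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Sum-to-zero (+1/-1) coded design [1, G, S, GxS] for a 2x2 layout."""
    return np.column_stack([np.ones_like(g, dtype=float), g, s, g * s])


def anova_group_by_sex(
    data: pd.DataFrame,
    value: str = "iiv",
    group_col: str = "group",
    sex_col: str = "sex",
) -> dict[str, TestResult]:
    """Two-way fixed-effects ANOVA on a 2 x 2 (possibly unbalanced) design.

    Uses Type III sums of squares with sum-to-zero factor coding, obtained by
    model comparison: each effect's SS is the SSE increase when its column is
    dropped from the full interaction model. Returns main effects and the
    interaction with partial eta squared (SS_effect / (SS_effect + SS_error)).
    """
    df = data[[value, group_col, sex_col]].dropna()
    g_levels = sorted(df[group_col].unique())
    s_levels = sorted(df[sex_col].unique())
    if len(g_levels) != 2 or len(s_levels) != 2:
        raise ValueError("both factors must have exactly two levels")
    counts = df.groupby([group_col, sex_col], observed=True).size()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError("empty cell in the 2x2 design")

    y = df[value].to_numpy(dtype=float)
    g = np.where(df[group_col].to_numpy() == g_levels[0], -1.0, 1.0)
    s = np.where(df[sex_col].to_numpy() == s_levels[0], -1.0, 1.0)
    X = _effects_design(g, s)
    n = y.size

    def sse(Xm: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        r = y - Xm @ beta
        return float(r @ r)

    sse_full = sse(X)
    df_err = n - X.shape[1]
    out: dict[str, TestResult] = {}
    for name, col in (("group", 1), ("sex", 2), ("interaction", 3)):
        ss_eff = sse(np.delete(X, col, axis=1)) - sse_full
        ss_eff = max(ss_eff, 0.0)
        f = (ss_eff / 1.0) / (sse_full / df_err)
        p = float(sps.f.sf(f, 1, df_err))
        eta_p = ss_eff / (ss_eff + sse_full) if (ss_eff + sse_full) > 0 else 0.0
        out[name] = TestResult(name="F", value=float(f), df=(1, df_err),
                               p_raw=p, effect_size=float(eta_p),
                               effect_label="partial_eta_sq")
    return out


def _name_collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns involved in a linear dependency of [1 | X] (SVD null space)."""
    M = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    M = M / np.linalg.norm(M, axis=0)
    names = ["const"] + list(X.columns)
    rank = np.linalg.matrix_rank(M)
    _, _, vt = np.linalg.svd(M)
    involved = np.any(np.abs(vt[rank:]) > 1e-8, axis=0)
    return [n for n, flag in zip(names, involved) if flag and n != "const"]


def multiple_regression(y, X: pd.DataFrame) -> RegressionResult:
    """OLS of y on the predictor table X with standardized coefficients.

    Listwise-deletes incomplete rows (logged), requires n > k + 1 and a
    full-rank design; betas come from b * sd(x) / sd(y).
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    frame = pd.concat([y, X.astype(float)], axis=1)
    n_in = len(frame)
    frame = frame.dropna()
    if len(frame) < n_in:
        warnings.warn(
            f"dropped {n_in - len(frame)} incomplete case(s) of {n_in}",
            stacklevel=2,
        )
    k = X.shape[1]
    if len(frame) <= k + 1:
        raise ValueError(f"need n > k+1 complete cases (n={len(frame)}, k={k})")
    yv = frame["y"]
    Xv = frame[X.columns]
    design = sm.add_constant(Xv)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = _name_collinear_columns(Xv)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(yv, design).fit()
    sy = yv.std(ddof=1)
    beta = fit.params * design.std(ddof=1) / sy
    beta["const"] = np.nan
    coef = pd.DataFrame({
        "b": fit.params, "se_b": fit.bse, "beta": beta,
        "t": fit.tvalues, "p": fit.pvalues,
    })
    return RegressionResult(
        coef=coef, r_squared=float(fit.rsquared), f_stat=float(fit.fvalue),
        df_model=int(fit.df_model), df_resid=int(fit.df_resid),
        n=len(frame), p_model=float(fit.f_pvalue),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def chi_square_counts(table, correction: bool = False) -> TestResult:
    """Chi-square test of independence on a 2x2 (or r x c) count table."""
    res = sps.chi2_contingency(np.asarray(table), correction=correction)
    return TestResult(name="chi2", value=float(res.statistic),
                      df=float(res.dof), p_raw=float(res.pvalue))


def relative_strength_pct(numerator_N: float, denominator_N: float) -> float:
    """Relative strength in %: 100 x paretic/non-paretic for stroke
    (100 x non-dominant/dominant for controls). NaN, with a warning, when a
    limb value is missing or the denominator is non-positive."""
    if (numerator_N is None or denominator_N is None
            or np.isnan(numerator_N) or np.isnan(denominator_N)):
        warnings.warn("missing limb strength; relative strength undefined",
                      stacklevel=2)
        return float("nan")
    if denominator_N <= 0:
        warnings.warn("non-positive reference limb strength; relative "
                      "strength undefined", stacklevel=2)
        return float("nan")
    return 100.0 * float(numerator_N) / float(denominator_N)


def add_relative_strength(meta: pd.DataFrame) -> pd.DataFrame:
    """Append a ``relative_strength_pct`` column from the two limb columns."""
    out = meta.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["relative_strength_pct"] = [
            relative_strength_pct(r.strength_paretic, r.strength_nonparetic)
            for r in meta.itertuples()
        ]
    return out


def compare_groups(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("stroke", "healthy"),
    gating: str = "levene",
    gating_alpha: float = 0.05,
) -> pd.DataFrame:
    """Build a group-comparison table (one row per variable) from raw data.

    ``gating='levene'`` picks Welch when Levene's test rejects variance
    equality at ``gating_alpha``, pooled otherwise; ``'pooled'``/``'welch'``
    force one variant. Raw p values get a BH-FDR column across variables.
    """
    if gating not in ("levene", "pooled", "welch"):
        raise ValueError(f"unknown gating {gating!r}")
    g1, g2 = groups
    rows = []
    for var in variables:
        x1 = cohort.loc[cohort[group_col] == g1, var].dropna()
        x2 = cohort.loc[cohort[group_col] == g2, var].dropna()
        s1 = SummaryStats.from_values(g1, x1)
        s2 = SummaryStats.from_values(g2, x2)
        if gating == "levene":
            lv = levene_test({g1: x1, g2: x2})
            variant = "welch" if lv.p_raw < gating_alpha else "pooled"
            levene_p = lv.p_raw
        else:
            variant, levene_p = gating, np.nan
        tt = t_test_from_summaries(s1, s2, variant)
        rows.append({
            "variable": var,
            f"n_{g1}": s1.n, f"mean_{g1}": s1.mean, f"sd_{g1}": s1.sd,
            f"n_{g2}": s2.n, f"mean_{g2}": s2.mean, f"sd_{g2}": s2.sd,
            "levene_p": levene_p, "variant": variant,
            "t": tt.value, "df": tt.df, "p_raw": tt.p_raw,
            "cohens_d": cohens_d_from_summaries(s1, s2),
        })
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
    return table


#: comparison variables, in table order, when present in the cohort frame
DEFAULT_COMPARISON_VARIABLES = (
    "iiv", "episodic_memory", "visuospatial", "processing_speed",
    "executive_function", "education_years", "drs2", "relative_strength_pct",
    "age",
)
COGNITIVE_PREDICTORS = ("episodic_memory", "visuospatial",
                        "processing_speed", "executive_function")
CLINICAL_PREDICTORS = ("education_years", "drs2", "relative_strength_pct", "mrs")


def _regression_record(res: RegressionResult) -> dict:
    return {
        "r_squared": res.r_squared, "f_stat": res.f_stat,
        "df_model": res.df_model, "df_resid": res.df_resid,
        "p_model": res.p_model, "n": res.n,
        "coefficients": res.coef.reset_index(names="term")
                                .to_dict(orient="records"),
    }


def cohort_statistics(
    cohort: pd.DataFrame,
    gating: str = "levene",
    gating_alpha: float = 0.05,
    stroke_label: str = "stroke",
    healthy_label: str = "healthy",
) -> dict:
    """Full statistical battery on a joined cohort table (metadata + iiv).

    Returns a dict with the group-comparison table (t / d / FDR), the sex
    chi-square, the Group x Sex ANOVA on IIV, and the two stroke-only
    prediction models (cognitive and clinical predictors of IIV).
    """
    cohort = cohort.copy()
    if ("relative_strength_pct" not in cohort.columns
            and {"strength_paretic", "strength_nonparetic"} <= set(cohort.columns)):
        cohort = add_relative_strength(cohort)
    variables = [v for v in DEFAULT_COMPARISON_VARIABLES if v in cohort.columns]
    comparison = compare_groups(cohort, variables,
                                groups=(stroke_label, healthy_label),
                                gating=gating, gating_alpha=gating_alpha)

    out: dict = {"comparison": comparison}
    if "sex" in cohort.columns:
        counts = pd.crosstab(cohort["group"], cohort["sex"])
        out["chi_square_sex"] = chi_square_counts(counts.to_numpy())
    if {"iiv", "sex"} <= set(cohort.columns):
        out["anova_iiv"] = anova_group_by_sex(cohort, value="iiv")

    stroke = cohort[cohort["group"] == stroke_label]
    for name, preds in (("model_cognitive", COGNITIVE_PREDICTORS),
                        ("model_clinical", CLINICAL_PREDICTORS)):
        cols = [p for p in preds if p in stroke.columns]
        if "iiv" in stroke.columns and len(cols) == len(preds):
            try:
                out[name] = multiple_regression(stroke["iiv"],
                                                stroke[list(cols)])
            except ValueError as err:
                warnings.warn(f"skipping {name}: {err}", stacklevel=2)
    return out


def statistics_report(results: dict) -> dict:
    """JSON-serializable view of :func:`cohort_statistics` output."""
    rep: dict = {}
    comp = results["comparison"]
    rep["comparison"] = comp.to_dict(orient="records")
    if "chi_square_sex" in results:
        t = results["chi_square_sex"]
        rep["chi_square_sex"] = {"chi2": t.value, "df": t.df, "p": t.p_raw}
    if "anova_iiv" in results:
        rep["anova_iiv"] = {
            eff: {"F": t.value, "df": list(t.df), "p": t.p_raw,
                  "partial_eta_sq": t.effect_size}
            for eff, t in results["anova_iiv"].items()
        }
    for name in ("model_cognitive", "model_clinical"):
        if name in results:
            rep[name] = _regression_record(results[name])
    return rep
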