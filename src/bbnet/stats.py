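"""Statistical layer: paired contrasts, FDR, effect sizes, correlation, ANOVA.

State contrasts (pre- vs during-/post-stimulation) use paired t-tests with
Benjamini-Hochberg false-discovery-rate correction across each test family,
and Cohen's d computed on the within-subject differences (d > 0.8 large,
0.4-0.8 medium, < 0.4 small, on the absolute value). Brain-behavior
relations use Pearson correlation between band power and digit-span
performance. Group-level behavior is assessed by a two-way fixed-effects
ANOVA (group x state) with eta-squared effect sizes, and a generic
paired-design sample-size utility inverts the noncentral-t power function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Cohen's d magnitude cutoffs: large above 0.8, medium from 0.4, small below.
D_LARGE = 0.8
D_MEDIUM = 0.4


@dataclass
class StatTestResult:
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None
    reject: bool | None = None
    effect_size: float | None = None
    size_label: str | None = None


@dataclass
class AnovaTable:
    """Fixed-effects two-way ANOVA summary: one row per effect."""

    table: pd.DataFrame  # index: group, state, interaction, residual
    residual_df: float

    def effect(self, name) -> pd.Series:
        return self.table.loc[name]


def effect_size_label(d: float) -> str:
    """Classify |d|: > 0.8 large, 0.4-0.8 medium, < 0.4 small."""
    d = abs(d)
    if d > D_LARGE:
        return "large"
    if d >= D_MEDIUM:
        return "medium"
    return "small"


def _paired_differences(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("all paired differences are identical; the paired "
                         "t statistic is undefined")
    return d


def paired_t(x, y) -> StatTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    d = _paired_differences(x, y)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    dz = d.mean() / d.std(ddof=1)
    return StatTestResult(statistic=float(t), df=float(n - 1), p_raw=float(p),
                          effect_size=float(dz),
                          size_label=effect_size_label(dz))


def cohens_d_paired(x, y) -> tuple:
    """Cohen's d for paired data (mean difference / SD of differences)."""
    d = _paired_differences(x, y)
    dz = float(d.mean() / d.std(ddof=1))
    return dz, effect_size_label(dz)


def bh_fdr(p_values, q=0.05) -> tuple:
    """Benjamini-Hochberg step-up correction.

    Returns ``(reject, p_adjusted)`` arrays; adjusted p-values are monotone
    non-decreasing in the rank of the raw p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def pearson_r(a, b) -> tuple:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation is undefined for a zero-variance input")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def correlation_map(predictors: pd.DataFrame, behavior: pd.Series,
                    alpha=0.05) -> pd.DataFrame:
    """Correlate a behavioral score with each predictor column.

    ``predictors`` is indexed by subject with one column per channel (or
    channel-band); ``behavior`` is indexed by the same subjects. Returns one
    row per column with Pearson r, p and a sign flag — ``positive`` /
    ``negative`` when significant at ``alpha``, else ``ns`` — mirroring
    topographic significance-dot maps.
    """
    behavior = behavior.reindex(predictors.index)
    if behavior.isna().any():
        raise ValueError("behavior scores missing for some subjects in the "
                         "predictor table")
    rows = []
    for col in predictors.columns:
        r, p = pearson_r(predictors[col].to_numpy(), behavior.to_numpy())
        flag = "ns"
        if p < alpha:
            flag = "positive" if r > 0 else "negative"
        rows.append({"predictor": col, "r": r, "p": p, "flag": flag})
    return pd.DataFrame(rows)


def two_way_anova(y, group, state) -> AnovaTable:
    """Fixed-effects two-way ANOVA with interaction (type II sums of squares).

    ``y`` are scores, ``group``/``state`` the two categorical factors. State
    is treated as an ordinary between-cell factor, matching how the study's
    summary table is laid out, even though state is within-subject; this is
    a fidelity choice and is flagged in the report metadata. Returns F, p
    and eta-squared (SS_effect / SS_total) per effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "group": pd.Categorical(group),
                       "state": pd.Categorical(state)})
    if df["group"].nunique() < 2 or df["state"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    cells = df.groupby(["group", "state"], observed=True).size()
    if (cells < 2).any():
        raise ValueError("need >= 2 observations per cell for the interaction")
    model = smf.ols("y ~ C(group) * C(state)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_total = aov["sum_sq"].sum()
    rename = {"C(group)": "group", "C(state)": "state",
              "C(group):C(state)": "interaction", "Residual": "residual"}
    aov = aov.rename(index=rename)
    scale = max(1.0, float(np.mean(np.square(df["y"]))))
    if ss_total > 1e-12 * scale * len(df):
        aov["eta_sq"] = aov["sum_sq"] / ss_total
    else:  # all observations identical: no variance to apportion
        aov["eta_sq"] = 0.0
        aov["F"] = 0.0
        aov.loc[aov.index != "residual", "PR(>F)"] = 1.0
    table = aov.loc[["group", "state", "interaction", "residual"],
                    ["df", "sum_sq", "F", "PR(>F)", "eta_sq"]]
    table = table.rename(columns={"PR(>F)": "p"})
    return AnovaTable(table=table, residual_df=float(table.loc["residual", "df"]))


def paired_power(d, n, alpha=0.05) -> float:
    """Power of a two-sided paired t-test at effect size ``d`` and ``n`` pairs."""
    if n < 2:
        return 0.0
    df = n - 1
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n)
    upper = sps.nct.sf(t_crit, df, nc)
    lower = sps.nct.cdf(-t_crit, df, nc)  # numerically 0/NaN at large |nc|
    if np.isnan(lower):
        lower = 0.0
    if np.isnan(upper):
        upper = 1.0 if nc > t_crit else 0.0
    return float(upper + lower)


def required_n_paired(d, alpha=0.05, power=0.8, n_max=1_000_000) -> int:
    """Smallest number of pairs giving the requested power for effect ``d``.

    Iterates the noncentral-t power function of the two-sided paired t-test.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    d = float(d)
    for n in range(2, n_max + 1):
        if paired_power(d, n, alpha) >= power:
            return n
    raise ValueError(f"requested power not attainable with n <= {n_max}")


def family_paired_tests(pairs, q=0.05) -> pd.DataFrame:
    """Run one FDR-corrected family of paired t-tests.

    ``pairs`` maps a test label to a ``(x, y)`` pair of DataFrames indexed by
    subject with one column per test unit (e.g. one channel or one node
    metric); every column of every pair is tested and all tests in the call
    share a single Benjamini-Hochberg correction. Degenerate units (zero
    difference variance) are reported with NaN statistics instead of failing
    the family.
    """
    rows = []
    for label, (x, y) in pairs.items():
        for col in x.columns:
            try:
                res = paired_t(x[col].to_numpy(), y[col].to_numpy())
                rows.append({"test": label, "unit": col,
                             "t": res.statistic, "df": res.df,
                             "p_raw": res.p_raw, "d": res.effect_size,
                             "size_label": res.size_label})
            except ValueError:
                rows.append({"test": label, "unit": col, "t": np.nan,
                             "df": np.nan, "p_raw": np.nan, "d": np.nan,
                             "size_label": "degenerate"})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_adjusted"] = np.nan
    out["reject"] = False
    if ok.any():
        reject, p_adj = bh_fdr(out.loc[ok, "p_raw"].to_numpy(), q=q)
        out.loc[ok, "p_adjusted"] = p_adj
        out.loc[ok, "reject"] = reject
    return out
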