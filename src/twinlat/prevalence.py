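"""Descriptive and inferential prevalence statistics.

Contingency tables with uncorrected Pearson chi-square tests (no Yates
continuity correction — the convention throughout), Bonferroni adjustment
per family of item comparisons, scale reliability (Cronbach's alpha,
item-total correlations), unbalanced two-way ANOVA, and the pairwise
cross-measure correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ChiSquareResult",
    "AnovaResult",
    "chisq_test",
    "bonferroni_alpha",
    "item_total_correlations",
    "cronbach_alpha",
    "anova_two_way",
    "correlation_matrix",
    "preference_tables",
    "direction_tables",
]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    """F, dfs and p per effect of a two-factor design with interaction."""

    table: pd.DataFrame  # index: effect; columns: F, df_num, df_den, p


def chisq_test(counts) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    Uses the uncorrected statistic sum (O-E)^2/E with expected counts
    row_total * col_total / N; df = (r-1)(c-1).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("contingency table has negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero row or column")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha/m for a family of m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def _item_score_matrix(item_scores: pd.DataFrame) -> pd.DataFrame:
    mat = item_scores.apply(pd.to_numeric)
    if mat.shape[1] < 2 or mat.shape[0] < 3:
        raise ValueError("need at least 3 subjects and 2 items")
    return mat


def item_total_correlations(
    item_scores: pd.DataFrame, corrected: bool = False
) -> pd.Series:
    """Pearson correlation of each item with the total score.

    ``item_scores`` is subjects x items, each entry the item's signed point
    score (right minus left points, in -2..+2).  With ``corrected=True``
    each item is correlated with the total of the *other* items (item-rest);
    the default correlates with the full total, item included.
    Zero-variance items yield NaN with a warning.
    """
    mat = _item_score_matrix(item_scores).dropna()
    total = mat.sum(axis=1)
    out = {}
    for col in mat.columns:
        x = mat[col]
        y = total - x if corrected else total
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            warnings.warn(f"item {col!r} (or its total) has zero variance; r set to NaN")
            out[col] = np.nan
        else:
            out[col] = float(stats.pearsonr(x, y)[0])
    return pd.Series(out, name="item_total_r")


def cronbach_alpha(item_scores: pd.DataFrame) -> float:
    """Internal-consistency reliability alpha = k/(k-1) (1 - sum var_i / var_tot)."""
    mat = _item_score_matrix(item_scores).dropna()
    k = mat.shape[1]
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def anova_two_way(
    values,
    factor_sample,
    factor_sex,
    ss_type: int = 3,
) -> AnovaResult:
    """Two-way ANOVA (factor_sample x factor_sex) with interaction.

    Unbalanced designs are handled by the requested sums-of-squares type
    (default Type III with sum-to-zero contrasts; 1 and 2 also available).
    Raises on empty cells, naming the offending cell.
    """
    if ss_type not in (1, 2, 3):
        raise ValueError("ss_type must be 1, 2 or 3")
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "sample": pd.Categorical(factor_sample),
            "sex": pd.Categorical(factor_sex),
        }
    ).dropna()
    cells = df.groupby(["sample", "sex"], observed=False).size()
    empty = cells[cells < 2]
    if len(empty):
        raise ValueError(f"cells with fewer than 2 observations: {list(empty.index)}")
    model = smf.ols("y ~ C(sample, Sum) * C(sex, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)
    tab = tab.loc[[i for i in tab.index if i not in ("Residual", "Intercept")]]
    resid_df = int(model.df_resid)
    out = pd.DataFrame(
        {
            "F": tab["F"].to_numpy(),
            "df_num": tab["df"].astype(int).to_numpy(),
            "df_den": resid_df,
            "p": tab["PR(>F)"].to_numpy(),
        },
        index=["sample", "sex", "sample:sex"],
    )
    return AnovaResult(table=out)


def correlation_matrix(measures: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Binary measures enter as their 0/1 codes.  Constant columns produce NaN
    entries with a warning.  Returns (r, p) DataFrames.
    """
    cols = list(measures.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = measures[[a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            x, y = pair[a].astype(float), pair[b].astype(float)
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                warnings.warn(f"constant column in pair ({a}, {b}); r set to NaN")
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


def _three_class_counts(sub: pd.DataFrame, group_col: str, groups) -> np.ndarray:
    tab = (
        sub.groupby(["pref_class", group_col], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=["LH", "NP", "RH"], columns=list(groups), fill_value=0)
    )
    return tab.to_numpy()


def preference_tables(
    classes: pd.DataFrame, roster: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-item 3x2 preference comparisons (the Table-1-style report).

    ``classes`` is long format: subject_id, item_id, pref_class (LH/NP/RH);
    ``roster`` maps subject_id to cohort {twin, singleton} and sex.  For each
    item, three chi-square tests: sex within twins, sex within singletons,
    twins vs singletons.  Bonferroni level is alpha / number of items.
    """
    merged = classes.merge(roster[["subject_id", "cohort", "sex"]], on="subject_id")
    items = list(dict.fromkeys(classes["item_id"]))
    adj = bonferroni_alpha(alpha, len(items))
    rows = []
    for item in items:
        sub = merged[merged["item_id"] == item]
        comparisons = [
            ("sex_in_twins", sub[sub["cohort"] == "twin"], "sex", ("male", "female")),
            ("sex_in_singletons", sub[sub["cohort"] == "singleton"], "sex", ("male", "female")),
            ("twin_vs_singleton", sub, "cohort", ("twin", "singleton")),
        ]
        for name, data, col, groups in comparisons:
            counts = _three_class_counts(data, col, groups)
            # drop all-zero preference rows (an item may have no NP responses)
            counts_nz = counts[counts.sum(axis=1) > 0]
            if counts_nz.shape[0] < 2 or (counts_nz.sum(axis=0) == 0).any():
                warnings.warn(f"{item}/{name}: degenerate table; test skipped")
                stat = df_ = p = float("nan")
            else:
                res = chisq_test(counts_nz)
                stat, df_, p = res.statistic, res.df, res.p_value
            rows.append(
                {
                    "item": item,
                    "comparison": name,
                    "chi2": stat,
                    "df": df_,
                    "p": p,
                    "significant_bonferroni": bool(p < adj) if p == p else False,
                }
            )
    return pd.DataFrame(rows)


def direction_tables(
    scored: pd.DataFrame, roster: pd.DataFrame, measures=("writing_bin", "drawing_bin", "EHI2", "PegQ2")
) -> pd.DataFrame:
    """Per-measure 2x2 NRH/RH comparisons (the Table-2-style report)."""
    merged = scored.merge(roster[["subject_id", "cohort", "sex"]], on="subject_id")
    rows = []
    for measure in measures:
        sub = merged.dropna(subset=[measure])
        comparisons = [
            ("sex_in_twins", sub[sub["cohort"] == "twin"], "sex", ("male", "female")),
            ("sex_in_singletons", sub[sub["cohort"] == "singleton"], "sex", ("male", "female")),
            ("twin_vs_singleton", sub, "cohort", ("twin", "singleton")),
        ]
        for name, data, col, groups in comparisons:
            tab = (
                data.assign(cls=data[measure].astype(int))
                .groupby(["cls", col], observed=False)
                .size()
                .unstack(fill_value=0)
                .reindex(index=[0, 1], columns=list(groups), fill_value=0)
            ).to_numpy()
            if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
                warnings.warn(
                    f"{measure}/{name}: a class is empty; test skipped"
                )
                stat = df_ = p = float("nan")
            else:
                res = chisq_test(tab)
                stat, df_, p = res.statistic, res.df, res.p_value
            rows.append(
                {
                    "measure": measure,
                    "comparison": name,
                    "chi2": stat,
                    "df": df_,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
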