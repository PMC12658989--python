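"""Study-level statistics: factorial ANOVA with Tukey letters, assumption
checks, and Pearson correlation matrices with Benjamini-Hochberg FDR.

The cytogenetic endpoints are modelled as a two-factor fixed-effects ANOVA
(exposure duration x concentration, with interaction), followed by Tukey-HSD
pairwise comparisons across the cell means and a compact letter display:
cells sharing a letter are not significantly different at the chosen alpha.
Endpoint-to-endpoint associations use Pearson's r with two-tailed p-values
and BH-FDR adjustment over the family of pairs; with only a few concentration
levels as replicates these correlations are exploratory and are flagged as
low-powered.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


def compact_letter_display(
    groups: list[str],
    means: dict[str, float],
    significant_pairs: set[frozenset[str]],
) -> dict[str, str]:
    """Piepho-style insert-and-absorb compact letter display.

    Starts from one column holding every group, splits a column whenever it
    contains a significantly different pair, then absorbs redundant columns.
    Guarantees: a significant pair never shares a letter; a non-significant
    pair always shares at least one.
    """
    columns: list[set[str]] = [set(groups)]
    for pair in significant_pairs:
        i, j = tuple(pair)
        expanded: list[set[str]] = []
        for col in columns:
            if i in col and j in col:
                expanded.extend([col - {i}, col - {j}])
            else:
                expanded.append(col)
        expanded.sort(key=len, reverse=True)
        columns = []
        for col in expanded:
            if col and not any(col <= kept for kept in columns):
                columns.append(col)
    # Stable letter order: columns sorted by the largest group mean they contain.
    columns.sort(key=lambda col: -max(means[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for k, col in enumerate(columns):
        for g in col:
            letters[g] += alphabet[k % len(alphabet)]
    return {g: "".join(sorted(s)) for g, s in letters.items()}


@dataclass
class AnovaResult:
    anova_table: pd.DataFrame
    tukey: pd.DataFrame  # pairwise comparisons with adjusted p-values
    letters: dict[str, str]  # compact letter display over cells
    cell_means: dict[str, float]
    model_formula: str


def anova_with_interaction(
    data: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("exposure_h", "concentration"),
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-factor ANOVA with interaction + Tukey HSD + letter display.

    ``data`` is long-format with one row per replicate.  Tukey comparisons run
    across the crossed cells (every factor-level combination).  If any cell is
    empty the model falls back to the additive form with a warning.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    f1, f2 = factors
    for f in (f1, f2):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    cell_sizes = data.groupby([f1, f2]).size()
    n_cells_expected = data[f1].nunique() * data[f2].nunique()
    interaction = len(cell_sizes) == n_cells_expected
    if not interaction:
        warnings.warn("empty factorial cells: falling back to the additive model")
    op = "*" if interaction else "+"
    formula = f"Q('{response}') ~ C(Q('{f1}')) {op} C(Q('{f2}'))"
    model = smf.ols(formula, data=data).fit()
    anova_table = sm.stats.anova_lm(model, typ=2)

    cells = data[f1].astype(str) + "|" + data[f2].astype(str)
    cell_means = data.groupby(cells)[response].mean().to_dict()
    if data.groupby(cells)[response].var(ddof=1).fillna(0).sum() == 0:
        # Degenerate: all observations identical within and across cells.
        groups = sorted(cell_means)
        letters = {g: "a" for g in groups}
        tukey_df = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "reject"]
        )
        return AnovaResult(anova_table, tukey_df, letters, cell_means, formula)

    res = pairwise_tukeyhsd(data[response].to_numpy(), cells.to_numpy(), alpha=alpha)
    uniq = [str(g) for g in res.groupsunique]
    pairs = list(itertools.combinations(range(len(uniq)), 2))
    tukey_df = pd.DataFrame(
        {
            "group1": [uniq[i] for i, _ in pairs],
            "group2": [uniq[j] for _, j in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
    sig = {
        frozenset((row.group1, row.group2))
        for row in tukey_df.itertuples()
        if row.reject
    }
    letters = compact_letter_display(uniq, cell_means, sig)
    return AnovaResult(anova_table, tukey_df, letters, cell_means, formula)


@dataclass
class AssumptionChecks:
    levene_stat: float
    levene_p: float
    shapiro_stat: float
    shapiro_p: float
    flagged: bool  # constant data: tests undefined
    note: str = ""


def assumption_checks(
    data: pd.DataFrame,
    response: str,
    group_cols: tuple[str, ...] = ("exposure_h", "concentration"),
) -> AssumptionChecks:
    """Levene's test across groups and Shapiro-Wilk on group-mean residuals."""
    groups = [g[response].to_numpy(float) for _, g in data.groupby(list(group_cols))]
    if len(data) < 3:
        raise ValueError("need at least 3 observations")
    y = data[response].to_numpy(float)
    if np.ptp(y) == 0:
        return AssumptionChecks(np.nan, np.nan, np.nan, np.nan, True, "constant response")
    resid = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(resid) == 0:
        return AssumptionChecks(np.nan, np.nan, np.nan, np.nan, True, "constant residuals")
    lev = sps.levene(*[g for g in groups if len(g) > 1])
    sw = sps.shapiro(resid)
    return AssumptionChecks(
        float(lev.statistic), float(lev.pvalue), float(sw.statistic), float(sw.pvalue), False
    )


def correlation_matrix(
    endpoint_table: pd.DataFrame,
    endpoints: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with BH-FDR adjustment.

    ``endpoint_table`` has one row per replicate (here: per concentration)
    and one column per endpoint.  Returns a tidy frame with r, two-tailed p,
    BH-adjusted p and a significance flag; pairs involving a zero-variance
    endpoint are reported with missing r/p and excluded from the BH family.
    A low-power warning is issued for n < 5.
    """
    cols = endpoints or [c for c in endpoint_table.columns]
    n = len(endpoint_table)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if n < 5:
        warnings.warn(
            f"only n={n} replicates per correlation: exploratory, low power"
        )
    rows = []
    for a, b in itertools.combinations(cols, 2):
        x = endpoint_table[a].to_numpy(float)
        y = endpoint_table[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((a, b, np.nan, np.nan))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((a, b, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["endpoint_a", "endpoint_b", "r", "p"])
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if mask.any():
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] <= alpha
    out["n"] = n
    return out


def correlation_pivot(tidy: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Square matrix form of a tidy correlation table (for heatmap export)."""
    names = sorted(set(tidy["endpoint_a"]) | set(tidy["endpoint_b"]))
    mat = pd.DataFrame(np.eye(len(names)) if value == "r" else np.zeros((len(names), len(names))),
                       index=names, columns=names)
    for row in tidy.itertuples():
        mat.loc[row.endpoint_a, row.endpoint_b] = getattr(row, value)
        mat.loc[row.endpoint_b, row.endpoint_a] = getattr(row, value)
    return mat
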