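"""Non-parametric group statistics and effect sizes.

Biomarker distributions from interaction recordings are typically heavily
skewed, so group comparisons use rank tests: Mann-Whitney U between groups
(exact enumeration for small tie-free samples, otherwise the tie-corrected
normal approximation) with the effect size r = |Z|/sqrt(N), and the
Wilcoxon signed-rank test for paired part-vs-neutral contrasts, reporting
W = the positive-rank sum.  Voice characteristics that vary strongly with
sex are analyzed with a two-way group x gender ANOVA (type-II sums of
squares) with generalized eta squared.  Families of p-values are corrected
by Holm's step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

EXACT_N_MAX = 12


@dataclass(frozen=True)
class GroupTestResult:
    test_name: str
    statistic: float
    p: float
    effect_size: float = np.nan
    dfs: tuple = ()
    note: str = ""


def _rank_Z(U: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    """Normal-approximation Z for the Mann-Whitney U, with tie correction."""
    N = n1 + n2
    mu = n1 * n2 / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12 * (N + 1 - tie_term)
    if var <= 0:
        return 0.0
    return (U - mu) / np.sqrt(var)


def _exact_mw_p(U_obs: float, x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments (tie-free small samples only)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    lo = np.mean(us <= U_obs)
    hi = np.mean(us >= U_obs)
    return float(min(1.0, 2 * min(lo, hi)))


def mann_whitney(x, y) -> GroupTestResult:
    """Two-sided Mann-Whitney U test with effect size r = |Z|/sqrt(N).

    U is the rank-sum statistic of the first sample.  For tie-free samples
    with n1+n2 <= 12 the p-value is exact (full enumeration); otherwise the
    tie-corrected normal approximation is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(x), len(y)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    Z = _rank_Z(U, n1, n2, pooled)
    ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= EXACT_N_MAX and not ties:
        p = _exact_mw_p(U, x, y)
        note = "exact"
    else:
        p = float(2 * sps.norm.sf(abs(Z)))
        note = "normal-approx"
    return GroupTestResult(
        "mann-whitney", U, p, effect_size=abs(Z) / np.sqrt(n1 + n2), note=note
    )


def wilcoxon_signed(x, y) -> GroupTestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; W is the sum of positive-difference
    ranks.  Exact sign-flip enumeration p for n <= 12, else the normal
    approximation.  All-zero differences yield a degenerate result
    (W = 0, p = 1) flagged in ``note``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return GroupTestResult("wilcoxon-signed", 0.0, 1.0, note="degenerate: all zero")
    ranks = sps.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        # enumerate all 2^n sign assignments; exact conditional on the
        # observed |differences| even when they are tied (mid-ranks)
        total = 0
        ge = 0
        le = 0
        for signs in range(1 << n):
            w = sum(ranks[i] for i in range(n) if signs >> i & 1)
            total += 1
            ge += w >= W
            le += w <= W
        p = min(1.0, 2 * min(ge, le) / total)
        note = "exact"
    else:
        mu = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        _, counts = np.unique(np.abs(d), return_counts=True)
        var -= (counts**3 - counts).sum() / 48
        Z = (W - mu) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(Z)))
        note = "normal-approx"
    mu = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    Z = (W - mu) / np.sqrt(var) if var > 0 else 0.0
    return GroupTestResult(
        "wilcoxon-signed", W, p, effect_size=abs(Z) / np.sqrt(n), note=note
    )


def anova_group_gender(values, group, gender) -> dict[str, GroupTestResult]:
    """Two-way between-subjects ANOVA (type-II SS) with generalized eta².

    Returns results for the two main effects and the interaction, keyed
    ``group``, ``gender``, ``group:gender``.  eta²_G here treats both
    factors as manipulated: SS_effect / (SS_effect + SS_error).
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, float),
            "group": pd.Categorical(group),
            "gender": pd.Categorical(gender),
        }
    )
    counts = df.groupby(["group", "gender"], observed=False).size()
    if (counts < 2).any():
        raise ValueError("every group x gender cell needs >= 2 observations")
    model = ols("y ~ C(group) * C(gender)", data=df).fit()
    table = anova_lm(model, typ=2)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = int(table.loc["Residual", "df"])
    out = {}
    for row, key in [
        ("C(group)", "group"),
        ("C(gender)", "gender"),
        ("C(group):C(gender)", "group:gender"),
    ]:
        ss = float(table.loc[row, "sum_sq"])
        out[key] = GroupTestResult(
            "anova",
            float(table.loc[row, "F"]),
            float(table.loc[row, "PR(>F)"]),
            effect_size=ss / (ss + ss_err),
            dfs=(int(table.loc[row, "df"]), df_err),
        )
    return out


def chi_square_2x2(table, correction: bool = False) -> GroupTestResult:
    """Pearson chi-square on a 2x2 table (continuity correction off by default)."""
    tab = np.asarray(table, float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = sps.chi2_contingency(tab, correction=correction)
    n = tab.sum()
    return GroupTestResult(
        "chi-square", float(stat), float(p), effect_size=float(np.sqrt(stat / n)),
        dfs=(int(dof),)
    )


def holm_correct(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, float)
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]
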