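"""Shared statistics: ANOVA, Tukey HSD, Welch t, BH adjustment, stars.

One- and two-way fixed-effect ANOVA use the classical balanced sum-of-squares
decomposition with p-values from :mod:`scipy.stats` distributions; two-way
designs must be balanced and complete (unbalanced data is a hard error rather
than a silent Type-I/II/III sums-of-squares choice).  Tukey's honestly
significant difference uses the studentized-range distribution
(:class:`scipy.stats.studentized_range`, Tukey-Kramer standard error for
unequal group sizes).  Multiple-testing adjustment is Benjamini-Hochberg via
:func:`statsmodels.stats.multitest.multipletests`.  Significance stars follow
the usual convention: ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    statistic: float  # studentized range q (or |t| for Welch pairs)
    p_adjusted: float
    stars: str


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def _check_groups(groups: Sequence[np.ndarray], min_groups: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < min_groups:
        raise StatsError(f"need at least {min_groups} groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise StatsError(f"group {i} has fewer than 2 values")
    return arrays


def _f_p(ss_effect: float, df_effect: int, ss_error: float, df_error: int) -> tuple[float, float]:
    """F and p with explicit zero-variance handling (all-equal data -> F=0, p=1)."""
    ms_error = ss_error / df_error if df_error > 0 else 0.0
    if ms_error <= 0:
        if ss_effect <= 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f = (ss_effect / df_effect) / ms_error
    return f, float(stats.f.sf(f, df_effect, df_error))


def one_way_anova(groups: Sequence[np.ndarray]) -> pd.DataFrame:
    """Classical one-way ANOVA table (between / within / total).

    Returns a frame indexed by term with columns ``sum_sq, df, mean_sq, F, p``.
    """
    arrays = _check_groups(groups)
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    f, p = _f_p(ss_between, df_between, ss_within, df_within)
    return pd.DataFrame(
        {
            "sum_sq": [ss_between, ss_within, ss_between + ss_within],
            "df": [df_between, df_within, df_between + df_within],
            "mean_sq": [
                ss_between / df_between,
                ss_within / df_within if df_within else np.nan,
                np.nan,
            ],
            "F": [f, np.nan, np.nan],
            "p": [p, np.nan, np.nan],
        },
        index=["between", "within", "total"],
    )


def two_way_anova(
    data: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    value: str,
) -> pd.DataFrame:
    """Balanced complete two-way fixed-effects ANOVA with interaction.

    ``data`` is long format with two factor columns and a value column.
    Every factor-level combination must be present with the same number
    (>= 2) of replicates; anything else raises :class:`StatsError`.
    """
    for col in (factor_a, factor_b, value):
        if col not in data.columns:
            raise StatsError(f"column {col!r} missing from data")
    counts = data.groupby([factor_a, factor_b], observed=True)[value].count()
    a_levels = data[factor_a].unique()
    b_levels = data[factor_b].unique()
    if len(counts) < len(a_levels) * len(b_levels):
        have = set(counts.index)
        missing = [
            (a, b) for a in a_levels for b in b_levels if (a, b) not in have
        ]
        raise StatsError(f"missing cell(s): {missing[:5]}")
    if counts.nunique() != 1:
        raise StatsError(
            "unbalanced design (replicate counts "
            f"{sorted(set(counts))}); rebalance the input or subsample"
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise StatsError("need >= 2 replicates per cell")

    y = data[value].astype(float)
    grand = y.mean()
    a_means = data.groupby(factor_a, observed=True)[value].mean()
    b_means = data.groupby(factor_b, observed=True)[value].mean()
    cell_means = data.groupby([factor_a, factor_b], observed=True)[value].mean()

    n_a, n_b = len(a_levels), len(b_levels)
    ss_a = n * n_b * float(((a_means - grand) ** 2).sum())
    ss_b = n * n_a * float(((b_means - grand) ** 2).sum())
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    fitted = data.set_index([factor_a, factor_b]).index.map(cell_means)
    ss_res = float(((y.to_numpy() - np.asarray(fitted)) ** 2).sum())

    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_res = n_a * n_b * (n - 1)
    f_a, p_a = _f_p(ss_a, df_a, ss_res, df_res)
    f_b, p_b = _f_p(ss_b, df_b, ss_res, df_res)
    f_ab, p_ab = _f_p(max(ss_ab, 0.0), df_ab, ss_res, df_res)
    total_ss = ss_a + ss_b + ss_ab + ss_res
    return pd.DataFrame(
        {
            "sum_sq": [ss_a, ss_b, ss_ab, ss_res, total_ss],
            "df": [df_a, df_b, df_ab, df_res, df_a + df_b + df_ab + df_res],
            "mean_sq": [
                ss_a / df_a,
                ss_b / df_b,
                ss_ab / df_ab,
                ss_res / df_res,
                np.nan,
            ],
            "F": [f_a, f_b, f_ab, np.nan, np.nan],
            "p": [p_a, p_b, p_ab, np.nan, np.nan],
        },
        index=[factor_a, factor_b, "interaction", "residual", "total"],
    )


def tukey_hsd(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD with studentized-range adjusted p-values.

    With two groups the adjusted p equals the pooled two-sample t-test p
    (the q = |t| * sqrt(2) identity).  ``alpha`` only affects downstream
    callers' decisions; every pair's adjusted p is always reported.
    """
    arrays = _check_groups(groups)
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise StatsError("labels must match the number of groups")
    k = len(arrays)
    df_error = sum(a.size for a in arrays) - k
    ms_error = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_error
    comparisons = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        diff = a.mean() - b.mean()
        if ms_error <= 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(ms_error / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_error))
        p = min(max(p, 0.0), 1.0)
        comparisons.append(
            PairwiseComparison(labels[i], labels[j], diff, q, p, significance_stars(p))
        )
    return comparisons


def tukey_frame(comparisons: Sequence[PairwiseComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    monotone, each >= its raw p, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    x, y = _check_groups([a, b])
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))
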