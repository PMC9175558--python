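"""Differential protein abundance, Venn partition, fold-change correlation.

Per-protein differential abundance between a strain group and the WT
reference is reported as ``log2fc`` (log2 ratio of floored group means),
with a Welch t-test on log2 abundances, Benjamini-Hochberg adjustment, and
the dual significance rule

    significant  <=>  p_adjusted < alpha  AND  |log2fc| > lfc_threshold

(defaults alpha = 0.05, lfc_threshold = 1.5).  Proteins absent (all-zero)
in one group are floored -- zero abundances are replaced by half the
smallest nonzero abundance in the matrix -- and flagged ``floored`` so the
large nominal fold-changes they produce stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stats_core import bh_adjust

logger = logging.getLogger(__name__)


class OmicsError(ValueError):
    """Invalid input to a differential-abundance computation."""


@dataclass(frozen=True)
class VennPartition:
    """Two-comparison partition of significant proteins.

    Satisfies inclusion-exclusion exactly: union = shared + unique_a +
    unique_b, |A| = shared + unique_a, |B| = shared + unique_b.
    """

    shared: int
    unique_a: int
    unique_b: int
    shared_ids: tuple = field(repr=False, default=())
    unique_a_ids: tuple = field(repr=False, default=())
    unique_b_ids: tuple = field(repr=False, default=())

    @property
    def union(self) -> int:
        return self.shared + self.unique_a + self.unique_b

    @property
    def shared_percent(self) -> float:
        return 100.0 * self.shared / self.union if self.union else float("nan")


def _floor_value(matrix: pd.DataFrame) -> float:
    values = matrix.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise OmicsError("abundance matrix has no nonzero entries")
    return float(nonzero.min()) / 2.0


def _welch_vectorized(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t on two (proteins x replicates) arrays.

    Zero pooled variance is resolved exactly: equal means give p = 1,
    distinct means p = 0 (the noiseless-recovery limit).
    """
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if degenerate.any():
        equal = degenerate & (mx == my)
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(equal, 0.0, np.inf), t)
        df = np.where(degenerate, float(nx + ny - 2), df)
    return t, df, p


def differential(
    matrix: pd.DataFrame,
    sample_groups: pd.Series,
    group: str,
    reference: str,
    alpha: float = 0.05,
    lfc_threshold: float = 1.5,
    floor: float | None = None,
) -> pd.DataFrame:
    """Per-protein differential abundance of ``group`` over ``reference``.

    ``matrix`` is proteins x samples (non-negative abundances);
    ``sample_groups`` maps sample id -> group label.  Proteins that are
    all-zero in both groups are excluded with a warning.  Returns a frame
    indexed by protein with columns ``log2fc, p, p_adjusted, significant,
    floored``.
    """
    for g in (group, reference):
        if g not in set(sample_groups):
            raise OmicsError(f"group {g!r} not present in sample map")
    unmapped = [s for s in matrix.columns if s not in sample_groups.index]
    if unmapped:
        raise OmicsError(f"sample(s) missing from group map: {unmapped[:5]}")
    g_cols = [s for s in matrix.columns if sample_groups[s] == group]
    r_cols = [s for s in matrix.columns if sample_groups[s] == reference]
    if len(g_cols) < 2 or len(r_cols) < 2:
        raise OmicsError("both groups need >= 2 samples")
    if (matrix.to_numpy() < 0).any():
        raise OmicsError("abundances must be non-negative")

    sub = matrix[g_cols + r_cols]
    all_zero = (sub == 0).all(axis=1)
    if all_zero.any():
        logger.warning(
            "excluding %d protein(s) with all-zero abundance in both groups",
            int(all_zero.sum()),
        )
        sub = sub[~all_zero]

    floor_val = floor if floor is not None else _floor_value(matrix)
    floored_mask = (sub == 0).any(axis=1)
    floored = sub.to_numpy(dtype=float)
    floored[floored == 0] = floor_val

    gx = floored[:, : len(g_cols)]
    rx = floored[:, len(g_cols) :]
    log2fc = np.log2(gx.mean(axis=1) / rx.mean(axis=1))
    _, _, p = _welch_vectorized(np.log2(gx), np.log2(rx))
    p_adj = bh_adjust(p)
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adjusted": p_adj,
            "significant": (p_adj < alpha) & (np.abs(log2fc) > lfc_threshold),
            "floored": floored_mask.to_numpy(),
        },
        index=sub.index,
    )
    result.index.name = "protein_id"
    return result


def direction_counts(diff: pd.DataFrame) -> tuple[int, int]:
    """(up in reference, up in group) counts among significant proteins.

    The two directional counts always total the number of significant
    proteins (log2fc is never exactly zero for a significant protein, since
    significance requires |log2fc| above a positive threshold).
    """
    sig = diff[diff["significant"]]
    up_in_reference = int((sig["log2fc"] < 0).sum())
    up_in_group = int((sig["log2fc"] > 0).sum())
    return up_in_reference, up_in_group


def venn(diff_a: pd.DataFrame, diff_b: pd.DataFrame) -> VennPartition:
    """Partition of significant ids between two comparisons over one universe."""
    universe_a, universe_b = set(diff_a.index), set(diff_b.index)
    if universe_a != universe_b:
        only = sorted((universe_a ^ universe_b))[:5]
        raise OmicsError(f"mismatched protein universes (e.g. {only})")
    a = set(diff_a.index[diff_a["significant"]])
    b = set(diff_b.index[diff_b["significant"]])
    shared = a & b
    return VennPartition(
        shared=len(shared),
        unique_a=len(a - b),
        unique_b=len(b - a),
        shared_ids=tuple(sorted(shared)),
        unique_a_ids=tuple(sorted(a - b)),
        unique_b_ids=tuple(sorted(b - a)),
    )


def venn_from_sets(a: set, b: set) -> VennPartition:
    """Venn partition directly from two significant-id sets."""
    shared = a & b
    return VennPartition(
        shared=len(shared),
        unique_a=len(a - b),
        unique_b=len(b - a),
        shared_ids=tuple(sorted(shared)),
        unique_a_ids=tuple(sorted(a - b)),
        unique_b_ids=tuple(sorted(b - a)),
    )


def fc_correlation(
    diff_a: pd.DataFrame,
    diff_b: pd.DataFrame,
    method: str = "pearson",
) -> tuple[float, int, pd.DataFrame]:
    """Correlation of log2 fold-changes between two comparisons.

    Returns ``(r, n, table)`` where the table pairs each protein's two
    fold-changes and flags the "gray points" -- proteins non-significant in
    both comparisons.
    """
    if set(diff_a.index) != set(diff_b.index):
        raise OmicsError("mismatched protein universes")
    if len(diff_a) < 3:
        raise OmicsError("need >= 3 shared proteins for a correlation")
    if method not in ("pearson", "spearman"):
        raise OmicsError(f"unknown correlation method {method!r}")
    b = diff_b.loc[diff_a.index]
    table = pd.DataFrame(
        {
            "log2fc_a": diff_a["log2fc"],
            "log2fc_b": b["log2fc"],
            "significant_a": diff_a["significant"],
            "significant_b": b["significant"],
        }
    )
    table["gray"] = ~table["significant_a"] & ~table["significant_b"]
    if method == "pearson":
        r = float(stats.pearsonr(table["log2fc_a"], table["log2fc_b"]).statistic)
    else:
        r = float(stats.spearmanr(table["log2fc_a"], table["log2fc_b"]).statistic)
    return r, len(table), table
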