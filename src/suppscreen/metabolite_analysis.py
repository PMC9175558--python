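"""Succinate:2-ketoglutarate ratios, strain fold-changes, treatment tests.

The succinate:2KG concentration ratio is the quantity thought to govern
2-ketoglutarate-dependent dioxygenase inhibition: succinate competes with
2KG at the active site, so dioxygenase flux falls as the ratio rises.
Ratios are computed per sample and summarized as mean +- s.d. over
replicates per strain x treatment cell; they are scale-invariant (a common
concentration rescaling cancels) and are only defined across metabolites
quantified in commensurate (absolute) units -- relative-quantitation
metabolites may enter folds and ANOVA but not cross-metabolite ratios.

Treatment effects are assessed by balanced two-way ANOVA
(strain x treatment with interaction) plus Tukey HSD on the cell means,
via :mod:`suppscreen.stats_core`.
"""

from __future__ import annotations

import pandas as pd

from .stats_core import PairwiseComparison, StatsError, tukey_hsd, two_way_anova

SUCCINATE = "succinate"
KETOGLUTARATE = "2-ketoglutarate"

TABLE_COLUMNS = (
    "sample_id",
    "strain",
    "treatment",
    "replicate",
    "metabolite",
    "concentration_um",
    "quantitation",
)


class MetaboliteError(ValueError):
    """Invalid metabolite-table input."""


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise MetaboliteError(f"missing column(s): {', '.join(missing)}")
    if table.duplicated(subset=["sample_id", "metabolite"]).any():
        dups = table[table.duplicated(subset=["sample_id", "metabolite"])]
        raise MetaboliteError(
            "duplicate (sample, metabolite) row(s), e.g. "
            f"{dups[['sample_id', 'metabolite']].iloc[0].tolist()}"
        )
    if (table["concentration_um"] < 0).any():
        raise MetaboliteError("concentrations must be >= 0")
    return table


def _pivot_pair(
    table: pd.DataFrame, numerator: str, denominator: str
) -> pd.DataFrame:
    sub = table[table["metabolite"].isin([numerator, denominator])]
    relative = sub[sub["quantitation"] != "absolute"]
    if len(relative):
        raise MetaboliteError(
            f"cross-metabolite ratios need absolute quantitation; "
            f"{sorted(relative['metabolite'].unique())} are relative"
        )
    wide = sub.pivot_table(
        index=["sample_id", "strain", "treatment", "replicate"],
        columns="metabolite",
        values="concentration_um",
        aggfunc="first",
    ).reset_index()
    for m in (numerator, denominator):
        if m not in wide.columns or wide[m].isna().any():
            missing = (
                wide.loc[wide[m].isna(), "sample_id"].tolist()
                if m in wide.columns
                else wide["sample_id"].tolist()
            )
            raise MetaboliteError(f"metabolite {m!r} missing for sample(s) {missing[:5]}")
    return wide


def succ_kg_ratio(
    table: pd.DataFrame,
    numerator: str = SUCCINATE,
    denominator: str = KETOGLUTARATE,
) -> pd.DataFrame:
    """Per-sample succinate/2KG ratio, summarized per strain x treatment.

    Returns a frame with columns ``strain, treatment, mean_ratio, sd, n``.
    A zero denominator concentration is an error naming the sample.
    """
    table = _validate_table(table)
    wide = _pivot_pair(table, numerator, denominator)
    zero = wide[wide[denominator] == 0]
    if len(zero):
        raise MetaboliteError(
            f"{denominator} is 0 in sample(s) {zero['sample_id'].tolist()[:5]}; "
            "ratio undefined"
        )
    wide = wide.assign(ratio=wide[numerator] / wide[denominator])
    summary = (
        wide.groupby(["strain", "treatment"], observed=True)["ratio"]
        .agg(mean_ratio="mean", sd="std", n="count")
        .reset_index()
    )
    return summary


def per_sample_ratio(
    table: pd.DataFrame,
    numerator: str = SUCCINATE,
    denominator: str = KETOGLUTARATE,
) -> pd.DataFrame:
    """Unsummarized per-sample ratios (one row per sample)."""
    table = _validate_table(table)
    wide = _pivot_pair(table, numerator, denominator)
    zero = wide[wide[denominator] == 0]
    if len(zero):
        raise MetaboliteError(
            f"{denominator} is 0 in sample(s) {zero['sample_id'].tolist()[:5]}"
        )
    return wide.assign(ratio=wide[numerator] / wide[denominator])


def strain_fold(
    table: pd.DataFrame,
    metabolite: str,
    reference_strain: str = "WT",
) -> pd.DataFrame:
    """Per-strain fold-change of mean concentration over the reference strain,
    computed separately per treatment level."""
    table = _validate_table(table)
    sub = table[table["metabolite"] == metabolite]
    if sub.empty:
        raise MetaboliteError(f"metabolite {metabolite!r} not in table")
    if reference_strain not in set(sub["strain"]):
        raise MetaboliteError(f"reference strain {reference_strain!r} not in table")
    means = (
        sub.groupby(["strain", "treatment"], observed=True)["concentration_um"]
        .mean()
        .rename("mean_um")
        .reset_index()
    )
    ref = means[means["strain"] == reference_strain].set_index("treatment")["mean_um"]
    if (ref <= 0).any():
        raise MetaboliteError(f"reference strain mean is zero for {metabolite!r}")
    means["fold_vs_reference"] = means.apply(
        lambda r: r["mean_um"] / ref[r["treatment"]], axis=1
    )
    return means


def treatment_test(
    table: pd.DataFrame,
    metabolite: str,
) -> tuple[pd.DataFrame, list[PairwiseComparison]]:
    """Two-way ANOVA (strain, treatment, interaction) plus Tukey on cells.

    Requires a balanced complete strain x treatment design; the Tukey step
    compares all strain:treatment cell means.
    """
    table = _validate_table(table)
    sub = table[table["metabolite"] == metabolite]
    if sub.empty:
        raise MetaboliteError(f"metabolite {metabolite!r} not in table")
    try:
        anova = two_way_anova(sub, "strain", "treatment", "concentration_um")
    except StatsError as exc:
        raise MetaboliteError(str(exc)) from exc
    cells = [
        (f"{s}:{t}", grp["concentration_um"].to_numpy())
        for (s, t), grp in sub.groupby(["strain", "treatment"], observed=True)
    ]
    comparisons = tukey_hsd([v for _, v in cells], labels=[lab for lab, _ in cells])
    return anova, comparisons
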