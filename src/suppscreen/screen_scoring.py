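"""Screen Z statistic, assay-window check, hit calling, and exclusions.

The per-compound, per-timepoint screen statistic is the conventional
screening-window Z score

    z = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|

where (mu_p, sigma_p) describe the experimental (treated) wells and
(mu_n, sigma_n) the same plate's vehicle-control wells.  z is at most 1;
positive values mean the treated/control separation exceeds three combined
standard deviations.  Because each screened compound occupies a single well,
the control s.d. is substituted for the unavailable experimental s.d. (the
"mock s.d." rule), and mu_p is simply that well's OD.

A compound is a hit when z > 0 at at least ``min_positive`` of the
``n_timepoints`` reads *and* the treated OD exceeds the control mean at each
counted read (so growth inhibitors, which also separate from controls, do
not score).  Compounds whose formulation contains sulfate are excluded --
they feed the sulfur-scavenging pathway the screen reports on -- as are
compounds forming colored solutions that offset the OD reading.  Ranking
uses the median z across timepoints, ties broken lexicographically by
compound id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("none", "sulfate_formulation", "colored_solution")


class ScoringError(ValueError):
    """Invalid input to screen scoring."""


@dataclass(frozen=True)
class ScreenStats:
    """One compound's screen statistic at one timepoint."""

    compound_id: str
    time_h: float
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    z: float

    @property
    def undefined(self) -> bool:
        """True when mu_p == mu_n left z undefined (zero separation)."""
        return bool(np.isnan(self.z))


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    n_timepoints: int
    n_positive: int
    is_hit: bool
    excluded: bool
    exclusion_reason: str


def zscore(mu_p: float, sigma_p: float, mu_n: float, sigma_n: float) -> float:
    """Screening-window Z; NaN (undefined) when the means coincide.

    Invariant under a common positive rescaling of all four inputs (OD
    units cancel); strictly decreasing in the sigmas and strictly
    increasing in the separation |mu_p - mu_n|.
    """
    for v in (mu_p, sigma_p, mu_n, sigma_n):
        if not np.isfinite(v):
            raise ScoringError("z score inputs must be finite")
    if sigma_p < 0 or sigma_n < 0:
        raise ScoringError("standard deviations must be >= 0")
    separation = abs(mu_p - mu_n)
    if separation == 0:
        return float("nan")
    return 1.0 - 3.0 * (sigma_p + sigma_n) / separation


def compound_series(
    data: pd.DataFrame,
    compound_id: str,
) -> list[ScreenStats]:
    """Per-timepoint screen statistics for one compound.

    ``data`` is the annotated measurement frame (see
    :func:`suppscreen.plate_model.join_annotations`).  Controls are the
    ``negative_control`` wells pooled on the compound's own plate(s); their
    sample s.d. (n-1) supplies sigma_n, and, for a single-well compound,
    sigma_p as well.  Timepoints with no control reading are skipped with a
    warning.
    """
    exp = data[(data["compound_id"] == compound_id) & (data["role"] == "experimental")]
    if exp.empty:
        raise ScoringError(f"no experimental wells for compound {compound_id!r}")
    plates = exp["plate_id"].unique()
    controls = data[
        (data["role"] == "negative_control") & (data["plate_id"].isin(plates))
    ]
    n_control_wells = controls[["plate_id", "well"]].drop_duplicates().shape[0]
    if n_control_wells < 2:
        raise ScoringError(
            f"need >= 2 control wells on plate(s) {list(plates)}; found {n_control_wells}"
        )
    single_well = exp[["plate_id", "well"]].drop_duplicates().shape[0] == 1
    stats_out: list[ScreenStats] = []
    ctrl_by_time = controls.groupby("time_h")["od600"]
    ctrl_mean = ctrl_by_time.mean()
    ctrl_sd = ctrl_by_time.std(ddof=1)
    for time_h, grp in exp.groupby("time_h"):
        if time_h not in ctrl_mean.index:
            logger.warning(
                "no control reading at t=%s h for %s; timepoint skipped",
                time_h,
                compound_id,
            )
            continue
        mu_n = float(ctrl_mean.loc[time_h])
        sigma_n = float(ctrl_sd.loc[time_h])
        values = grp["od600"].to_numpy(dtype=float)
        if single_well:
            mu_p, sigma_p = float(values[0]), sigma_n
        else:
            mu_p, sigma_p = float(values.mean()), float(values.std(ddof=1))
        stats_out.append(
            ScreenStats(
                compound_id=compound_id,
                time_h=float(time_h),
                mu_p=mu_p,
                sigma_p=sigma_p,
                mu_n=mu_n,
                sigma_n=sigma_n,
                z=zscore(mu_p, sigma_p, mu_n, sigma_n),
            )
        )
    return stats_out


def score_all(data: pd.DataFrame) -> dict[str, list[ScreenStats]]:
    """Compound series for every compound present in the annotated frame."""
    ids = sorted(data.loc[data["role"] == "experimental", "compound_id"].dropna().unique())
    return {cid: compound_series(data, cid) for cid in ids}


def assay_window(
    positive: np.ndarray,
    negative: np.ndarray,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Assay-window Z per timepoint between two well groups.

    ``positive`` and ``negative`` are (wells x timepoints) OD arrays (e.g.
    WT vs SDH-loss wells in ISE); each group uses its own mean and sample
    s.d.  Returns the per-timepoint z array and ``pass = all(z > 0)``.
    """
    pos = np.atleast_2d(np.asarray(positive, dtype=float))
    neg = np.atleast_2d(np.asarray(negative, dtype=float))
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ScoringError("each group needs >= 2 wells")
    if pos.shape[1] != neg.shape[1]:
        raise ScoringError("groups must share the same timepoints")
    z = np.array(
        [
            zscore(
                pos[:, j].mean(),
                pos[:, j].std(ddof=1),
                neg[:, j].mean(),
                neg[:, j].std(ddof=1),
            )
            for j in range(pos.shape[1])
        ]
    )
    ok = bool(np.all(np.nan_to_num(z, nan=-np.inf) > 0))
    return z, ok


def call_hits(
    series: dict[str, list[ScreenStats]],
    library: pd.DataFrame,
    min_positive: int = 6,
    n_timepoints: int = 7,
) -> list[HitCall]:
    """Classify compounds as hits and apply formulation exclusions.

    A timepoint counts as positive when z > 0 and the treated mean exceeds
    the control mean (growth stimulation, not just separation).
    """
    lib = library.set_index("compound_id")
    calls: list[HitCall] = []
    for cid in sorted(series):
        if cid not in lib.index:
            raise ScoringError(f"compound {cid!r} absent from library")
        stats_list = series[cid]
        n_pos = sum(
            1
            for s in stats_list
            if not s.undefined and s.z > 0 and s.mu_p > s.mu_n
        )
        row = lib.loc[cid]
        if bool(row["contains_sulfate"]):
            excluded, reason = True, "sulfate_formulation"
        elif bool(row["colored_solution"]):
            excluded, reason = True, "colored_solution"
        else:
            excluded, reason = False, "none"
        calls.append(
            HitCall(
                compound_id=cid,
                n_timepoints=len(stats_list),
                n_positive=n_pos,
                is_hit=(n_pos >= min_positive) and not excluded,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    return calls


def rank_hits(
    calls: list[HitCall],
    series: dict[str, list[ScreenStats]],
    library: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ranked hit report: compounds sorted by median z, descending.

    Ties break lexicographically by compound id.  Exclusion annotations are
    carried so a report can show the +/- sulfate column alongside ranks.
    """
    missing = [c.compound_id for c in calls if c.compound_id not in series]
    if missing:
        raise ScoringError(f"no score series for {missing[:5]}")
    rows = []
    for call in calls:
        zs = np.array([s.z for s in series[call.compound_id]], dtype=float)
        finite = zs[np.isfinite(zs)]
        summary = float(np.median(finite)) if finite.size else float("nan")
        rows.append(
            {
                "compound_id": call.compound_id,
                "summary_z": summary,
                "n_positive": call.n_positive,
                "is_hit": call.is_hit,
                "excluded": call.excluded,
                "exclusion_reason": call.exclusion_reason,
            }
        )
    report = pd.DataFrame(rows)
    if library is not None:
        report = report.merge(
            library[["compound_id", "name"]], on="compound_id", how="left"
        )
    report = report.sort_values(
        ["summary_z", "compound_id"],
        ascending=[False, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    return report
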