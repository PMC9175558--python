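"""Endpoint growth, diauxic-shift detection, percent change, selectivity.

Percent growth change compares treated with untreated endpoint OD600 at the
end of the 24 h assay:

    pct = 100 * (t - u) / u

with first-order (delta-method) error propagation over independent treated
and untreated errors:

    err = 100 * sqrt( (s_t / u)^2 + (t * s_u / u^2)^2 )

Diauxic-shift detection looks for two local maxima of the smoothed growth
rate (centered moving average of the first difference) separated by a rate
minimum below half the smaller maximum -- the deceleration between
fermentative and oxidative growth phases.

The selectivity classifier encodes the validation criterion: a compound is a
selective suppressor when it significantly stimulates both SDH-loss strains
in ISE while leaving WT and jlp1 in ISE, and every strain in AS, without a
significant positive effect.  A significant jlp1 rescue in ISE instead flags
a sulfur-bypass suspect (the compound feeds the pathway the screen relies
on), and a dominant significant negative effect flags toxicity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .plate_model import MEDIA, STRAINS

logger = logging.getLogger(__name__)

VERDICTS = ("selective_suppressor", "nonspecific", "bypass_suspect", "inactive", "toxic")


class GrowthMetricError(ValueError):
    """Invalid input to a growth-metric computation."""


@dataclass(frozen=True)
class GrowthEffect:
    """Percent growth change (+- propagated error) for one
    strain x medium x compound x dose cell."""

    strain: str
    medium: str
    compound_id: str
    concentration_um: float
    pct_change: float
    pct_change_err: float
    n_replicates: int
    endpoint_treated: tuple[float, float]  # (mean, sd)
    endpoint_untreated: tuple[float, float]


@dataclass(frozen=True)
class DiauxicCall:
    detected: bool
    shift_time_h: float | None
    phase1_rate_max: float
    phase2_rate_max: float


@dataclass(frozen=True)
class SelectivityVerdict:
    compound_id: str
    verdict: str
    cells: pd.DataFrame = field(compare=False)


def endpoint_growth(times, ods, target_h: float = 24.0) -> float:
    """OD at the latest timepoint <= ``target_h``.

    If every timepoint is later than the target, the earliest reading is
    returned with a warning (the assay ended before it began relative to the
    requested endpoint).
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.size == 0:
        raise GrowthMetricError("empty OD series")
    order = np.argsort(t, kind="stable")
    t, od = t[order], od[order]
    at_or_before = t <= target_h
    if not at_or_before.any():
        warnings.warn(
            f"no timepoint <= {target_h} h; using earliest reading at {t[0]} h",
            stacklevel=2,
        )
        return float(od[0])
    return float(od[at_or_before][-1])


def percent_change(
    treated_mean: float,
    treated_sd: float,
    untreated_mean: float,
    untreated_sd: float,
) -> tuple[float, float]:
    """Percent growth change and its first-order propagated error."""
    if untreated_mean <= 0:
        raise GrowthMetricError("untreated mean OD must be > 0")
    if treated_sd < 0 or untreated_sd < 0:
        raise GrowthMetricError("standard deviations must be >= 0")
    pct = 100.0 * (treated_mean - untreated_mean) / untreated_mean
    err = 100.0 * np.sqrt(
        (treated_sd / untreated_mean) ** 2
        + (treated_mean * untreated_sd / untreated_mean**2) ** 2
    )
    return float(pct), float(err)


def detect_diauxic(
    times,
    ods,
    smooth_window: int = 3,
    min_phase_rate: float = 0.02,
) -> DiauxicCall:
    """Detect a diauxic shift in one OD series.

    The centered-moving-average first-difference rate must show two local
    maxima >= ``min_phase_rate`` separated by a local minimum below half the
    smaller maximum; the shift time is at that minimum.  Invariant to
    additive OD offsets (only differences enter).
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if t.size < 5:
        raise GrowthMetricError("need at least 5 timepoints")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise GrowthMetricError("smooth_window must be a positive odd integer")
    rate = np.diff(od) / np.diff(t)
    mid_t = 0.5 * (t[:-1] + t[1:])
    if smooth_window > 1 and rate.size >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(rate, kernel, mode="valid")
        offset = smooth_window // 2
        mid_t = mid_t[offset : offset + smoothed.size]
    else:
        smoothed = rate

    peaks, _ = find_peaks(smoothed, height=min_phase_rate)
    if peaks.size < 2:
        hi = float(smoothed.max()) if smoothed.size else 0.0
        return DiauxicCall(False, None, hi, 0.0)
    # Consider the best-separated pair among qualifying peaks: take the two
    # tallest in time order and test the valley between them.
    top2 = np.sort(peaks[np.argsort(smoothed[peaks])[-2:]])
    i, j = int(top2[0]), int(top2[1])
    valley_idx = i + int(np.argmin(smoothed[i : j + 1]))
    valley = float(smoothed[valley_idx])
    smaller_peak = float(min(smoothed[i], smoothed[j]))
    detected = valley < 0.5 * smaller_peak
    return DiauxicCall(
        detected=bool(detected),
        shift_time_h=float(mid_t[valley_idx]) if detected else None,
        phase1_rate_max=float(smoothed[i]),
        phase2_rate_max=float(smoothed[j]),
    )


def effects_frame(effects) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append(
            {
                "strain": e.strain,
                "medium": e.medium,
                "compound_id": e.compound_id,
                "concentration_um": e.concentration_um,
                "pct_change": e.pct_change,
                "pct_change_err": e.pct_change_err,
                "n_replicates": e.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def validation_effects(
    joined: pd.DataFrame,
    target_h: float = 24.0,
    se: bool = False,
) -> pd.DataFrame:
    """Per-cell growth effects from an annotated validation dataset.

    For every strain x medium x compound x dose cell, the treated wells
    (role ``experimental``) are compared with the untreated wells (role
    ``untreated_reference``) of the same strain and medium: endpoint OD at
    ``target_h``, percent change with propagated error, and a Tukey-adjusted
    p for the treated-vs-untreated contrast (with two groups this equals the
    pooled two-sample t-test p).  ``se=True`` propagates standard errors
    (s.d. / sqrt(n)) instead of standard deviations.

    Returns a frame with one row per cell, ready for
    :func:`classify_selectivity`.
    """
    from .stats_core import tukey_hsd  # local import keeps module load light

    required = {"strain", "medium", "role", "compound_id", "time_h", "od600"}
    missing = required - set(joined.columns)
    if missing:
        raise GrowthMetricError(f"missing column(s): {sorted(missing)}")

    def cell_endpoints(frame: pd.DataFrame) -> np.ndarray:
        values = [
            endpoint_growth(g["time_h"], g["od600"], target_h)
            for _, g in frame.groupby(["plate_id", "well"])
        ]
        return np.asarray(values, dtype=float)

    rows = []
    treated_all = joined[joined["role"] == "experimental"]
    for (strain, medium, cid, conc), grp in treated_all.groupby(
        ["strain", "medium", "compound_id", "concentration_um"]
    ):
        untreated = joined[
            (joined["role"] == "untreated_reference")
            & (joined["strain"] == strain)
            & (joined["medium"] == medium)
        ]
        if untreated.empty:
            raise GrowthMetricError(
                f"no untreated reference wells for ({strain}, {medium})"
            )
        t_vals = cell_endpoints(grp)
        u_vals = cell_endpoints(untreated)
        scale_t = np.sqrt(len(t_vals)) if se else 1.0
        scale_u = np.sqrt(len(u_vals)) if se else 1.0
        pct, err = percent_change(
            t_vals.mean(),
            t_vals.std(ddof=1) / scale_t,
            u_vals.mean(),
            u_vals.std(ddof=1) / scale_u,
        )
        (comparison,) = tukey_hsd([t_vals, u_vals], labels=["treated", "untreated"])
        rows.append(
            {
                "strain": strain,
                "medium": medium,
                "compound_id": cid,
                "concentration_um": conc,
                "pct_change": pct,
                "pct_change_err": err,
                "n_replicates": len(t_vals),
                "p_adjusted": comparison.p_adjusted,
                "stars": comparison.stars,
            }
        )
    return pd.DataFrame(rows)


def classify_selectivity(
    cells: pd.DataFrame,
    alpha: float = 0.05,
    compound_id: str | None = None,
) -> SelectivityVerdict:
    """Classify a validated compound from its per-cell effects.

    ``cells`` is a frame with columns ``strain, medium, concentration_um,
    pct_change, p_adjusted`` covering all 8 strain x medium cells at one or
    more doses (the criterion is dose-agnostic: any tested dose may satisfy
    the pattern).  A cell is significantly positive/negative when its
    adjusted p is below ``alpha`` with the corresponding sign.
    """
    required = {"strain", "medium", "pct_change", "p_adjusted"}
    missing_cols = required - set(cells.columns)
    if missing_cols:
        raise GrowthMetricError(f"missing column(s): {sorted(missing_cols)}")
    have = set(zip(cells["strain"], cells["medium"]))
    missing = [(s, m) for s in STRAINS for m in MEDIA if (s, m) not in have]
    if missing:
        raise GrowthMetricError(f"missing strain x medium cell(s): {missing}")
    if compound_id is None:
        compound_id = (
            str(cells["compound_id"].iloc[0]) if "compound_id" in cells.columns else ""
        )

    sig = cells["p_adjusted"] < alpha

    def sig_positive(strain: str, medium: str) -> bool:
        mask = (cells["strain"] == strain) & (cells["medium"] == medium)
        return bool((sig & mask & (cells["pct_change"] > 0)).any())

    def sig_negative_any() -> bool:
        return bool((sig & (cells["pct_change"] < 0)).any())

    def sig_positive_any() -> bool:
        return bool((sig & (cells["pct_change"] > 0)).any())

    mutant_rescue = sig_positive("sdh1", "ISE") and sig_positive("sdh2", "ISE")
    off_target = (
        sig_positive("WT", "ISE")
        or sig_positive("jlp1", "ISE")
        or any(sig_positive(s, "AS") for s in STRAINS)
    )
    if mutant_rescue and not off_target:
        verdict = "selective_suppressor"
    elif sig_positive("jlp1", "ISE"):
        verdict = "bypass_suspect"
    elif sig_negative_any() and not sig_positive_any():
        verdict = "toxic"
    elif sig_positive_any():
        verdict = "nonspecific"
    else:
        verdict = "inactive"
    return SelectivityVerdict(compound_id, verdict, cells.copy())
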