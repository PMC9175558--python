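"""Screen scoring: Z statistic, compound series, hit calls, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from suppscreen.screen_scoring import (
    HitCall,
    ScoringError,
    ScreenStats,
    assay_window,
    call_hits,
    compound_series,
    rank_hits,
    score_all,
    zscore,
)
from suppscreen.plate_model import CompoundRecord, library_frame


class TestZScore:
    def test_hand_example(self):
        assert zscore(0.30, 0.01, 0.20, 0.01) == pytest.approx(0.40)

    def test_zero_noise_ceiling(self):
        assert zscore(0.5, 0.0, 0.2, 0.0) == 1.0

    def test_zero_separation_is_undefined(self):
        assert math.isnan(zscore(0.3, 0.01, 0.3, 0.01))

    def test_rejects_nonfinite_and_negative_sd(self):
        with pytest.raises(ScoringError):
            zscore(float("inf"), 0.0, 0.2, 0.0)
        with pytest.raises(ScoringError):
            zscore(0.3, -0.01, 0.2, 0.01)

    @given(
        mu_p=st.floats(0.0, 2.0),
        mu_n=st.floats(0.0, 2.0),
        sp=st.floats(0.0, 0.5),
        sn=st.floats(0.0, 0.5),
        gain=st.floats(0.01, 100.0),
    )
    def test_invariant_under_common_positive_gain(self, mu_p, mu_n, sp, sn, gain):
        z = zscore(mu_p, sp, mu_n, sn)
        z_scaled = zscore(gain * mu_p, gain * sp, gain * mu_n, gain * sn)
        if math.isnan(z):
            assert math.isnan(z_scaled)
        else:
            assert z_scaled == pytest.approx(z, rel=1e-9, abs=1e-9)

    def test_monotone_in_sigma_and_separation(self):
        base = zscore(0.4, 0.01, 0.2, 0.01)
        assert zscore(0.4, 0.01, 0.2, 0.02) < base  # noisier controls
        assert zscore(0.5, 0.01, 0.2, 0.01) > base  # wider separation

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mu_p, mu_n = rng.uniform(0, 1, 2)
            if mu_p == mu_n:
                continue
            assert zscore(mu_p, rng.uniform(0, 0.2), mu_n, rng.uniform(0, 0.2)) <= 1.0


def _annotated_single_plate(compound_od, control_ods, times=(0.0,)):
    """Minimal annotated frame: one compound well + controls on plate P1."""
    rows = []
    for t in times:
        rows.append(("P1", "A1", t, compound_od, "CX", "experimental"))
        for i, od in enumerate(control_ods):
            rows.append(("P1", f"H{i + 1}", t, od, None, "negative_control"))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "well", "time_h", "od600", "compound_id", "role"],
    )


class TestCompoundSeries:
    def test_mock_sd_hand_computation(self):
        data = _annotated_single_plate(0.25, [0.19, 0.20, 0.20, 0.21])
        (s,) = compound_series(data, "CX")
        assert s.mu_n == pytest.approx(0.20)
        assert s.sigma_n == pytest.approx(0.008165, abs=1e-6)
        assert s.sigma_p == s.sigma_n  # single well: mock s.d. rule
        assert s.z == pytest.approx(1 - 6 * 0.0081649658 / 0.05, abs=1e-6)
        assert s.z == pytest.approx(0.0202, abs=1e-3)

    def test_identical_controls_give_unit_z(self):
        data = _annotated_single_plate(0.25, [0.2, 0.2, 0.2, 0.2])
        (s,) = compound_series(data, "CX")
        assert s.z == 1.0

    def test_one_stat_per_timepoint(self):
        times = tuple(np.linspace(0, 24, 7))
        data = _annotated_single_plate(0.25, [0.19, 0.2, 0.2, 0.21], times)
        assert len(compound_series(data, "CX")) == 7

    def test_fewer_than_two_controls_is_an_error(self):
        data = _annotated_single_plate(0.25, [0.2])
        with pytest.raises(ScoringError, match="control"):
            compound_series(data, "CX")

    def test_missing_control_timepoint_skipped_with_warning(self, caplog):
        data = _annotated_single_plate(0.25, [0.19, 0.2, 0.2, 0.21], (0.0, 4.0))
        data = data[~((data["role"] == "negative_control") & (data["time_h"] == 4.0))]
        with caplog.at_level("WARNING"):
            series = compound_series(data, "CX")
        assert len(series) == 1
        assert "skipped" in caplog.text

    def test_multi_well_compound_uses_its_own_sd(self):
        base = _annotated_single_plate(0.25, [0.19, 0.2, 0.2, 0.21])
        extra = base.iloc[[0]].assign(well="B1", od600=0.27)
        (s,) = compound_series(pd.concat([base, extra]), "CX")
        assert s.mu_p == pytest.approx(0.26)
        assert s.sigma_p == pytest.approx(np.std([0.25, 0.27], ddof=1))


class TestAssayWindow:
    def test_separated_groups_pass(self):
        rng = np.random.default_rng(0)
        pos = 0.8 + rng.normal(0, 0.02, size=(4, 7))
        neg = 0.4 + rng.normal(0, 0.02, size=(4, 7))
        z, ok = assay_window(pos, neg)
        assert ok and np.all(z > 0) and len(z) == 7

    def test_identical_distributions_fail(self):
        wells = np.tile([0.4, 0.41, 0.39, 0.4], (3, 1)).T
        z, ok = assay_window(wells, wells)
        assert not ok

    def test_one_overlapping_timepoint_fails_the_window(self):
        rng = np.random.default_rng(1)
        pos = 0.8 + rng.normal(0, 0.02, size=(4, 7))
        neg = 0.4 + rng.normal(0, 0.02, size=(4, 7))
        neg[:, 3] = pos[:, 3] + rng.normal(0, 0.001, 4)  # collapse one read
        z, ok = assay_window(pos, neg)
        assert not ok and not (z[3] > 0)

    def test_small_groups_rejected(self):
        with pytest.raises(ScoringError):
            assay_window(np.ones((1, 7)), np.ones((4, 7)))


def _series(cid, zs, direction=1.0):
    return [
        ScreenStats(cid, float(t), 0.3 + 0.1 * direction, 0.01, 0.3, 0.01, z)
        for t, z in enumerate(zs)
    ]


def _library(ids, sulfate=(), colored=()):
    return library_frame(
        CompoundRecord(c, c, contains_sulfate=c in sulfate, colored_solution=c in colored)
        for c in ids
    )


class TestCallAndRankHits:
    def test_six_of_seven_rule(self):
        series = {"A": _series("A", [0.1, 0.2, 0.05, 0.3, -0.1, 0.15, 0.2])}
        (call,) = call_hits(series, _library(["A"]))
        assert call.n_positive == 6 and call.is_hit

    def test_all_negative_not_hit(self):
        series = {"A": _series("A", [-0.2] * 7)}
        (call,) = call_hits(series, _library(["A"]))
        assert call.n_positive == 0 and not call.is_hit

    def test_inhibitor_direction_not_counted(self):
        series = {"A": _series("A", [0.5] * 7, direction=-1.0)}  # mu_p < mu_n
        (call,) = call_hits(series, _library(["A"]))
        assert call.n_positive == 0 and not call.is_hit

    def test_sulfate_formulation_excluded_despite_positive_scores(self):
        series = {"A": _series("A", [0.5] * 7)}
        (call,) = call_hits(series, _library(["A"], sulfate={"A"}))
        assert call.excluded and call.exclusion_reason == "sulfate_formulation"
        assert not call.is_hit

    def test_colored_solution_exclusion(self):
        series = {"A": _series("A", [0.5] * 7)}
        (call,) = call_hits(series, _library(["A"], colored={"A"}))
        assert call.exclusion_reason == "colored_solution" and not call.is_hit

    def test_unknown_compound_is_an_error(self):
        series = {"A": _series("A", [0.5] * 7)}
        with pytest.raises(ScoringError, match="absent"):
            call_hits(series, _library(["B"]))

    def test_rank_by_median_z_with_lexicographic_ties(self):
        series = {
            "B": _series("B", [0.1] * 7),
            "A": _series("A", [0.4] * 7),
            "C": _series("C", [0.1] * 7),
        }
        calls = call_hits(series, _library(["A", "B", "C"]))
        report = rank_hits(calls, series)
        assert list(report["compound_id"]) == ["A", "B", "C"]
        assert report.loc[0, "summary_z"] == pytest.approx(0.4)


def test_planted_screen_end_to_end(joined_screen, screen_dataset):
    """Suppressors score as hits; bypass/colored compounds are excluded."""
    series = score_all(joined_screen)
    calls = call_hits(series, screen_dataset.library)
    truth = screen_dataset.truth.set_index("compound_id")["effect_class"]
    by_class: dict[str, list[HitCall]] = {}
    for call in calls:
        by_class.setdefault(truth[call.compound_id], []).append(call)
    supp_hits = [c for c in by_class["suppressor"] if c.is_hit]
    assert len(supp_hits) / len(by_class["suppressor"]) >= 0.9
    assert all(c.excluded for c in by_class["sulfate_bypass"])
    assert all(c.excluded for c in by_class["colored"])
    assert not any(c.is_hit for c in by_class["toxic"])
    report = rank_hits(calls, series, screen_dataset.library)
    # every strong suppressor outranks every inert compound
    ranks = report.set_index("compound_id").index
    worst_supp = max(ranks.get_loc(c.compound_id) for c in by_class["suppressor"])
    best_inert = min(ranks.get_loc(c.compound_id) for c in by_class["inert"])
    assert worst_supp < best_inert
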