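"""Synthetic-data generator: curve contracts, layout counts, planted truth."""

import numpy as np
import pandas as pd
import pytest

from suppscreen.plate_model import ValidationError
from suppscreen.synthetic_data import (
    DEFAULT_KINETICS,
    SimulationConfig,
    StrainKinetics,
    bypass_effect,
    colored_effect,
    growth_curve,
    planted_effects,
    simulate_abundance,
    simulate_metabolites,
    simulate_screen,
    simulate_validation,
    suppressor_effect,
    toxic_effect,
)

TIMES = np.linspace(0, 24, 49)
KIN = StrainKinetics("sdh1", "ISE", od0=0.05, cap1=0.5, rate1=0.8, mid1=6.0)
KIN_DIAUXIC = StrainKinetics(
    "WT", "AS", od0=0.05, cap1=0.5, rate1=1.2, mid1=6.0,
    cap2=0.4, rate2=1.0, mid2=16.0, diauxic=True,
)


class TestGrowthCurve:
    def test_noiseless_endpoint_matches_closed_form(self):
        t = np.array([0.0, 200.0])
        od = growth_curve(KIN, None, t)
        assert od[-1] == pytest.approx(0.05 + 0.5, abs=1e-9)
        od2 = growth_curve(KIN_DIAUXIC, None, t)
        assert od2[-1] == pytest.approx(0.05 + 0.5 + 0.4, abs=1e-9)

    def test_suppressor_scales_growth_above_baseline(self):
        t = np.array([0.0, 200.0])
        inert = growth_curve(KIN, None, t)[-1]
        lifted = growth_curve(KIN, suppressor_effect("c", 0.15), t)[-1]
        assert lifted - KIN.od0 == pytest.approx(1.15 * (inert - KIN.od0), rel=1e-12)

    def test_effect_ignored_off_target(self):
        effect = suppressor_effect("c", 0.15)  # targets sdh in ISE only
        wt = DEFAULT_KINETICS[("WT", "ISE")]
        assert np.allclose(growth_curve(wt, effect, TIMES), growth_curve(wt, None, TIMES))

    def test_colored_effect_is_constant_offset(self):
        base = growth_curve(KIN, None, TIMES)
        shifted = growth_curve(KIN, colored_effect("c", 0.3), TIMES)
        assert np.allclose(shifted - base, 0.3)

    def test_seed_determinism(self):
        a = growth_curve(KIN, None, TIMES, 0.02, np.random.default_rng(7))
        b = growth_curve(KIN, None, TIMES, 0.02, np.random.default_rng(7))
        c = growth_curve(KIN, None, TIMES, 0.02, np.random.default_rng(8))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            growth_curve(KIN, None, [2.0, 1.0])
        with pytest.raises(ValidationError):
            growth_curve(KIN, None, TIMES, noise_sd=-0.1)
        with pytest.raises(ValidationError):
            toxic_effect("c", magnitude=0.5)

    def test_noiseless_curves_monotone_nondecreasing(self):
        for kin in DEFAULT_KINETICS.values():
            od = growth_curve(kin, None, TIMES)
            assert np.all(np.diff(od) >= -1e-12), kin.strain

    def test_diauxic_rate_has_single_interior_minimum_between_phases(self):
        od = growth_curve(KIN_DIAUXIC, None, TIMES)
        rate = np.diff(od)
        peak1 = rate[: len(rate) // 2].argmax()
        peak2 = rate[len(rate) // 2 :].argmax() + len(rate) // 2
        between = rate[peak1 : peak2 + 1]
        # one sign change of the first difference of the rate: down then up
        direction = np.sign(np.diff(between))
        changes = np.count_nonzero(np.diff(direction[direction != 0]) != 0)
        assert changes == 1


class TestSimulateScreen:
    def test_default_geometry(self):
        config = SimulationConfig(seed=0)
        ds = simulate_screen(config)
        ann = ds.annotations
        assert config.n_plates == 16
        assert (ann["role"] == "experimental").sum() == 1280
        assert (ann["role"] == "negative_control").sum() == 64
        assert ann["plate_id"].nunique() == 16

    def test_single_compound_record_count(self):
        config = SimulationConfig(seed=0, library_size=1)
        ds = simulate_screen(config)
        assert len(ds.measurements) == (1 + 4) * 7 == 35
        assert ds.annotations["plate_id"].nunique() == 1

    def test_truth_conserves_planted_counts(self):
        config = SimulationConfig(seed=3, library_size=400, compounds_per_plate=80)
        effects = planted_effects(
            config, np.random.default_rng(3),
            suppressor_fraction=0.05, n_bypass=6, n_colored=2, n_toxic=3,
        )
        ds = simulate_screen(config, effects)
        counts = ds.truth["effect_class"].value_counts()
        assert counts["suppressor"] == round(0.05 * 400)
        assert counts["sulfate_bypass"] == 6
        assert counts["colored"] == 2
        assert counts["toxic"] == 3
        assert counts.sum() == 400

    def test_capacity_error_reports_required_plates(self):
        config = SimulationConfig(seed=0, compounds_per_plate=95, library_size=190)
        with pytest.raises(ValidationError, match="capacity"):
            simulate_screen(config)

    def test_deterministic_under_config_seed(self):
        config = SimulationConfig(seed=9, library_size=40, compounds_per_plate=40)
        a = simulate_screen(config)
        b = simulate_screen(config)
        assert a.measurements == b.measurements
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_sulfate_flag_follows_bypass_class(self):
        config = SimulationConfig(seed=1, library_size=10, compounds_per_plate=10)
        ds = simulate_screen(config, [bypass_effect("C0003")])
        lib = ds.library.set_index("compound_id")
        assert lib.loc["C0003", "contains_sulfate"]
        assert not lib.drop("C0003")["contains_sulfate"].any()


class TestSimulateValidation:
    def test_covers_all_cells_with_replicates(self):
        ds = simulate_validation(suppressor_effect("s"), n_reps=4, seed=0)
        ann = ds.annotations
        cells = ann.groupby(["strain", "medium", "role"]).size()
        assert len(cells) == 4 * 2 * 2
        assert (cells == 4).all()

    def test_requires_two_replicates(self):
        with pytest.raises(ValidationError):
            simulate_validation(suppressor_effect("s"), n_reps=1)


class TestSimulateAbundance:
    def test_zero_de_counts_gives_null_truth(self):
        _, _, truth = simulate_abundance(
            n_proteins=50, de_shared=0, de_a_only=0, de_b_only=0, seed=0
        )
        assert not truth["differential"].any()

    def test_default_partition_mirrors_shared_mostly_structure(self):
        _, _, truth = simulate_abundance(n_proteins=1200, seed=0)
        counts = truth["comparison"].value_counts()
        assert counts["shared"] == 991
        assert counts["a_only"] == 24
        assert counts["b_only"] == 77

    def test_replicate_minimum_enforced(self):
        with pytest.raises(ValidationError):
            simulate_abundance(n_proteins=10, n_replicates=1)

    def test_noiseless_matrix_encodes_exact_fold_changes(self):
        m, g, truth = simulate_abundance(
            n_proteins=200, de_shared=30, de_a_only=5, de_b_only=5,
            noise_sd=0.0, absent_fraction=0.0, seed=4,
        )
        wt = m.loc[:, g == "WT"].mean(axis=1)
        a = m.loc[:, g == "sdh1"].mean(axis=1)
        lfc = np.log2(a / wt)
        assert np.allclose(lfc, truth["true_log2fc_a"], atol=1e-9)


class TestSimulateMetabolites:
    def test_noiseless_fold_is_exact(self):
        table, _ = simulate_metabolites(cv=0.0, seed=0)
        means = table[table["metabolite"] == "succinate"].groupby("strain")[
            "concentration_um"
        ].mean()
        assert means["sdh1"] / means["WT"] != 5.0  # treatment lowers mutant mean
        untreated = table[
            (table["metabolite"] == "succinate") & (table["treatment"] == "untreated")
        ].groupby("strain")["concentration_um"].mean()
        assert untreated["sdh1"] / untreated["WT"] == pytest.approx(5.0)

    def test_null_treatment_truth_is_flat(self):
        _, truth = simulate_metabolites(treatment_effect=0.0, seed=0)
        succ = truth[truth["metabolite"] == "succinate"]
        by_strain = succ.groupby("strain")["true_mean_um"].nunique()
        assert (by_strain == 1).all()

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            simulate_metabolites(succinate_fold=0.0)
        with pytest.raises(ValidationError):
            simulate_metabolites(n_reps=1)
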