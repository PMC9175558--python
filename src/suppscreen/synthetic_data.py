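"""Synthetic plate, proteome, and metabolite data with planted ground truth.

Generates datasets with the statistical structure the downstream analysis
assumes: four yeast strains (WT, sdh1, sdh2, jlp1) growing in two sulfur
media (AS, ISE), a 1280-compound library screened at 80 compounds per plate
with 4 vehicle-control wells, mitochondrial proteomes with ~1000
differential proteins mostly shared between the two SDH-loss mutants, and
metabolite tables with succinate elevated up to ~5-fold and 2-ketoglutarate
reduced in the mutants.

Growth model
------------
Per-well OD600 is a sum of one or two logistic terms,

    OD(t) = od0 + cap1 * expit(rate1 * (t - mid1))
                [+ cap2 * expit(rate2 * (t - mid2)) if diauxic]

plus additive Gaussian noise truncated at zero.  The double-logistic form is
the minimal curve family with an identifiable inter-phase deceleration (the
diauxic shift between fermentative and oxidative growth).  A compound effect
that applies to a well's (strain, medium) scales the capacities by
(1 + magnitude); a colored compound instead adds a constant OD offset
(absorbance, not growth).

Default strain-by-medium kinetics are calibrated qualitatively: in AS all
strains reach similar 24 h density with WT and jlp1 diauxic; in ISE the
ordering is WT > sdh1 ~ sdh2 >> jlp1 (jlp1 near-flat, as its sulfonate
dioxygenase is deleted).  ISE kinetics saturate early so that a 10-20%
capacity lift is separable from control-well noise at nearly every read --
the regime in which a 6-of-7-timepoint hit rule has power (see
docs/methods.md).  All randomness flows through explicit seeded generators;
identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .plate_model import (
    MEASUREMENT_COLUMNS,
    MEDIA,
    ROW_LETTERS,
    STRAINS,
    CompoundRecord,
    MeasurementTable,
    ValidationError,
    WellAddress,
    WellAnnotation,
    annotations_frame,
    library_frame,
)

EFFECT_CLASSES = ("inert", "suppressor", "sulfate_bypass", "toxic", "colored")

DEFAULT_TIMEPOINTS_H = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)

SCREEN_STRAIN = "sdh1"
SCREEN_MEDIUM = "ISE"


@dataclass(frozen=True)
class StrainKinetics:
    """Noiseless growth-curve parameters for one strain in one medium."""

    strain: str
    medium: str
    od0: float
    cap1: float
    rate1: float
    mid1: float
    cap2: float = 0.0
    rate2: float = 0.0
    mid2: float = 0.0
    diauxic: bool = False

    def __post_init__(self) -> None:
        if self.od0 < 0 or self.cap1 <= 0 or self.rate1 <= 0:
            raise ValidationError("od0 >= 0, cap1 > 0 and rate1 > 0 required")
        if self.diauxic:
            if self.cap2 <= 0 or self.rate2 <= 0:
                raise ValidationError("diauxic kinetics need cap2 > 0 and rate2 > 0")
            if self.mid2 <= self.mid1:
                raise ValidationError("diauxic kinetics need mid2 > mid1")

    def noiseless(self, times: np.ndarray, cap_scale: float = 1.0) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        od = self.od0 + cap_scale * self.cap1 * expit(self.rate1 * (t - self.mid1))
        if self.diauxic:
            od = od + cap_scale * self.cap2 * expit(self.rate2 * (t - self.mid2))
        return od


#: Qualitative calibration of the eight strain x medium growth phenotypes.
DEFAULT_KINETICS: dict[tuple[str, str], StrainKinetics] = {
    ("WT", "AS"): StrainKinetics(
        "WT", "AS", od0=0.05, cap1=0.75, rate1=0.9, mid1=5.0,
        cap2=0.35, rate2=0.7, mid2=14.0, diauxic=True,
    ),
    ("jlp1", "AS"): StrainKinetics(
        "jlp1", "AS", od0=0.05, cap1=0.72, rate1=0.9, mid1=5.0,
        cap2=0.33, rate2=0.7, mid2=14.0, diauxic=True,
    ),
    ("sdh1", "AS"): StrainKinetics("sdh1", "AS", od0=0.05, cap1=1.05, rate1=0.8, mid1=6.0),
    ("sdh2", "AS"): StrainKinetics("sdh2", "AS", od0=0.05, cap1=1.02, rate1=0.8, mid1=6.0),
    ("WT", "ISE"): StrainKinetics("WT", "ISE", od0=0.05, cap1=1.30, rate1=1.5, mid1=2.0),
    ("sdh1", "ISE"): StrainKinetics("sdh1", "ISE", od0=0.05, cap1=0.95, rate1=1.5, mid1=2.0),
    ("sdh2", "ISE"): StrainKinetics("sdh2", "ISE", od0=0.05, cap1=0.92, rate1=1.5, mid1=2.0),
    ("jlp1", "ISE"): StrainKinetics("jlp1", "ISE", od0=0.05, cap1=0.06, rate1=0.3, mid1=10.0),
}


@dataclass(frozen=True)
class CompoundEffect:
    """Planted ground-truth effect of one library compound.

    ``magnitude`` is a fractional capacity change for growth effects
    (suppressor default within +0.10..+0.20, toxic negative) and a constant
    OD offset for ``colored`` compounds.
    """

    compound_id: str
    effect_class: str = "inert"
    magnitude: float = 0.0
    target_strains: frozenset = frozenset(STRAINS)
    target_media: frozenset = frozenset(MEDIA)

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValidationError(f"unknown effect class {self.effect_class!r}")
        if self.effect_class == "toxic" and self.magnitude >= 0:
            raise ValidationError("toxic effects need magnitude < 0")
        if self.effect_class == "toxic" and self.magnitude <= -1:
            raise ValidationError("toxic magnitude must stay above -1")

    def applies_to(self, strain: str, medium: str) -> bool:
        return strain in self.target_strains and medium in self.target_media


def suppressor_effect(compound_id: str, magnitude: float = 0.15) -> CompoundEffect:
    """A selective suppressor: lifts SDH-loss growth in ISE only."""
    return CompoundEffect(
        compound_id,
        "suppressor",
        magnitude,
        target_strains=frozenset({"sdh1", "sdh2"}),
        target_media=frozenset({"ISE"}),
    )


def bypass_effect(compound_id: str, magnitude: float = 1.0) -> CompoundEffect:
    """A sulfate-formulated compound: relieves sulfur limitation everywhere."""
    return CompoundEffect(compound_id, "sulfate_bypass", magnitude)


def toxic_effect(compound_id: str, magnitude: float = -0.5) -> CompoundEffect:
    return CompoundEffect(compound_id, "toxic", magnitude)


def colored_effect(compound_id: str, offset: float = 0.3) -> CompoundEffect:
    """A colored solution: constant absorbance offset, no growth change."""
    return CompoundEffect(compound_id, "colored", offset)


@dataclass(frozen=True)
class SimulationConfig:
    """Screen-simulation parameters (defaults mirror the assay design:
    7 reads over 0-24 h, 4 vehicle wells/plate, 80 compounds/plate, a
    1280-compound library, single experimental well per compound)."""

    seed: int = 0
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    noise_sd: float = 0.01
    n_control_wells: int = 4
    compounds_per_plate: int = 80
    library_size: int = 1280

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_control_wells < 2:
            raise ValidationError("need at least 2 control wells")
        if list(self.timepoints_h) != sorted(self.timepoints_h):
            raise ValidationError("timepoints must be sorted ascending")
        if self.library_size < 1 or self.compounds_per_plate < 1:
            raise ValidationError("library_size and compounds_per_plate must be >= 1")

    @property
    def n_plates(self) -> int:
        return ceil(self.library_size / self.compounds_per_plate)


@dataclass
class ScreenDataset:
    """One simulated screen: measurements + annotations + library + truth."""

    measurements: MeasurementTable
    annotations: pd.DataFrame
    library: pd.DataFrame
    truth: pd.DataFrame


def growth_curve(
    kinetics: StrainKinetics,
    effect: CompoundEffect | None,
    times: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one well's OD series under ``kinetics`` and an optional effect.

    Noise is additive Gaussian (sd ``noise_sd``), truncated at zero.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValidationError("times must be sorted ascending")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    cap_scale = 1.0
    offset = 0.0
    if effect is not None and effect.applies_to(kinetics.strain, kinetics.medium):
        if effect.effect_class in ("suppressor", "sulfate_bypass", "toxic"):
            cap_scale = 1.0 + effect.magnitude
        elif effect.effect_class == "colored":
            offset = effect.magnitude
    od = kinetics.noiseless(t, cap_scale=cap_scale) + offset
    if noise_sd > 0:
        if rng is None:
            raise ValidationError("noisy simulation needs an explicit rng")
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return np.clip(od, 0.0, None)


def planted_effects(
    config: SimulationConfig,
    rng: np.random.Generator,
    suppressor_fraction: float = 0.02,
    suppressor_magnitude: float = 0.15,
    n_bypass: int = 16,
    n_colored: int = 4,
    n_toxic: int = 10,
) -> list[CompoundEffect]:
    """Random placement of planted effect classes across the library.

    Defaults mirror the study conditions: ~2% true suppressors at +15%
    capacity, 16 sulfate-formulated bypass compounds, 4 colored solutions.
    """
    ids = [_compound_id(i) for i in range(config.library_size)]
    n_supp = round(suppressor_fraction * config.library_size)
    n_special = n_supp + n_bypass + n_colored + n_toxic
    if n_special > config.library_size:
        raise ValidationError("more planted effects than library compounds")
    chosen = rng.choice(config.library_size, size=n_special, replace=False)
    effects: list[CompoundEffect] = []
    k = 0
    for _ in range(n_supp):
        effects.append(suppressor_effect(ids[chosen[k]], suppressor_magnitude))
        k += 1
    for _ in range(n_bypass):
        effects.append(bypass_effect(ids[chosen[k]]))
        k += 1
    for _ in range(n_colored):
        effects.append(colored_effect(ids[chosen[k]]))
        k += 1
    for _ in range(n_toxic):
        effects.append(toxic_effect(ids[chosen[k]]))
        k += 1
    return effects


def _compound_id(index: int) -> str:
    return f"C{index + 1:04d}"


def simulate_screen(
    config: SimulationConfig,
    effects: Iterable[CompoundEffect] = (),
    kinetics: StrainKinetics | None = None,
) -> ScreenDataset:
    """Simulate the single-well suppression screen (sdh1 in ISE).

    Each plate holds ``compounds_per_plate`` experimental wells (one well
    per compound, filling columns 1 up), plus ``n_control_wells`` vehicle
    wells in the last column.  Sulfate-formulated compounds carry
    ``contains_sulfate=True`` in the returned library; colored ones carry
    ``colored_solution=True``.
    """
    kin = kinetics or DEFAULT_KINETICS[(SCREEN_STRAIN, SCREEN_MEDIUM)]
    # control wells occupy the trailing column(s); compounds may not spill there
    control_columns = ceil(config.n_control_wells / len(ROW_LETTERS))
    per_plate_capacity = len(ROW_LETTERS) * (12 - control_columns)
    if config.compounds_per_plate > per_plate_capacity:
        needed = ceil(config.library_size / per_plate_capacity)
        raise ValidationError(
            f"plate capacity exceeded: at most {per_plate_capacity} compounds/plate "
            f"with {config.n_control_wells} controls; need >= {needed} plates"
        )
    effect_map = {e.compound_id: e for e in effects}
    unknown = set(effect_map) - {_compound_id(i) for i in range(config.library_size)}
    if unknown:
        raise ValidationError(f"effects reference unknown compound(s): {sorted(unknown)[:5]}")

    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.timepoints_h, dtype=float)

    records: list[dict] = []
    annotations: list[WellAnnotation] = []
    for idx in range(config.library_size):
        cid = _compound_id(idx)
        plate = idx // config.compounds_per_plate
        slot = idx % config.compounds_per_plate
        addr = WellAddress(
            plate_id=f"P{plate + 1:02d}",
            row=ROW_LETTERS[slot % len(ROW_LETTERS)],
            column=slot // len(ROW_LETTERS) + 1,
        )
        annotations.append(
            WellAnnotation(addr, SCREEN_STRAIN, SCREEN_MEDIUM, cid, 10.0, "experimental")
        )
        od = growth_curve(kin, effect_map.get(cid), times, config.noise_sd, rng)
        records.extend(
            {"plate_id": addr.plate_id, "well": addr.well, "time_h": t, "od600": o}
            for t, o in zip(times, od)
        )
    for plate in range(config.n_plates):
        for c in range(config.n_control_wells):
            addr = WellAddress(
                plate_id=f"P{plate + 1:02d}",
                row=ROW_LETTERS[c % len(ROW_LETTERS)],
                column=12 - c // len(ROW_LETTERS),
            )
            annotations.append(
                WellAnnotation(addr, SCREEN_STRAIN, SCREEN_MEDIUM, None, 0.0, "negative_control")
            )
            od = growth_curve(kin, None, times, config.noise_sd, rng)
            records.extend(
                {"plate_id": addr.plate_id, "well": addr.well, "time_h": t, "od600": o}
                for t, o in zip(times, od)
            )

    library = library_frame(
        CompoundRecord(
            compound_id=_compound_id(i),
            name=f"compound-{i + 1:04d}",
            contains_sulfate=(
                effect_map.get(_compound_id(i)) is not None
                and effect_map[_compound_id(i)].effect_class == "sulfate_bypass"
            ),
            colored_solution=(
                effect_map.get(_compound_id(i)) is not None
                and effect_map[_compound_id(i)].effect_class == "colored"
            ),
            stock_mM=10.0,
        )
        for i in range(config.library_size)
    )
    truth = pd.DataFrame(
        {
            "compound_id": [_compound_id(i) for i in range(config.library_size)],
            "effect_class": [
                effect_map[_compound_id(i)].effect_class
                if _compound_id(i) in effect_map
                else "inert"
                for i in range(config.library_size)
            ],
            "magnitude": [
                effect_map[_compound_id(i)].magnitude
                if _compound_id(i) in effect_map
                else 0.0
                for i in range(config.library_size)
            ],
        }
    )
    measurements = MeasurementTable(pd.DataFrame(records, columns=list(MEASUREMENT_COLUMNS)))
    return ScreenDataset(measurements, annotations_frame(annotations), library, truth)


def simulate_validation(
    effect: CompoundEffect,
    n_reps: int = 4,
    concentration_um: float = 25.0,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
    noise_sd: float = 0.01,
    seed: int = 0,
    kinetics: dict[tuple[str, str], StrainKinetics] | None = None,
) -> ScreenDataset:
    """Simulate the dose-validation assay: 4 strains x 2 media, treated vs
    untreated wells with ``n_reps`` technical replicates each (one plate per
    medium)."""
    if n_reps < 2:
        raise ValidationError("validation needs >= 2 replicates per condition")
    kin_table = kinetics or DEFAULT_KINETICS
    rng = np.random.default_rng(seed)
    times = np.asarray(timepoints_h, dtype=float)
    records: list[dict] = []
    annotations: list[WellAnnotation] = []
    for medium in MEDIA:
        plate_id = f"V-{medium}"
        slot = 0
        for strain in STRAINS:
            for treated in (True, False):
                for _rep in range(n_reps):
                    addr = WellAddress(
                        plate_id, ROW_LETTERS[slot // 12], slot % 12 + 1
                    )
                    slot += 1
                    annotations.append(
                        WellAnnotation(
                            addr,
                            strain,
                            medium,
                            effect.compound_id if treated else None,
                            concentration_um if treated else 0.0,
                            "experimental" if treated else "untreated_reference",
                        )
                    )
                    od = growth_curve(
                        kin_table[(strain, medium)],
                        effect if treated else None,
                        times,
                        noise_sd,
                        rng,
                    )
                    records.extend(
                        {
                            "plate_id": addr.plate_id,
                            "well": addr.well,
                            "time_h": t,
                            "od600": o,
                        }
                        for t, o in zip(times, od)
                    )
    library = library_frame(
        [
            CompoundRecord(
                effect.compound_id,
                effect.compound_id,
                contains_sulfate=effect.effect_class == "sulfate_bypass",
                colored_solution=effect.effect_class == "colored",
            )
        ]
    )
    truth = pd.DataFrame(
        {
            "compound_id": [effect.compound_id],
            "effect_class": [effect.effect_class],
            "magnitude": [effect.magnitude],
        }
    )
    measurements = MeasurementTable(pd.DataFrame(records, columns=list(MEASUREMENT_COLUMNS)))
    return ScreenDataset(measurements, annotations_frame(annotations), library, truth)


def simulate_abundance(
    n_proteins: int = 6000,
    n_replicates: int = 3,
    de_shared: int = 991,
    de_a_only: int = 24,
    de_b_only: int = 77,
    lfc_mean: float = 2.5,
    lfc_sd: float = 0.0,
    down_in_mutant_fraction: float = 0.9,
    absent_fraction: float = 0.01,
    noise_sd: float = 0.25,
    seed: int = 0,
    groups: tuple[str, str, str] = ("WT", "sdh1", "sdh2"),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a proteins x samples abundance matrix with planted truth.

    Comparison A is group[1] vs WT, comparison B group[2] vs WT.  The
    default differential partition (991 shared / 24 A-only / 77 B-only)
    mirrors a proteome where SDH loss remodels ~1100 proteins, ~91% of them
    shared between the two mutants.  Log2 abundances are Gaussian around a
    protein base level; differential proteins are shifted by a signed true
    log2 fold-change of magnitude ``lfc_mean`` (+- ``lfc_sd``), most of them
    down in the mutant (more abundant in WT).  A small fraction of the
    down-in-mutant proteins are rendered fully absent (all-zero) in the
    mutant group to exercise the zero-flooring rule downstream.

    Returns ``(matrix, sample_groups, truth)``.
    """
    if n_replicates < 2:
        raise ValidationError("need >= 2 replicates per group (variance undefined)")
    n_de = de_shared + de_a_only + de_b_only
    if n_de > n_proteins:
        raise ValidationError("differential counts exceed n_proteins")
    if not 0 <= down_in_mutant_fraction <= 1:
        raise ValidationError("down_in_mutant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = [f"prot{i + 1:05d}" for i in range(n_proteins)]
    reference, group_a, group_b = groups
    samples = [f"{g}_{r + 1}" for g in groups for r in range(n_replicates)]
    sample_groups = pd.Series(
        [g for g in groups for _ in range(n_replicates)], index=samples, name="group"
    )

    base = rng.normal(10.0, 2.0, size=n_proteins)
    membership = np.array(
        ["shared"] * de_shared
        + ["a_only"] * de_a_only
        + ["b_only"] * de_b_only
        + ["none"] * (n_proteins - n_de)
    )
    rng.shuffle(membership)

    # Signed true log2FC (mutant minus WT); deterministic directional counts
    # so the planted up/down split is exact under noiseless recovery.
    magnitude = np.abs(lfc_mean + lfc_sd * rng.normal(size=n_proteins))
    sign = np.zeros(n_proteins)
    de_idx = np.flatnonzero(membership != "none")
    n_down = round(down_in_mutant_fraction * len(de_idx))
    signs = np.array([-1.0] * n_down + [1.0] * (len(de_idx) - n_down))
    rng.shuffle(signs)
    sign[de_idx] = signs

    lfc_a = np.where(np.isin(membership, ("shared", "a_only")), sign * magnitude, 0.0)
    lfc_b = np.where(np.isin(membership, ("shared", "b_only")), sign * magnitude, 0.0)

    def _group_log2(shift: np.ndarray) -> np.ndarray:
        mean = base[:, None] + shift[:, None]
        return mean + rng.normal(0.0, noise_sd, size=(n_proteins, n_replicates))

    log2_ref = _group_log2(np.zeros(n_proteins))
    log2_a = _group_log2(lfc_a)
    log2_b = _group_log2(lfc_b)
    matrix = pd.DataFrame(
        np.concatenate(
            [2.0 ** log2_ref, 2.0 ** log2_a, 2.0 ** log2_b], axis=1
        ),
        index=proteins,
        columns=samples,
    )

    # Fully absent proteins: all-zero in the group where they are depleted.
    absent = np.full(n_proteins, "", dtype=object)
    down_idx = np.flatnonzero(sign < 0)
    n_absent = round(absent_fraction * len(down_idx))
    if n_absent:
        absent_idx = rng.choice(down_idx, size=n_absent, replace=False)
        for i in absent_idx:
            if membership[i] in ("shared", "a_only"):
                matrix.iloc[i, n_replicates : 2 * n_replicates] = 0.0
                absent[i] = group_a
            if membership[i] in ("shared", "b_only"):
                matrix.iloc[i, 2 * n_replicates :] = 0.0
                absent[i] = group_b if absent[i] == "" else "both_mutants"

    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "differential": membership != "none",
            "comparison": membership,
            "true_log2fc_a": lfc_a,
            "true_log2fc_b": lfc_b,
            "absent_in": absent,
        }
    ).set_index("protein_id")
    return matrix, sample_groups, truth


DEFAULT_METABOLITES = ("succinate", "2-ketoglutarate", "pyruvate", "choline")


def simulate_metabolites(
    strains: Sequence[str] = ("WT", "sdh1", "sdh2"),
    treatments: Sequence[str] = ("untreated", "DMAE"),
    n_reps: int = 3,
    succinate_fold: float = 5.0,
    kg_fold: float = 0.5,
    treatment_effect: float = 0.4,
    cv: float = 0.10,
    wt_succinate_um: float = 150.0,
    wt_kg_um: float = 120.0,
    metabolites: Sequence[str] = DEFAULT_METABOLITES,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format metabolite concentration table with truth.

    SDH-loss strains carry ``succinate_fold``-times the WT succinate and
    ``kg_fold``-times the WT 2-ketoglutarate.  The treatment (DMAE) lowers
    succinate by fraction ``treatment_effect`` in the mutants only; WT is
    unaffected by treatment in truth.  Replicate concentrations are Gaussian
    around the strain x treatment mean with coefficient of variation ``cv``.
    Choline is profiled in relative units (no absolute calibration) and is
    strongly raised by DMAE in every strain, mimicking a precursor feed.
    """
    if n_reps < 2:
        raise ValidationError("need n_reps >= 2")
    if succinate_fold <= 0 or kg_fold <= 0:
        raise ValidationError("fold parameters must be > 0")
    if not 0 <= treatment_effect < 1:
        raise ValidationError("treatment_effect must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def true_mean(strain: str, treatment: str, metabolite: str) -> float:
        mutant = strain != "WT"
        if metabolite == "succinate":
            level = wt_succinate_um * (succinate_fold if mutant else 1.0)
            if mutant and treatment == "DMAE":
                level *= 1.0 - treatment_effect
            return level
        if metabolite == "2-ketoglutarate":
            return wt_kg_um * (kg_fold if mutant else 1.0)
        if metabolite == "choline":
            return 1.0 * (8.5 if treatment == "DMAE" else 1.0)
        return 80.0  # inert filler metabolite (e.g. pyruvate-like)

    rows = []
    truth_rows = []
    for strain in strains:
        for treatment in treatments:
            for metabolite in metabolites:
                mean = true_mean(strain, treatment, metabolite)
                truth_rows.append(
                    {
                        "strain": strain,
                        "treatment": treatment,
                        "metabolite": metabolite,
                        "true_mean_um": mean,
                    }
                )
            for rep in range(1, n_reps + 1):
                sample_id = f"{strain}_{treatment}_{rep}"
                for metabolite in metabolites:
                    mean = true_mean(strain, treatment, metabolite)
                    conc = mean * (1.0 + cv * rng.standard_normal()) if cv > 0 else mean
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "strain": strain,
                            "treatment": treatment,
                            "replicate": rep,
                            "metabolite": metabolite,
                            "concentration_um": max(conc, 0.0),
                            "quantitation": "relative"
                            if metabolite == "choline"
                            else "absolute",
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
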