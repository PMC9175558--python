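"""Pipeline driver: configuration, stage execution, and report assembly.

Stages (``simulate -> score -> hits -> validate -> omics -> metabolites``)
run in order; each writes its CSV report(s) under ``out_dir`` and a run log
plus the resolved configuration are always written alongside.  All
randomness derives from the single ``seed`` through per-stage
:class:`numpy.random.SeedSequence` children, so a re-run with the same
configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth_metrics import classify_selectivity, validation_effects
from .metabolite_analysis import strain_fold, succ_kg_ratio, treatment_test
from .omics_diff import differential, fc_correlation, venn
from .plate_model import (
    join_annotations,
    read_annotations,
    read_library,
    read_measurements,
)
from .screen_scoring import call_hits, rank_hits, score_all
from .stats_core import tukey_frame
from .synthetic_data import (
    SimulationConfig,
    bypass_effect,
    planted_effects,
    simulate_abundance,
    simulate_metabolites,
    simulate_screen,
    simulate_validation,
    suppressor_effect,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "hits", "validate", "omics", "metabolites")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is embedded in the message."""


@dataclass
class PipelineConfig:
    """Resolved run configuration (round-trips losslessly through YAML)."""

    seed: int = 0
    out_dir: str = "results"
    simulate: bool = True
    measurements_path: str | None = None
    annotations_path: str | None = None
    library_path: str | None = None
    # screen scoring
    min_positive: int = 6
    n_timepoints: int = 7
    alpha: float = 0.05
    # omics thresholds
    adjusted_p: float = 0.05
    abs_log2fc: float = 1.5
    # simulator: screen
    library_size: int = 1280
    compounds_per_plate: int = 80
    n_control_wells: int = 4
    noise_sd: float = 0.01
    suppressor_fraction: float = 0.02
    suppressor_magnitude: float = 0.15
    n_bypass: int = 16
    n_colored: int = 4
    n_toxic: int = 10
    # simulator: proteome
    n_proteins: int = 6000
    de_shared: int = 991
    de_a_only: int = 24
    de_b_only: int = 77
    protein_noise_sd: float = 0.25
    lfc_mean: float = 2.5
    # simulator: metabolites
    succinate_fold: float = 5.0
    kg_fold: float = 0.5
    treatment_effect: float = 0.4
    metabolite_cv: float = 0.10
    metabolite_reps: int = 3

    def __post_init__(self) -> None:
        for name in ("alpha", "adjusted_p", "abs_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage_seed(seed: int, stage: str) -> int:
    # stable child seed per stage, independent of which stages run
    idx = STAGES.index(stage)
    state = np.random.SeedSequence((int(seed), idx)).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(_stage_seed(seed, stage))


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] | None = None
) -> dict:
    """Execute the requested stages and write their reports.

    Returns a dict of in-memory stage outputs.  Only explicitly requested
    stages write reports, but upstream data dependencies (simulated or read
    from the configured paths, scored series for hit calling) are computed
    as needed.
    """
    requested = tuple(stages) if stages is not None else STAGES
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("suppscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    state: dict = {}
    try:
        logger.info(
            "suppscreen %s (numpy %s, pandas %s) seed=%d stages=%s",
            __version__,
            np.__version__,
            pd.__version__,
            config.seed,
            ",".join(requested),
        )
        config.to_yaml(out / "config.yaml")
        logger.info("resolved config written to %s", out / "config.yaml")
        for stage in STAGES:
            if stage not in requested:
                continue
            try:
                _STAGE_FUNCS[stage](config, state, out)
                logger.info("stage %s complete", stage)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return state


def _ensure_screen_data(config: PipelineConfig, state: dict) -> None:
    if "screen" in state:
        return
    if config.simulate:
        sim_cfg = SimulationConfig(
            seed=_stage_seed(config.seed, "simulate"),
            noise_sd=config.noise_sd,
            n_control_wells=config.n_control_wells,
            compounds_per_plate=config.compounds_per_plate,
            library_size=config.library_size,
        )
        effects = planted_effects(
            sim_cfg,
            _stage_rng(config.seed, "simulate"),
            suppressor_fraction=config.suppressor_fraction,
            suppressor_magnitude=config.suppressor_magnitude,
            n_bypass=config.n_bypass,
            n_colored=config.n_colored,
            n_toxic=config.n_toxic,
        )
        state["screen"] = simulate_screen(sim_cfg, effects)
    else:
        for name in ("measurements_path", "annotations_path", "library_path"):
            path = getattr(config, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"{name} not found: {path}")
        from .synthetic_data import ScreenDataset

        state["screen"] = ScreenDataset(
            measurements=read_measurements(config.measurements_path),
            annotations=read_annotations(config.annotations_path),
            library=read_library(config.library_path),
            truth=pd.DataFrame(columns=["compound_id", "effect_class", "magnitude"]),
        )


def _stage_simulate(config: PipelineConfig, state: dict, out: Path) -> None:
    _ensure_screen_data(config, state)
    ds = state["screen"]
    ds.measurements.write_csv(out / "measurements.csv")
    ds.annotations.to_csv(out / "annotations.csv", index=False)
    ds.library.to_csv(out / "library.csv", index=False)
    ds.truth.to_csv(out / "truth_compounds.csv", index=False)


def _ensure_scores(config: PipelineConfig, state: dict) -> None:
    if "series" in state:
        return
    _ensure_screen_data(config, state)
    ds = state["screen"]
    joined = join_annotations(ds.measurements, ds.annotations, ds.library)
    state["joined"] = joined
    state["series"] = score_all(joined)


def _stage_score(config: PipelineConfig, state: dict, out: Path) -> None:
    _ensure_scores(config, state)
    rows = [
        {
            "compound_id": s.compound_id,
            "time_h": s.time_h,
            "mu_p": s.mu_p,
            "sigma_p": s.sigma_p,
            "mu_n": s.mu_n,
            "sigma_n": s.sigma_n,
            "z": s.z,
        }
        for series in state["series"].values()
        for s in series
    ]
    pd.DataFrame(rows).to_csv(out / "zscores.csv", index=False)


def _stage_hits(config: PipelineConfig, state: dict, out: Path) -> None:
    _ensure_scores(config, state)
    calls = call_hits(
        state["series"],
        state["screen"].library,
        min_positive=config.min_positive,
        n_timepoints=config.n_timepoints,
    )
    state["calls"] = calls
    report = rank_hits(calls, state["series"], state["screen"].library)
    state["hit_report"] = report
    report.to_csv(out / "hits.csv", index=False)


def _stage_validate(config: PipelineConfig, state: dict, out: Path) -> None:
    seed = _stage_seed(config.seed, "validate")
    verdicts = []
    cells_frames = []
    for effect in (
        suppressor_effect("validated-suppressor", config.suppressor_magnitude),
        bypass_effect("sulfate-bypass"),
    ):
        ds = simulate_validation(effect, noise_sd=config.noise_sd, seed=seed)
        joined = join_annotations(ds.measurements, ds.annotations, ds.library)
        cells = validation_effects(joined)
        verdict = classify_selectivity(cells, alpha=config.alpha)
        verdicts.append(
            {"compound_id": verdict.compound_id, "verdict": verdict.verdict}
        )
        cells_frames.append(cells.assign(compound_id=effect.compound_id))
    state["validation"] = pd.DataFrame(verdicts)
    pd.concat(cells_frames, ignore_index=True).to_csv(
        out / "validation_effects.csv", index=False
    )
    state["validation"].to_csv(out / "validation_verdicts.csv", index=False)


def _stage_omics(config: PipelineConfig, state: dict, out: Path) -> None:
    seed = _stage_seed(config.seed, "omics")
    matrix, groups, truth = simulate_abundance(
        n_proteins=config.n_proteins,
        de_shared=config.de_shared,
        de_a_only=config.de_a_only,
        de_b_only=config.de_b_only,
        noise_sd=config.protein_noise_sd,
        lfc_mean=config.lfc_mean,
        seed=seed,
    )
    diff_a = differential(
        matrix, groups, "sdh1", "WT",
        alpha=config.adjusted_p, lfc_threshold=config.abs_log2fc,
    )
    diff_b = differential(
        matrix, groups, "sdh2", "WT",
        alpha=config.adjusted_p, lfc_threshold=config.abs_log2fc,
    )
    part = venn(diff_a, diff_b)
    r, n, _table = fc_correlation(diff_a, diff_b)
    diff_a.to_csv(out / "omics_diff_sdh1.csv")
    diff_b.to_csv(out / "omics_diff_sdh2.csv")
    pd.DataFrame(
        [
            {
                "shared": part.shared,
                "unique_a": part.unique_a,
                "unique_b": part.unique_b,
                "union": part.union,
                "shared_percent": part.shared_percent,
                "fc_correlation_r": r,
                "n_proteins": n,
            }
        ]
    ).to_csv(out / "omics_venn.csv", index=False)
    state["omics"] = {"diff_a": diff_a, "diff_b": diff_b, "venn": part, "r": r,
                      "truth": truth}


def _stage_metabolites(config: PipelineConfig, state: dict, out: Path) -> None:
    seed = _stage_seed(config.seed, "metabolites")
    table, truth = simulate_metabolites(
        n_reps=config.metabolite_reps,
        succinate_fold=config.succinate_fold,
        kg_fold=config.kg_fold,
        treatment_effect=config.treatment_effect,
        cv=config.metabolite_cv,
        seed=seed,
    )
    ratios = succ_kg_ratio(table)
    folds = strain_fold(table, "succinate")
    anova, comparisons = treatment_test(table, "succinate")
    table.to_csv(out / "metabolites.csv", index=False)
    ratios.to_csv(out / "metabolite_ratios.csv", index=False)
    folds.to_csv(out / "succinate_folds.csv", index=False)
    anova.to_csv(out / "succinate_anova.csv")
    tukey_frame(comparisons).to_csv(out / "succinate_tukey.csv", index=False)
    state["metabolites"] = {
        "table": table,
        "truth": truth,
        "ratios": ratios,
        "folds": folds,
        "anova": anova,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "hits": _stage_hits,
    "validate": _stage_validate,
    "omics": _stage_omics,
    "metabolites": _stage_metabolites,
}
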