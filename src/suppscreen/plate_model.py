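"""Data model and CSV I/O for 96-well plate-reader growth screens.

The screen's primary data are long-format OD600 time series keyed by
(plate, well, time), a per-well annotation table (strain, medium, compound,
dose, role), and a compound-library table whose formulation flags
(``contains_sulfate``, ``colored_solution``) drive downstream hit exclusions.

Canonical on-disk layout is long-format CSV, one row per well per timepoint;
a wide plate-grid layout (time down the rows, wells across the columns) is
supported read-only.  Well coordinates follow plate-reader convention:
letter rows A-H, 1-based columns 1-12.  Time is stored in decimal hours;
readers accept minutes via a dialect flag.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ROW_LETTERS = "ABCDEFGH"
N_COLUMNS = 12

STRAINS = ("WT", "sdh1", "sdh2", "jlp1")
MEDIA = ("AS", "ISE")
ROLES = ("experimental", "negative_control", "untreated_reference", "blank")

MEASUREMENT_COLUMNS = ("plate_id", "well", "time_h", "od600")
ANNOTATION_COLUMNS = (
    "plate_id",
    "well",
    "strain",
    "medium",
    "compound_id",
    "concentration_um",
    "role",
)
LIBRARY_COLUMNS = (
    "compound_id",
    "name",
    "contains_sulfate",
    "colored_solution",
    "stock_mM",
)

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Parsed data violate a plate-model invariant."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well on a named 96-well plate (row letter A-H, column 1-12)."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise ValidationError(f"row {self.row!r} outside A-{ROW_LETTERS[-1]}")
        if not 1 <= self.column <= N_COLUMNS:
            raise ValidationError(f"column {self.column} outside 1-{N_COLUMNS}")

    @property
    def well(self) -> str:
        """Well label such as ``'A1'``."""
        return f"{self.row}{self.column}"

    @classmethod
    def from_label(cls, plate_id: str, label: str) -> "WellAddress":
        m = _WELL_RE.match(label.strip())
        if m is None:
            raise ValidationError(f"unparseable well label {label!r}")
        return cls(plate_id=plate_id, row=m.group(1).upper(), column=int(m.group(2)))


@dataclass(frozen=True)
class WellAnnotation:
    """Experimental annotation of one well.

    Invariants: a ``negative_control`` well carries vehicle only (no
    compound), and concentration is zero exactly when no compound is present.
    """

    address: WellAddress
    strain: str
    medium: str
    compound_id: str | None = None
    concentration_um: float = 0.0
    role: str = "experimental"

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValidationError(f"unknown strain {self.strain!r}")
        if self.medium not in MEDIA:
            raise ValidationError(f"unknown medium {self.medium!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.concentration_um < 0:
            raise ValidationError("concentration must be >= 0")
        if self.role == "negative_control" and self.compound_id is not None:
            raise ValidationError(
                f"negative control {self.address.well} must be vehicle-only"
            )
        if (self.concentration_um == 0) != (self.compound_id is None):
            raise ValidationError(
                f"well {self.address.well}: concentration must be 0 iff no compound"
            )

    def to_row(self) -> dict:
        return {
            "plate_id": self.address.plate_id,
            "well": self.address.well,
            "strain": self.strain,
            "medium": self.medium,
            "compound_id": self.compound_id,
            "concentration_um": self.concentration_um,
            "role": self.role,
        }


@dataclass(frozen=True)
class CompoundRecord:
    """A library entry; formulation flags drive screen exclusions."""

    compound_id: str
    name: str
    contains_sulfate: bool = False
    colored_solution: bool = False
    stock_mM: float = 10.0

    def __post_init__(self) -> None:
        if self.stock_mM <= 0:
            raise ValidationError("stock concentration must be > 0 mM")

    def to_row(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "name": self.name,
            "contains_sulfate": self.contains_sulfate,
            "colored_solution": self.colored_solution,
            "stock_mM": self.stock_mM,
        }


class MeasurementTable:
    """Long-format OD600 time series keyed by (plate, well, time).

    Wraps a :class:`pandas.DataFrame` with columns ``plate_id, well, time_h,
    od600``; rows are kept sorted by plate, well and time.  Duplicate
    (plate, well, time) keys and negative ODs are rejected on construction.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing measurement column(s): {', '.join(missing)}")
        frame = frame.loc[:, list(MEASUREMENT_COLUMNS)].copy()
        frame["plate_id"] = frame["plate_id"].astype(str)
        frame["well"] = frame["well"].astype(str).str.upper()
        frame["time_h"] = pd.to_numeric(frame["time_h"]).astype(float)
        frame["od600"] = pd.to_numeric(frame["od600"]).astype(float)
        self._validate(frame)
        self._frame = frame.sort_values(
            ["plate_id", "well", "time_h"], kind="mergesort"
        ).reset_index(drop=True)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        bad_well = frame.loc[~frame["well"].str.match(_WELL_RE), "well"].unique()
        if len(bad_well):
            raise ValidationError(f"unparseable well label(s): {sorted(bad_well)}")
        neg = frame[frame["od600"] < 0]
        if len(neg):
            where = [
                f"{r.plate_id}:{r.well}@{r.time_h}h" for r in neg.head(5).itertuples()
            ]
            raise ValidationError(f"negative OD600 at {', '.join(where)}")
        if frame["time_h"].lt(0).any():
            raise ValidationError("negative time values present")
        dup = frame.duplicated(subset=["plate_id", "well", "time_h"], keep=False)
        if dup.any():
            keys = (
                frame.loc[dup, ["plate_id", "well", "time_h"]]
                .drop_duplicates()
                .head(5)
            )
            where = [f"{r.plate_id}:{r.well}@{r.time_h}h" for r in keys.itertuples()]
            raise ValidationError(f"duplicate (well, time) measurement(s): {', '.join(where)}")

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format frame (treat as read-only)."""
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[WellAddress, float, float]]
    ) -> "MeasurementTable":
        rows = [
            {
                "plate_id": addr.plate_id,
                "well": addr.well,
                "time_h": float(t),
                "od600": float(od),
            }
            for addr, t, od in records
        ]
        return cls(pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)))

    def write_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)


def _parse_float(series: pd.Series) -> pd.Series:
    """Correctly rounded float parsing (Python's parser, NaN on failure)."""

    def convert(value):
        try:
            return float(value)
        except (TypeError, ValueError):
            return float("nan")

    return series.map(convert)


DEFAULT_DIALECT: dict = {
    "format": "long",  # or "wide": time down the rows, wells across columns
    "time_unit": "h",  # or "min"
    "plate_column": "plate_id",
    "well_column": "well",
    "time_column": "time_h",
    "od_column": "od600",
    "plate_id": None,  # required for wide format (one plate per file)
}


def read_measurements(path: str | Path, dialect: Mapping | None = None) -> MeasurementTable:
    """Read a measurement CSV into a validated :class:`MeasurementTable`.

    Malformed rows (unparseable time or OD) are dropped with a logged
    warning; structural problems (missing columns, duplicates, negative ODs)
    raise :class:`FormatError` / :class:`ValidationError`.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    raw = pd.read_csv(path, dtype=str, float_precision="round_trip")
    if d["format"] == "wide":
        frame = _wide_to_long(raw, d)
    else:
        rename = {
            d["plate_column"]: "plate_id",
            d["well_column"]: "well",
            d["time_column"]: "time_h",
            d["od_column"]: "od600",
        }
        missing = [src for src in rename if src not in raw.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)} in {path}")
        frame = raw.rename(columns=rename).loc[:, list(MEASUREMENT_COLUMNS)]
    if frame.empty:
        logger.warning("no data rows in %s", path)
        return MeasurementTable(pd.DataFrame(columns=list(MEASUREMENT_COLUMNS)))
    time = _parse_float(frame["time_h"])
    od = _parse_float(frame["od600"])
    bad = time.isna() | od.isna()
    if bad.any():
        logger.warning(
            "dropping %d malformed row(s) in %s (rows %s)",
            int(bad.sum()),
            path,
            list(frame.index[bad][:5]),
        )
        frame = frame[~bad].copy()
        time, od = time[~bad], od[~bad]
    frame = frame.assign(time_h=time, od600=od)
    if d["time_unit"] == "min":
        frame["time_h"] = frame["time_h"] / 60.0
    return MeasurementTable(frame)


def _wide_to_long(raw: pd.DataFrame, dialect: Mapping) -> pd.DataFrame:
    plate_id = dialect.get("plate_id")
    if plate_id is None:
        raise FormatError("wide-format measurements need dialect['plate_id']")
    if raw.shape[1] < 2:
        raise FormatError("wide format needs a time column plus well columns")
    time_col = raw.columns[0]
    well_cols = [c for c in raw.columns[1:]]
    bad = [c for c in well_cols if not _WELL_RE.match(str(c).strip())]
    if bad:
        raise FormatError(f"non-well column header(s) in wide file: {bad}")
    long = raw.melt(id_vars=[time_col], var_name="well", value_name="od600")
    long = long.rename(columns={time_col: "time_h"})
    long["plate_id"] = str(plate_id)
    return long.loc[:, list(MEASUREMENT_COLUMNS)]


def annotations_frame(annotations: Iterable[WellAnnotation]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [a.to_row() for a in annotations], columns=list(ANNOTATION_COLUMNS)
    )
    return validate_annotations(frame)


def validate_annotations(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing annotation column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(ANNOTATION_COLUMNS)].copy()
    frame["plate_id"] = frame["plate_id"].astype(str)
    frame["well"] = frame["well"].astype(str).str.upper()
    frame["concentration_um"] = pd.to_numeric(frame["concentration_um"])
    frame["compound_id"] = frame["compound_id"].where(frame["compound_id"].notna(), None)
    for col, allowed in (("strain", STRAINS), ("medium", MEDIA), ("role", ROLES)):
        bad = set(frame[col].unique()) - set(allowed)
        if bad:
            raise ValidationError(f"unknown {col} value(s): {sorted(bad)}")
    dup = frame.duplicated(subset=["plate_id", "well"], keep=False)
    if dup.any():
        keys = frame.loc[dup, ["plate_id", "well"]].drop_duplicates()
        raise ValidationError(
            "duplicate well annotation(s): "
            + ", ".join(f"{r.plate_id}:{r.well}" for r in keys.head(5).itertuples())
        )
    has_compound = frame["compound_id"].notna()
    bad_nc = (frame["role"] == "negative_control") & has_compound
    if bad_nc.any():
        raise ValidationError(
            "negative control well(s) with a compound: "
            + ", ".join(frame.loc[bad_nc, "well"].head(5))
        )
    bad_conc = (frame["concentration_um"] == 0) != ~has_compound
    if bad_conc.any():
        raise ValidationError(
            "concentration must be 0 iff compound_id is empty; offending well(s): "
            + ", ".join(frame.loc[bad_conc, "well"].head(5))
        )
    return frame


def read_annotations(path: str | Path) -> pd.DataFrame:
    return validate_annotations(pd.read_csv(path))


def write_annotations(frame: pd.DataFrame, path: str | Path) -> None:
    validate_annotations(frame).to_csv(path, index=False)


def library_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([r.to_row() for r in records], columns=list(LIBRARY_COLUMNS))
    return validate_library(frame)


def validate_library(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing library column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(LIBRARY_COLUMNS)].copy()
    if frame["compound_id"].duplicated().any():
        dups = frame.loc[frame["compound_id"].duplicated(), "compound_id"]
        raise ValidationError(f"duplicate compound id(s): {sorted(set(dups))[:5]}")
    for col in ("contains_sulfate", "colored_solution"):
        frame[col] = frame[col].astype(bool)
    frame["stock_mM"] = pd.to_numeric(frame["stock_mM"])
    if frame["stock_mM"].le(0).any():
        raise ValidationError("stock_mM must be > 0 for every compound")
    return frame


def read_library(path: str | Path) -> pd.DataFrame:
    return validate_library(pd.read_csv(path))


def write_library(frame: pd.DataFrame, path: str | Path) -> None:
    validate_library(frame).to_csv(path, index=False)


def join_annotations(
    measurements: MeasurementTable,
    annotations: pd.DataFrame,
    library: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join measurements with well annotations (and, optionally, the library).

    The join is lossless: exactly one output row per measurement record.
    Unannotated wells and compounds absent from the library are hard errors
    listing the offending addresses / ids.
    """
    ann = validate_annotations(annotations)
    merged = measurements.frame.merge(
        ann, on=["plate_id", "well"], how="left", validate="many_to_one"
    )
    unannotated = merged["strain"].isna()
    if unannotated.any():
        keys = (
            merged.loc[unannotated, ["plate_id", "well"]]
            .drop_duplicates()
            .head(10)
        )
        raise ValidationError(
            "unannotated well(s): "
            + ", ".join(f"{r.plate_id}:{r.well}" for r in keys.itertuples())
        )
    if library is not None:
        lib = validate_library(library)
        used = set(merged["compound_id"].dropna().unique())
        unknown = sorted(used - set(lib["compound_id"]))
        if unknown:
            raise ValidationError(f"compound id(s) missing from library: {unknown[:10]}")
        merged = merged.merge(lib, on="compound_id", how="left")
    if len(merged) != len(measurements):
        raise AssertionError("annotation join changed the record count")
    return merged


def subtract_blank(
    measurements: MeasurementTable, annotations: pd.DataFrame
) -> MeasurementTable:
    """Subtract each plate's designated blank-well series from all its wells.

    Background subtraction is off by default in the pipeline (the assay reads
    a uniform cell lawn against a media blank only when one is annotated);
    this helper implements the optional switch.  Results are clipped at 0.
    """
    ann = validate_annotations(annotations)
    blanks = ann[ann["role"] == "blank"]
    frame = measurements.frame.copy()
    for plate_id, group in blanks.groupby("plate_id"):
        well = group["well"].iloc[0]
        blank_series = frame[
            (frame["plate_id"] == plate_id) & (frame["well"] == well)
        ].set_index("time_h")["od600"]
        on_plate = frame["plate_id"] == plate_id
        frame.loc[on_plate, "od600"] = (
            frame.loc[on_plate, "od600"]
            - frame.loc[on_plate, "time_h"].map(blank_series).fillna(0.0)
        ).clip(lower=0.0)
    return MeasurementTable(frame)


def final_concentration_um(
    stock_mm: float,
    stock_volume_nl: float,
    culture_volume_ul: float,
    include_stock_volume: bool = True,
) -> float:
    """Final compound concentration (uM) after pinning stock into culture.

    E.g. 200 nL of 10 mM DMSO stock into 200 uL of culture gives ~10 uM.
    """
    if stock_mm <= 0 or stock_volume_nl <= 0 or culture_volume_ul <= 0:
        raise ValidationError("volumes and stock concentration must be positive")
    stock_ul = stock_volume_nl / 1000.0
    total_ul = culture_volume_ul + (stock_ul if include_stock_volume else 0.0)
    return stock_mm * 1000.0 * stock_ul / total_ul


def mixed_od(od_a: float, volume_a_ul: float, od_b: float, volume_b_ul: float) -> float:
    """OD600 of a mixture of two volumes (e.g. 1:1 culture + drug -> half OD)."""
    if volume_a_ul <= 0 or volume_b_ul <= 0:
        raise ValidationError("mixture volumes must be positive")
    if od_a < 0 or od_b < 0:
        raise ValidationError("OD values must be >= 0")
    return (od_a * volume_a_ul + od_b * volume_b_ul) / (volume_a_ul + volume_b_ul)
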