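"""Patient cohort data model for preoperative CR-POPF risk prediction.

A cohort is a list of patient records, each carrying the preoperative
clinicoradiological markers used to predict clinically relevant postoperative
pancreatic fistula (CR-POPF) after pancreaticoduodenectomy, a diagnosis
stratum (PDAC vs non-PDAC), and optionally the binary CR-POPF outcome label.

This module provides:

* :class:`MarkerDefinition` and the default 14-marker panel with its
  dichotomization cut-offs (e.g. MPD index at 0.3, BMI at 25 kg/m^2);
* :class:`PatientRecord` with validation of derived-marker consistency
  (BMI from height/weight, MPD index = MPD size / parenchymal thickness);
* the derived-marker formulas (BMI, MPD index, PNI, CONUT);
* cut-off discretization of records into binary profiles;
* stratification by preoperative diagnosis;
* CSV round-trip I/O and a YAML panel loader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "CohortError",
    "SchemaError",
    "MarkerDefinition",
    "PatientRecord",
    "DiscretizedProfile",
    "Cohort",
    "PDAC",
    "NON_PDAC",
    "default_panel",
    "compute_mpd_index",
    "compute_bmi",
    "compute_pni",
    "compute_conut",
    "marker_value",
    "discretize_record",
    "discretize_cohort",
    "stratify_by_diagnosis",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_panel",
]


class CohortError(ValueError):
    """Invalid patient data or marker configuration."""


class SchemaError(CohortError):
    """Malformed cohort file (unknown column, bad value, duplicate id)."""


PDAC = "PDAC"
NON_PDAC = "non-PDAC"
MALE = "male"
FEMALE = "female"

# Tolerances for cross-checking stored vs recomputed derived markers.  These
# are deliberately looser than float round-off so that hand-entered data
# rounded to clinical precision (BMI to 0.1, MPD index to 0.01) still passes.
_BMI_ATOL = 0.05
_MPD_INDEX_ATOL = 0.005


@dataclass(frozen=True)
class MarkerDefinition:
    """A candidate CR-POPF predictor and how it is dichotomized.

    Continuous markers carry a finite ``cutoff`` and map to bin 1 when the
    value is at or above it; binary markers (yes/no, male/female, PDAC/other)
    carry no cutoff and map to bin 1 when the condition is present.
    """

    name: str
    kind: str  # "continuous" | "binary"
    cutoff: Optional[float] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise CohortError(f"marker {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.cutoff is None or not math.isfinite(self.cutoff):
                raise CohortError(
                    f"continuous marker {self.name!r} requires a finite cutoff"
                )
        elif self.cutoff is not None:
            raise CohortError(f"binary marker {self.name!r} must not have a cutoff")


def default_panel() -> tuple[MarkerDefinition, ...]:
    """The 14 candidate preoperative markers with their published cut-offs.

    Albumin and parenchymal thickness have no published dichotomization
    cut-off; the package uses the standard hypoalbuminemia threshold
    (3.5 g/dL) and the cohort-typical parenchymal thickness (13 mm).
    """
    return (
        MarkerDefinition("age", "continuous", 65.0, "age in years"),
        MarkerDefinition("sex", "binary", None, "male sex"),
        MarkerDefinition("bmi", "continuous", 25.0, "body mass index, kg/m^2"),
        MarkerDefinition("vfa", "continuous", 100.0, "visceral fat area, cm^2"),
        MarkerDefinition("pni", "continuous", 45.0, "prognostic nutritional index"),
        MarkerDefinition("albumin", "continuous", 3.5, "serum albumin, g/dL"),
        MarkerDefinition(
            "parenchymal_thickness", "continuous", 13.0, "pancreatic parenchymal thickness, mm"
        ),
        MarkerDefinition("mpd_size", "continuous", 3.0, "main pancreatic duct size, mm"),
        MarkerDefinition(
            "mpd_index", "continuous", 0.3, "MPD size / parenchymal thickness"
        ),
        MarkerDefinition("diabetes", "binary", None, "diabetes mellitus"),
        MarkerDefinition("biliary_drainage", "binary", None, "preoperative biliary drainage"),
        MarkerDefinition("conut", "continuous", 3.0, "CONUT score (dichotomized at >=3)"),
        MarkerDefinition("sarcopenia", "binary", None, "sarcopenia on CT"),
        MarkerDefinition("diagnosis", "binary", None, "preoperative diagnosis of PDAC"),
    )


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v) or v <= 0:
            raise CohortError(f"{name} must be a positive finite number, got {v!r}")


def compute_mpd_index(mpd_size: float, parenchymal_thickness: float) -> float:
    """MPD index: main pancreatic duct size divided by parenchymal thickness.

    Both measurements are in millimetres; the ratio is dimensionless.  A low
    index indicates a non-dilated duct within thick (typically soft)
    parenchyma, the anatomy most prone to fistula.
    """
    _require_positive(mpd_size=mpd_size, parenchymal_thickness=parenchymal_thickness)
    return mpd_size / parenchymal_thickness


def compute_bmi(height: float, weight: float) -> float:
    """Body mass index from height (m) and weight (kg)."""
    _require_positive(height=height, weight=weight)
    return weight / height**2


def compute_pni(albumin: float, lymphocytes: float) -> float:
    """Onodera prognostic nutritional index.

    PNI = 10 x serum albumin (g/dL) + 0.005 x total lymphocyte count (/mm^3).
    """
    _require_positive(albumin=albumin, lymphocytes=lymphocytes)
    return 10.0 * albumin + 0.005 * lymphocytes


def compute_conut(albumin: float, lymphocytes: float, cholesterol: float) -> int:
    """Controlling nutritional status (CONUT) score, 0 (normal) to 12 (severe).

    Sum of three sub-scores: albumin (g/dL) >=3.5 -> 0, 3.0-3.49 -> 2,
    2.5-2.99 -> 4, <2.5 -> 6; lymphocytes (/mm^3) >=1600 -> 0, 1200-1599 -> 1,
    800-1199 -> 2, <800 -> 3; total cholesterol (mg/dL) >=180 -> 0,
    140-179 -> 1, 100-139 -> 2, <100 -> 3.
    """
    _require_positive(albumin=albumin, lymphocytes=lymphocytes, cholesterol=cholesterol)
    if albumin >= 3.5:
        a = 0
    elif albumin >= 3.0:
        a = 2
    elif albumin >= 2.5:
        a = 4
    else:
        a = 6
    if lymphocytes >= 1600:
        l = 0
    elif lymphocytes >= 1200:
        l = 1
    elif lymphocytes >= 800:
        l = 2
    else:
        l = 3
    if cholesterol >= 180:
        c = 0
    elif cholesterol >= 140:
        c = 1
    elif cholesterol >= 100:
        c = 2
    else:
        c = 3
    return a + l + c


@dataclass(frozen=True)
class PatientRecord:
    """One patient's preoperative markers, diagnosis stratum and outcome label.

    ``cr_popf`` is the binary outcome (ISGPS grade B/C fistula); it may be
    absent at prediction time.  ``vfa`` and ``sarcopenia`` are optional
    because CT body-composition measurements are not available in every
    cohort.  Stored derived markers are validated against their defining
    formulas when the raw inputs are present.
    """

    id: str
    diagnosis: str  # PDAC | non-PDAC
    age: Optional[float] = None
    sex: Optional[str] = None  # male | female
    height: Optional[float] = None  # m
    weight: Optional[float] = None  # kg
    bmi: Optional[float] = None  # kg/m^2
    vfa: Optional[float] = None  # cm^2
    albumin: Optional[float] = None  # g/dL
    lymphocytes: Optional[float] = None  # /mm^3
    pni: Optional[float] = None
    parenchymal_thickness: Optional[float] = None  # mm
    mpd_size: Optional[float] = None  # mm
    mpd_index: Optional[float] = None
    diabetes: Optional[bool] = None
    biliary_drainage: Optional[bool] = None
    conut: Optional[int] = None
    sarcopenia: Optional[bool] = None
    cr_popf: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.diagnosis not in (PDAC, NON_PDAC):
            raise CohortError(
                f"record {self.id!r}: diagnosis must be {PDAC!r} or {NON_PDAC!r}, "
                f"got {self.diagnosis!r}"
            )
        if self.sex is not None and self.sex not in (MALE, FEMALE):
            raise CohortError(f"record {self.id!r}: sex must be male/female")
        for name in (
            "age",
            "height",
            "weight",
            "bmi",
            "vfa",
            "albumin",
            "lymphocytes",
            "pni",
            "parenchymal_thickness",
            "mpd_size",
            "mpd_index",
        ):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise CohortError(
                    f"record {self.id!r}: {name} must be positive, got {v!r}"
                )
        if self.conut is not None and self.conut < 0:
            raise CohortError(f"record {self.id!r}: conut must be non-negative")
        if self.bmi is not None and self.height is not None and self.weight is not None:
            if abs(self.bmi - compute_bmi(self.height, self.weight)) > _BMI_ATOL:
                raise CohortError(
                    f"record {self.id!r}: bmi {self.bmi} inconsistent with "
                    f"height/weight (expected {compute_bmi(self.height, self.weight):.2f})"
                )
        if (
            self.mpd_index is not None
            and self.mpd_size is not None
            and self.parenchymal_thickness is not None
        ):
            expected = compute_mpd_index(self.mpd_size, self.parenchymal_thickness)
            if abs(self.mpd_index - expected) > _MPD_INDEX_ATOL:
                raise CohortError(
                    f"record {self.id!r}: mpd_index {self.mpd_index} inconsistent "
                    f"with mpd_size/parenchymal_thickness (expected {expected:.4f})"
                )


@dataclass(frozen=True)
class DiscretizedProfile:
    """A record reduced to binary bins over an ordered marker list.

    Bin 1 means at-or-above the cutoff, or condition present (male sex,
    PDAC diagnosis, yes); bin 0 means below the cutoff or absent.
    """

    marker_names: tuple[str, ...]
    bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.marker_names) != len(self.bins):
            raise CohortError("marker_names and bins must have equal length")
        if any(b not in (0, 1) for b in self.bins):
            raise CohortError("bins must be 0 or 1")


@dataclass(frozen=True)
class Cohort:
    """Patient records plus the marker panel used to interpret them."""

    records: tuple[PatientRecord, ...]
    panel: tuple[MarkerDefinition, ...] = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "panel", tuple(self.panel))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate record id(s): {', '.join(dupes)}")
        names = [m.name for m in self.panel]
        if len(set(names)) != len(names):
            raise CohortError("duplicate marker names in panel")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> list[bool]:
        out = []
        for r in self.records:
            if r.cr_popf is None:
                raise CohortError(f"record {r.id!r} has no CR-POPF label")
            out.append(r.cr_popf)
        return out


def marker_value(record: PatientRecord, name: str) -> Optional[float]:
    """Numeric value of a panel marker for one record (binary -> 0/1)."""
    if name == "sex":
        return None if record.sex is None else float(record.sex == MALE)
    if name == "diagnosis":
        return float(record.diagnosis == PDAC)
    if name in ("diabetes", "biliary_drainage", "sarcopenia"):
        v = getattr(record, name)
        return None if v is None else float(v)
    if not hasattr(record, name):
        raise CohortError(f"unknown marker {name!r}")
    v = getattr(record, name)
    return None if v is None else float(v)


def discretize_record(
    record: PatientRecord, panel: Sequence[MarkerDefinition]
) -> DiscretizedProfile:
    """Dichotomize a record over a marker panel.

    Continuous markers map to 1 iff value >= cutoff (a value exactly at the
    cutoff goes to the upper bin); binary markers map to 1 iff present.
    """
    bins = []
    for m in panel:
        v = marker_value(record, m.name)
        if v is None:
            raise CohortError(f"record {record.id!r}: missing value for marker {m.name!r}")
        if m.kind == "continuous":
            bins.append(int(v >= m.cutoff))
        else:
            bins.append(int(v != 0))
    return DiscretizedProfile(tuple(m.name for m in panel), tuple(bins))


def discretize_cohort(
    cohort: Cohort, marker_names: Optional[Sequence[str]] = None
) -> list[DiscretizedProfile]:
    """Discretize every record over (a subset of) the cohort's panel."""
    by_name = {m.name: m for m in cohort.panel}
    if marker_names is None:
        panel = cohort.panel
    else:
        try:
            panel = tuple(by_name[n] for n in marker_names)
        except KeyError as e:
            raise CohortError(f"marker {e.args[0]!r} not in panel") from None
    return [discretize_record(r, panel) for r in cohort.records]


def stratify_by_diagnosis(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition a cohort into its PDAC and non-PDAC strata."""
    pdac = [r for r in cohort.records if r.diagnosis == PDAC]
    non = [r for r in cohort.records if r.diagnosis == NON_PDAC]
    return Cohort(tuple(pdac), cohort.panel), Cohort(tuple(non), cohort.panel)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FLOAT_COLUMNS = (
    "age",
    "height",
    "weight",
    "bmi",
    "vfa",
    "albumin",
    "lymphocytes",
    "pni",
    "parenchymal_thickness",
    "mpd_size",
    "mpd_index",
)
_BOOL_COLUMNS = ("diabetes", "biliary_drainage", "sarcopenia", "cr_popf")
_COLUMNS = (
    ("id", "diagnosis", "sex")
    + _FLOAT_COLUMNS
    + _BOOL_COLUMNS[:3]
    + ("conut",)
    + _BOOL_COLUMNS[3:]
)
# vfa / sarcopenia may be wholly absent from a file (not every cohort has CT
# body-composition measurements); cr_popf is absent for unlabeled cohorts.
_OPTIONAL_COLUMNS = {"vfa", "sarcopenia", "cr_popf"}


def _parse_cell(column: str, raw: object, row: int):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    s = str(raw).strip()
    if s == "":
        return None
    try:
        if column in _FLOAT_COLUMNS:
            return float(s)
        if column in _BOOL_COLUMNS:
            if s not in ("0", "1"):
                raise ValueError("expected 0 or 1")
            return s == "1"
        if column == "conut":
            return int(float(s))
        return s
    except ValueError as e:
        raise SchemaError(f"row {row}: column {column!r}: unparseable value {s!r} ({e})")


def read_cohort_csv(
    path: str | Path, panel: Optional[Sequence[MarkerDefinition]] = None
) -> Cohort:
    """Read a cohort from CSV (one row per patient, header required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in _COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")
    missing = [
        c for c in _COLUMNS if c not in df.columns and c not in _OPTIONAL_COLUMNS
    ]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        data = {
            c: _parse_cell(c, getattr(row, c), i) for c in df.columns
        }
        rid = data.get("id")
        if rid is None:
            raise SchemaError(f"row {i}: missing id")
        if rid in seen:
            raise SchemaError(f"row {i}: duplicate id {rid!r}")
        seen.add(rid)
        try:
            records.append(PatientRecord(**data))
        except CohortError as e:
            raise SchemaError(f"row {i}: {e}") from e
    return Cohort(tuple(records), tuple(panel) if panel is not None else default_panel())


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV; booleans as 0/1, missing values as empty cells."""
    rows = []
    for r in cohort.records:
        row = {}
        for c in _COLUMNS:
            v = getattr(r, c)
            if v is None:
                row[c] = ""
            elif c in _BOOL_COLUMNS:
                row[c] = int(v)
            else:
                row[c] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_COLUMNS))
    df.to_csv(path, index=False)


def load_panel(path: str | Path) -> tuple[MarkerDefinition, ...]:
    """Load a marker panel from a YAML/JSON file (list of name/kind/cutoff)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SchemaError("panel file must contain a list of marker definitions")
    markers = []
    for entry in raw:
        try:
            markers.append(
                MarkerDefinition(
                    name=entry["name"],
                    kind=entry["kind"],
                    cutoff=entry.get("cutoff"),
                    description=entry.get("description", ""),
                )
            )
        except (KeyError, TypeError) as e:
            raise SchemaError(f"malformed panel entry {entry!r}: {e}") from e
    return tuple(markers)
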