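"""Patient records, categorical encodings, outcome labeling and cohort CSV I/O.

The screening classifier operates on six categorical predictors: sex, age band,
increased neck circumference, craniofacial abnormalities, witnessed apneas and
nocturia.  This module defines the raw per-subject record (continuous age and
neck circumference, plus descriptive covariates), the deterministic mapping
onto the classifier's categorical levels, and the apnea–hypopnea-index (AHI)
outcome rule.  Missing values are represented explicitly (``None``) end to end;
nothing in this module imputes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

__all__ = [
    "PatientRecord",
    "EncodedRecord",
    "EncodingConfig",
    "MODEL_VARIABLES",
    "VARIABLE_LEVELS",
    "COHORT_COLUMNS",
    "encode_record",
    "encode_cohort",
    "osa_label",
    "read_cohort",
    "write_cohort",
]

#: Names of the six classifier predictors, in canonical order.
MODEL_VARIABLES = (
    "sex",
    "age_band",
    "nc_increased",
    "cfa",
    "witnessed_apneas",
    "nocturia",
)

_BOOL_FIELDS = (
    "cfa",
    "witnessed_apneas",
    "nocturia",
    "snoring",
    "morning_headache",
    "non_restful_sleep",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "cardiac_pathology",
    "stroke",
    "depression",
)

#: Canonical cohort CSV header.
COHORT_COLUMNS = (
    "id",
    "sex",
    "age_years",
    "neck_circumference_cm",
    "cfa",
    "witnessed_apneas",
    "nocturia",
    "bmi",
    "ess",
    "snoring",
    "morning_headache",
    "non_restful_sleep",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "cardiac_pathology",
    "stroke",
    "depression",
    "psg_type",
    "ahi",
)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: six model predictors, covariates, PSG type and AHI.

    Every field except ``id`` may be ``None`` (missing).  Invariants (checked
    by :meth:`validate`): adult cohort (age >= 18), AHI >= 0, Epworth score in
    0–24, positive neck circumference and BMI.
    """

    id: str
    sex: str | None = None  # "male" / "female"
    age_years: float | None = None
    neck_circumference_cm: float | None = None
    cfa: bool | None = None
    witnessed_apneas: bool | None = None
    nocturia: bool | None = None
    bmi_kg_m2: float | None = None
    ess_score: int | None = None
    snoring: bool | None = None
    morning_headache: bool | None = None
    non_restful_sleep: bool | None = None
    hypertension: bool | None = None
    diabetes: bool | None = None
    dyslipidemia: bool | None = None
    cardiac_pathology: bool | None = None
    stroke: bool | None = None
    depression: bool | None = None
    psg_type: str | None = None  # "I" / "III"
    ahi_events_per_hour: float | None = None
    nc_increased: bool | None = None  # precomputed override for the NC rule

    def validate(self) -> None:
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"record {self.id!r}: invalid sex {self.sex!r}")
        if self.age_years is not None and self.age_years < 18:
            raise ValueError(f"record {self.id!r}: age_years {self.age_years} < 18 (adult cohort)")
        if self.neck_circumference_cm is not None and self.neck_circumference_cm <= 0:
            raise ValueError(f"record {self.id!r}: non-positive neck circumference")
        if self.bmi_kg_m2 is not None and self.bmi_kg_m2 <= 0:
            raise ValueError(f"record {self.id!r}: non-positive BMI")
        if self.ess_score is not None and not 0 <= self.ess_score <= 24:
            raise ValueError(f"record {self.id!r}: ess_score {self.ess_score} outside 0-24")
        if self.psg_type is not None and self.psg_type not in ("I", "III"):
            raise ValueError(f"record {self.id!r}: psg_type must be 'I' or 'III'")
        if self.ahi_events_per_hour is not None and self.ahi_events_per_hour < 0:
            raise ValueError(f"record {self.id!r}: negative AHI")


@dataclass(frozen=True)
class EncodingConfig:
    """Thresholds mapping continuous measurements to classifier levels.

    ``age_band_edges`` are left-closed, right-open cut points: the defaults
    (40, 55, 70) give bands [18,40), [40,55), [55,70), [70, inf).
    ``nc_increased_threshold_cm`` may be a single value or a (male, female)
    pair; neck circumference >= threshold counts as increased.  The obesity
    and Epworth thresholds are used only for descriptive reporting, never by
    the classifier.
    """

    age_band_edges: tuple[float, ...] = (40.0, 55.0, 70.0)
    nc_increased_threshold_cm: float | tuple[float, float] = 40.0
    obesity_bmi_threshold: float = 30.0
    ess_increased_threshold: int = 11

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.age_band_edges)
        if list(edges) != sorted(set(edges)):
            raise ValueError("age_band_edges must be strictly increasing")
        object.__setattr__(self, "age_band_edges", edges)
        thr = self.nc_increased_threshold_cm
        if isinstance(thr, (int, float)):
            if thr <= 0:
                raise ValueError("nc_increased_threshold_cm must be positive")
        else:
            if len(thr) != 2 or any(t <= 0 for t in thr):
                raise ValueError("sex-specific NC thresholds must be a positive (male, female) pair")

    def age_band_labels(self) -> tuple[str, ...]:
        """Band labels, e.g. ('<40', '40-54', '55-69', '>=70') for the defaults."""
        edges = self.age_band_edges
        labels = [f"<{edges[0]:g}"]
        for lo, hi in zip(edges, edges[1:]):
            if float(lo).is_integer() and float(hi).is_integer():
                labels.append(f"{lo:g}-{hi - 1:g}")
            else:
                labels.append(f"[{lo:g},{hi:g})")
        labels.append(f">={edges[-1]:g}")
        return tuple(labels)

    def age_band(self, age_years: float) -> str:
        labels = self.age_band_labels()
        for label, edge in zip(labels, self.age_band_edges):
            if age_years < edge:
                return label
        return labels[-1]

    def nc_threshold_for(self, sex: str | None) -> float | None:
        thr = self.nc_increased_threshold_cm
        if isinstance(thr, (int, float)):
            return float(thr)
        if sex == "male":
            return float(thr[0])
        if sex == "female":
            return float(thr[1])
        return None  # sex-specific rule but sex unknown


DEFAULT_ENCODING = EncodingConfig()

#: Declared levels per classifier variable (default encoding).
VARIABLE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "age_band": DEFAULT_ENCODING.age_band_labels(),
    "nc_increased": ("yes", "no"),
    "cfa": ("yes", "no"),
    "witnessed_apneas": ("yes", "no"),
    "nocturia": ("yes", "no"),
}


@dataclass(frozen=True)
class EncodedRecord:
    """Categorical levels (``None`` = missing) for the six classifier inputs."""

    sex: str | None = None
    age_band: str | None = None
    nc_increased: str | None = None
    cfa: str | None = None
    witnessed_apneas: str | None = None
    nocturia: str | None = None

    def as_dict(self) -> dict[str, str | None]:
        return {v: getattr(self, v) for v in MODEL_VARIABLES}

    def validate(self, levels: dict[str, tuple[str, ...]] | None = None) -> None:
        levels = levels or VARIABLE_LEVELS
        for var in MODEL_VARIABLES:
            val = getattr(self, var)
            if val is not None and val not in levels[var]:
                raise ValueError(f"invalid level {val!r} for variable {var!r}")


def _yesno(flag: bool | None) -> str | None:
    if flag is None:
        return None
    return "yes" if flag else "no"


def encode_record(record: PatientRecord, config: EncodingConfig = DEFAULT_ENCODING) -> EncodedRecord:
    """Map a raw record onto the classifier's categorical levels.

    Deterministic and total on valid records; missing inputs map to missing
    levels, never imputed.  A precomputed ``nc_increased`` flag on the record
    takes precedence over the threshold rule.
    """
    record.validate()
    if record.nc_increased is not None:
        nc = _yesno(record.nc_increased)
    elif record.neck_circumference_cm is None:
        nc = None
    else:
        thr = config.nc_threshold_for(record.sex)
        nc = None if thr is None else _yesno(record.neck_circumference_cm >= thr)
    return EncodedRecord(
        sex=record.sex,
        age_band=None if record.age_years is None else config.age_band(record.age_years),
        nc_increased=nc,
        cfa=_yesno(record.cfa),
        witnessed_apneas=_yesno(record.witnessed_apneas),
        nocturia=_yesno(record.nocturia),
    )


def encode_cohort(
    records: Iterable[PatientRecord], config: EncodingConfig = DEFAULT_ENCODING
) -> list[EncodedRecord]:
    return [encode_record(r, config) for r in records]


def osa_label(ahi: float | None, threshold: float = 5.0) -> bool:
    """Outcome rule: OSA (or the severity class) is present iff AHI >= threshold.

    The comparison is closed: AHI exactly at the threshold is positive.
    Raises ``ValueError`` for a missing AHI — a subject without a sleep study
    cannot be labelled; callers must not coerce this to False.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ahi is None:
        raise ValueError("AHI is missing: subject is unlabelable")
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    return ahi >= threshold


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_bool(text: str, row_id: str, column: str) -> bool:
    t = text.strip().lower()
    if t in ("1", "yes", "true", "y"):
        return True
    if t in ("0", "no", "false", "n"):
        return False
    raise ValueError(f"row {row_id!r}, column {column!r}: cannot parse boolean {text!r}")


def _parse_float(text: str, row_id: str, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"row {row_id!r}, column {column!r}: malformed number {text!r}") from None


def read_cohort(path, config: EncodingConfig = DEFAULT_ENCODING) -> list[PatientRecord]:
    """Read a cohort CSV (header required, empty cell = missing).

    Unknown columns are ignored, except a precomputed ``nc_increased`` column,
    which overrides the threshold rule during encoding.  Duplicate ids and
    malformed cells raise ``ValueError`` with row/column context.
    """
    records: list[PatientRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: cohort CSV must have a header with an 'id' column")
        for row in reader:
            rid = (row.get("id") or "").strip()
            if not rid:
                raise ValueError(f"{path}: row with empty id")
            if rid in seen:
                raise ValueError(f"{path}: duplicate id {rid!r}")
            seen.add(rid)

            def cell(col: str) -> str | None:
                val = row.get(col)
                if val is None or val.strip() == "":
                    return None
                return val.strip()

            def fnum(col: str) -> float | None:
                v = cell(col)
                return None if v is None else _parse_float(v, rid, col)

            def fbool(col: str) -> bool | None:
                v = cell(col)
                return None if v is None else _parse_bool(v, rid, col)

            ess = fnum("ess")
            sex = cell("sex")
            if sex is not None:
                sex = sex.lower()
                sex = {"m": "male", "f": "female"}.get(sex, sex)
            rec = PatientRecord(
                id=rid,
                sex=sex,
                age_years=fnum("age_years"),
                neck_circumference_cm=fnum("neck_circumference_cm"),
                cfa=fbool("cfa"),
                witnessed_apneas=fbool("witnessed_apneas"),
                nocturia=fbool("nocturia"),
                bmi_kg_m2=fnum("bmi"),
                ess_score=None if ess is None else int(ess),
                snoring=fbool("snoring"),
                morning_headache=fbool("morning_headache"),
                non_restful_sleep=fbool("non_restful_sleep"),
                hypertension=fbool("hypertension"),
                diabetes=fbool("diabetes"),
                dyslipidemia=fbool("dyslipidemia"),
                cardiac_pathology=fbool("cardiac_pathology"),
                stroke=fbool("stroke"),
                depression=fbool("depression"),
                psg_type=cell("psg_type"),
                ahi_events_per_hour=fnum("ahi"),
                nc_increased=fbool("nc_increased") if "nc_increased" in (reader.fieldnames or ()) else None,
            )
            rec.validate()
            records.append(rec)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def write_cohort(records: Sequence[PatientRecord], path, include_nc_increased: bool = False) -> None:
    """Write records to the canonical cohort CSV (round-trip stable)."""
    columns = list(COHORT_COLUMNS)
    if include_nc_increased or any(r.nc_increased is not None for r in records):
        columns.append("nc_increased")
    colmap = {
        "id": "id",
        "sex": "sex",
        "age_years": "age_years",
        "neck_circumference_cm": "neck_circumference_cm",
        "cfa": "cfa",
        "witnessed_apneas": "witnessed_apneas",
        "nocturia": "nocturia",
        "bmi": "bmi_kg_m2",
        "ess": "ess_score",
        "snoring": "snoring",
        "morning_headache": "morning_headache",
        "non_restful_sleep": "non_restful_sleep",
        "hypertension": "hypertension",
        "diabetes": "diabetes",
        "dyslipidemia": "dyslipidemia",
        "cardiac_pathology": "cardiac_pathology",
        "stroke": "stroke",
        "depression": "depression",
        "psg_type": "psg_type",
        "ahi": "ahi_events_per_hour",
        "nc_increased": "nc_increased",
    }
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            writer.writerow([_fmt(getattr(rec, colmap[c])) for c in columns])
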