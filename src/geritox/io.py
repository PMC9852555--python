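"""CSV / YAML interfaces.

CSV dialect: comma-separated, UTF-8, header row required, dot decimal
separator, missing values as empty cells.  Column names match the record
field names exactly.  Booleans are written as ``True`` / ``False`` and
accepted case-insensitively, also as ``1`` / ``0`` / ``yes`` / ``no``;
integer fall counts > 0 map to ``True`` for ``falls_past_6mo``.

Units are a contract, not a conversion: an optional YAML config may
declare the unit for each laboratory column and loading *rejects* any
declaration that differs from the package conventions (hemoglobin g/dL,
albumin g/L, creatinine clearance mL/min, LDH U/L) instead of silently
converting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .records import (
    OUTCOME_FIELDS,
    PATIENT_FIELDS,
    OutcomeRecord,
    PatientRecord,
    ValidationError,
)

EXPECTED_UNITS = {
    "hemoglobin": "g/dL",
    "albumin": "g/L",
    "creatinine_clearance": "mL/min",
    "ldh": "U/L",
}

_BOOL_FIELDS = (
    "falls_past_6mo",
    "hearing_fair_or_worse",
    "walking_one_block_limited",
    "needs_help_medications",
    "decreased_social_activity",
    "polychemotherapy",
    "standard_dose",
    "grade34_ae",
    "ed_visit",
    "hospital_admission",
    "discontinued_chemo",
)

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


class UnitsError(ValidationError):
    """A declared unit differs from the package convention."""


def load_config(path) -> dict:
    """Load a YAML run config; validates the optional ``units`` section."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    check_units(cfg.get("units", {}))
    return cfg


def check_units(declared: dict) -> None:
    for col, unit in (declared or {}).items():
        if col not in EXPECTED_UNITS:
            raise UnitsError(f"units declared for unknown column {col!r}")
        if unit != EXPECTED_UNITS[col]:
            raise UnitsError(
                f"{col} declared in {unit!r} but this pipeline requires "
                f"{EXPECTED_UNITS[col]!r}; convert before loading"
            )


def _parse_bool(value, field_name: str):
    if value is None:
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        if field_name == "falls_past_6mo":
            return value > 0  # a fall count
        return bool(value)
    s = str(value).strip().lower()
    if s == "":
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    try:
        return _parse_bool(float(s), field_name)
    except ValueError:
        raise ValidationError(f"cannot parse boolean {field_name}={value!r}") from None


def _opt_float(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s == "" else float(s)


def record_from_row(row) -> PatientRecord:
    """Build a :class:`PatientRecord` from a mapping / pandas row."""
    get = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
    stage_raw = get("stage")
    if isinstance(stage_raw, float) and float(stage_raw).is_integer():
        stage_raw = int(stage_raw)
    ecog = _opt_float(get("ecog_ps"))
    return PatientRecord(
        patient_id=(str(get("patient_id")) if get("patient_id") is not None else None),
        age=float(get("age")),
        sex=str(get("sex")),
        cancer_type=str(get("cancer_type")),
        stage=str(stage_raw),
        ecog_ps=None if ecog is None else int(ecog),
        hemoglobin=_opt_float(get("hemoglobin")),
        creatinine_clearance=_opt_float(get("creatinine_clearance")),
        albumin=_opt_float(get("albumin")),
        ldh=_opt_float(get("ldh")),
        falls_past_6mo=_parse_bool(get("falls_past_6mo"), "falls_past_6mo"),
        hearing_fair_or_worse=_parse_bool(get("hearing_fair_or_worse"), "hearing_fair_or_worse"),
        walking_one_block_limited=_parse_bool(get("walking_one_block_limited"), "walking_one_block_limited"),
        needs_help_medications=_parse_bool(get("needs_help_medications"), "needs_help_medications"),
        decreased_social_activity=_parse_bool(get("decreased_social_activity"), "decreased_social_activity"),
        polychemotherapy=_parse_bool(get("polychemotherapy"), "polychemotherapy"),
        standard_dose=_parse_bool(get("standard_dose"), "standard_dose"),
    )


def outcome_from_row(row) -> OutcomeRecord | None:
    get = row.get if hasattr(row, "get") else lambda k, d=None: getattr(row, k, d)
    flags = {f: _parse_bool(get(f), f) for f in OUTCOME_FIELDS if f != "length_of_stay"}
    if any(v is None for v in flags.values()):
        return None
    return OutcomeRecord(length_of_stay=_opt_float(get("length_of_stay")), **flags)


@dataclass
class LoadResult:
    """Typed records plus per-row validation errors (1-based row numbers)."""

    patients: list[PatientRecord]
    outcomes: list[OutcomeRecord | None]
    errors: list[tuple[int, str]]
    dataframe: pd.DataFrame

    @property
    def has_outcomes(self) -> bool:
        return any(o is not None for o in self.outcomes)


def read_patients_csv(path, units: dict | None = None) -> LoadResult:
    """Read a patient CSV into typed records.

    Hard-fails only on a malformed header (no required demographic
    columns); individual bad rows are collected in ``errors`` and skipped.
    Unknown columns produce a warning and are ignored.
    """
    check_units(units or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = set(PATIENT_FIELDS) | set(OUTCOME_FIELDS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
    required = {"age", "sex", "cancer_type", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"header is missing required columns: {sorted(missing)}")

    patients, outcomes, errors = [], [], []
    has_outcome_cols = any(
        c in df.columns for c in OUTCOME_FIELDS if c != "length_of_stay"
    )
    for i, row in enumerate(df.to_dict("records"), start=1):
        row = {k: (None if str(v).strip() == "" else v) for k, v in row.items()}
        try:
            patients.append(record_from_row(row))
            outcomes.append(outcome_from_row(row) if has_outcome_cols else None)
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    return LoadResult(patients, outcomes, errors, df)


def cohort_to_dataframe(
    patients: list[PatientRecord], outcomes: list[OutcomeRecord | None] | None = None
) -> pd.DataFrame:
    """Flatten records into the canonical CSV column layout."""
    cols = ["patient_id"] + [f for f in PATIENT_FIELDS if f != "patient_id"]
    data = {c: [getattr(p, c) for p in patients] for c in cols}
    if outcomes is not None and any(o is not None for o in outcomes):
        for c in OUTCOME_FIELDS:
            data[c] = [None if o is None else getattr(o, c) for o in outcomes]
    return pd.DataFrame(data)


def write_cohort_csv(path, patients, outcomes=None) -> None:
    cohort_to_dataframe(patients, outcomes).to_csv(path, index=False)


def write_scores_csv(path, scores_df: pd.DataFrame) -> None:
    scores_df.to_csv(path, index=False)
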