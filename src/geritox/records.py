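"""Patient-level domain records.

A :class:`PatientRecord` carries everything needed to compute both risk
scores: demographics, tumour descriptors, baseline laboratory values and
the five geriatric-questionnaire items used by the CARG tool, plus the two
treatment descriptors (polychemotherapy, standard vs. reduced dose).
An :class:`OutcomeRecord` carries the four binary tolerability outcomes
observed during chemotherapy and up to three months after.

Laboratory units are fixed by convention and enforced at the I/O layer:
hemoglobin in g/dL, albumin in g/L, creatinine clearance in mL/min and
LDH in U/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

SEXES = ("male", "female")
CANCER_TYPES = ("GI", "breast", "lung", "GU_GYN", "other")
STAGES = ("1", "2", "3", "4", "localized_NOS")


class ValidationError(ValueError):
    """A record field violates its domain constraint."""


class MissingFieldError(ValidationError):
    """A field required for the requested computation is absent."""

    def __init__(self, field_name: str, context: str = ""):
        self.field_name = field_name
        msg = f"missing required field {field_name!r}"
        if context:
            msg += f" for {context}"
        super().__init__(msg)


def _check_positive(name: str, value) -> None:
    if value is not None and not value > 0:
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class PatientRecord:
    """One patient's baseline data.

    ``stage`` is one of ``"1"``–``"4"`` or ``"localized_NOS"`` (a localized
    cancer whose exact stage was not otherwise specified); integers are
    accepted and normalised.  Any lab value may be ``None`` (missing);
    scoring then fails loudly rather than imputing.
    """

    age: float
    sex: str
    cancer_type: str
    stage: str
    ecog_ps: int | None = None
    hemoglobin: float | None = None
    creatinine_clearance: float | None = None
    albumin: float | None = None
    ldh: float | None = None
    falls_past_6mo: bool | None = None
    hearing_fair_or_worse: bool | None = None
    walking_one_block_limited: bool | None = None
    needs_help_medications: bool | None = None
    decreased_social_activity: bool | None = None
    polychemotherapy: bool | None = None
    standard_dose: bool | None = None
    patient_id: str | None = None

    def __post_init__(self):
        if self.age < 18:
            raise ValidationError(f"age must be >= 18, got {self.age}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.cancer_type not in CANCER_TYPES:
            raise ValidationError(
                f"cancer_type must be one of {CANCER_TYPES}, got {self.cancer_type!r}"
            )
        self.stage = str(self.stage)
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.ecog_ps is not None:
            self.ecog_ps = int(self.ecog_ps)
            if not 0 <= self.ecog_ps <= 4:
                raise ValidationError(f"ecog_ps must be 0-4, got {self.ecog_ps}")
        for name in ("hemoglobin", "creatinine_clearance", "albumin", "ldh"):
            _check_positive(name, getattr(self, name))

    @property
    def is_stage4(self) -> bool:
        return self.stage == "4"

    def require(self, *names: str, context: str = "") -> None:
        """Raise :class:`MissingFieldError` for the first absent field."""
        for name in names:
            if getattr(self, name) is None:
                raise MissingFieldError(name, context)


@dataclass
class OutcomeRecord:
    """The four binary tolerability outcomes (+ optional length of stay).

    ``length_of_stay`` (days) may only be present when the patient was
    admitted to hospital.
    """

    grade34_ae: bool
    ed_visit: bool
    hospital_admission: bool
    discontinued_chemo: bool
    length_of_stay: float | None = None

    def __post_init__(self):
        if self.length_of_stay is not None:
            if not self.hospital_admission:
                raise ValidationError(
                    "length_of_stay present without hospital_admission"
                )
            if self.length_of_stay < 0:
                raise ValidationError("length_of_stay must be >= 0")


PATIENT_FIELDS = tuple(f.name for f in fields(PatientRecord))
OUTCOME_FIELDS = tuple(f.name for f in fields(OutcomeRecord))
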