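"""Index4 and CARG chemotherapy-toxicity risk scores.

Index4 awards 1 point each for: ECOG performance status above 1,
creatinine clearance below 40 mL/min, albumin below 35 g/L, and stage 4
cancer.  It dichotomises naturally at 0 versus >= 1.

The CARG (Cancer and Aging Research Group) tool sums 11 weighted items:
3 points each for low hemoglobin (< 11 g/dL men / < 10 g/dL women),
creatinine clearance below 34 mL/min, and one or more falls in the past
six months; 2 points each for age older than 72, gastrointestinal or
genitourinary cancer, standard (non-reduced) chemotherapy dose,
polychemotherapy, hearing rated fair or worse, and limited ability to
walk one block; 1 point each for needing help taking medications and for
decreased social activity.  Risk categories: low 0-5, intermediate 6-9,
high >= 10.  The stated weights sum to 23, which is the maximum total this
implementation can produce.

All threshold comparisons are strict, exactly as the criteria are worded
("below 40" means < 40, "older than 72" means > 72); values sitting
exactly on a boundary score no points.  Missing inputs raise
:class:`~geritox.records.MissingFieldError` rather than being imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import MissingFieldError, PatientRecord

INDEX4_GROUPS = ("score0", "score_ge1")
CARG_GROUPS = ("low", "intermediate", "high")
CARG_MAX_TOTAL = 23

#: CARG item weights, in reporting order.
CARG_WEIGHTS = {
    "hemoglobin_low": 3,
    "crcl_lt34": 3,
    "falls": 3,
    "age_gt72": 2,
    "gi_gu_cancer": 2,
    "standard_dose": 2,
    "polychemotherapy": 2,
    "hearing": 2,
    "walking": 2,
    "med_help": 1,
    "social_activity": 1,
}

DICHOTOMIZATION_RULES = (
    "index4_ge1",
    "index4_eq0",
    "carg_high",
    "carg_int_high",
    "carg_low",
    "carg_low_int",
)


@dataclass(frozen=True)
class ScoreResult:
    """A computed score with its per-item point breakdown and risk group."""

    tool: str  # "index4" or "carg"
    total: int
    item_points: dict[str, int]
    group: str

    def __post_init__(self):
        if self.total != sum(self.item_points.values()):
            raise ValueError("total does not equal the sum of item points")


def index4_score(record: PatientRecord) -> ScoreResult:
    """Compute the Index4 score (0-4) from a patient record.

    Requires ``ecog_ps``, ``creatinine_clearance``, ``albumin`` and
    ``stage``; raises :class:`MissingFieldError` naming the first absent
    field.
    """
    record.require("ecog_ps", "creatinine_clearance", "albumin", context="index4")
    items = {
        "ecog_gt1": int(record.ecog_ps > 1),
        "crcl_lt40": int(record.creatinine_clearance < 40),
        "albumin_lt35": int(record.albumin < 35),
        "stage4": int(record.is_stage4),
    }
    total = sum(items.values())
    group = "score0" if total == 0 else "score_ge1"
    return ScoreResult("index4", total, items, group)


def carg_hemoglobin_low(hemoglobin: float, sex: str) -> bool:
    """The CARG anemia item: hemoglobin < 11 g/dL for men, < 10 for women.

    Distinct from :func:`anemia_descriptive`; the two cut-offs must not be
    conflated.
    """
    return hemoglobin < (11.0 if sex == "male" else 10.0)


def anemia_descriptive(hemoglobin: float, sex: str) -> bool:
    """Descriptive anemia: hemoglobin < 12 g/dL for men, < 11 for women.

    Used only for cohort-description tables, never inside the CARG score.
    """
    return hemoglobin < (12.0 if sex == "male" else 11.0)


def carg_score(record: PatientRecord) -> ScoreResult:
    """Compute the CARG toxicity score (0-23) from a patient record."""
    record.require(
        "hemoglobin",
        "creatinine_clearance",
        "falls_past_6mo",
        "hearing_fair_or_worse",
        "walking_one_block_limited",
        "needs_help_medications",
        "decreased_social_activity",
        "polychemotherapy",
        "standard_dose",
        context="carg",
    )
    conditions = {
        "hemoglobin_low": carg_hemoglobin_low(record.hemoglobin, record.sex),
        "crcl_lt34": record.creatinine_clearance < 34,
        "falls": bool(record.falls_past_6mo),
        "age_gt72": record.age > 72,
        "gi_gu_cancer": record.cancer_type in ("GI", "GU_GYN"),
        "standard_dose": bool(record.standard_dose),
        "polychemotherapy": bool(record.polychemotherapy),
        "hearing": bool(record.hearing_fair_or_worse),
        "walking": bool(record.walking_one_block_limited),
        "med_help": bool(record.needs_help_medications),
        "social_activity": bool(record.decreased_social_activity),
    }
    items = {k: CARG_WEIGHTS[k] * int(v) for k, v in conditions.items()}
    total = sum(items.values())
    return ScoreResult("carg", total, items, carg_risk_category(total))


def carg_risk_category(total: int) -> str:
    """Map a CARG total to its risk category: 0-5 low, 6-9 intermediate, >= 10 high."""
    if total < 0:
        raise ValueError(f"CARG total must be non-negative, got {total}")
    if total <= 5:
        return "low"
    if total <= 9:
        return "intermediate"
    return "high"


def dichotomize(score: ScoreResult, rule: str) -> bool:
    """Evaluate one of the six dichotomisation rules on a score.

    Positive-classification rules (``index4_ge1``, ``carg_high``,
    ``carg_int_high``) return the "test positive" indicator; the mirrored
    rules (``index4_eq0``, ``carg_low``, ``carg_low_int``) return the
    "classified negative" indicator used when predicting the *absence* of
    an outcome.
    """
    if rule not in DICHOTOMIZATION_RULES:
        raise ValueError(f"unknown rule {rule!r}")
    expected_tool = "index4" if rule.startswith("index4") else "carg"
    if score.tool != expected_tool:
        raise ValueError(f"rule {rule!r} is incompatible with a {score.tool} score")
    if rule == "index4_ge1":
        return score.total >= 1
    if rule == "index4_eq0":
        return score.total == 0
    if rule == "carg_high":
        return score.group == "high"
    if rule == "carg_int_high":
        return score.group in ("intermediate", "high")
    if rule == "carg_low":
        return score.group == "low"
    return score.group in ("low", "intermediate")  # carg_low_int


def cockcroft_gault(
    age: float, weight_kg: float, sex: str, serum_creatinine_umol_l: float
) -> float:
    """Cockcroft-Gault creatinine-clearance estimate in mL/min.

    ``CrCl = (140 - age) * weight / (72 * Scr[mg/dL])``, multiplied by 0.85
    for women; serum creatinine is taken in µmol/L (1 mg/dL = 88.4 µmol/L).
    Convenience helper only -- the scoring pipeline's canonical input is a
    precomputed ``creatinine_clearance``.
    """
    for name, v in (
        ("age", age),
        ("weight_kg", weight_kg),
        ("serum_creatinine_umol_l", serum_creatinine_umol_l),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if age >= 140:
        raise ValueError("Cockcroft-Gault is undefined for age >= 140")
    scr_mg_dl = serum_creatinine_umol_l / 88.4
    crcl = (140.0 - age) * weight_kg / (72.0 * scr_mg_dl)
    if sex == "female":
        crcl *= 0.85
    return crcl


def score_dataframe(df: pd.DataFrame, tools: tuple[str, ...] = ("index4", "carg")) -> pd.DataFrame:
    """Score every row of a patient-record DataFrame.

    Returns a DataFrame aligned with ``df``'s index holding totals, groups
    and per-item point columns.  Rows whose scoring fails get an entry in
    the ``error`` column instead of scores.
    """
    from .io import record_from_row  # local import to avoid a cycle

    out_rows = []
    for _, row in df.iterrows():
        out: dict[str, object] = {}
        try:
            rec = record_from_row(row)
            if "index4" in tools:
                s = index4_score(rec)
                out["index4_total"] = s.total
                out["index4_group"] = s.group
                out.update({f"index4_{k}": v for k, v in s.item_points.items()})
            if "carg" in tools:
                s = carg_score(rec)
                out["carg_total"] = s.total
                out["carg_group"] = s.group
                out.update({f"carg_{k}": v for k, v in s.item_points.items()})
            out["error"] = ""
        except (MissingFieldError, ValueError) as exc:
            out = {"error": str(exc)}
        out_rows.append(out)
    res = pd.DataFrame(out_rows, index=df.index)
    if "patient_id" in df.columns:
        res.insert(0, "patient_id", df["patient_id"])
    return res
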