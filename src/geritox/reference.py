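"""Packaged reference data from the published validation cohort (n = 117).

The original study deposited only aggregate tables, not patient-level
data.  This module encodes those aggregates in machine-readable form:

* outcome x risk-group contingency counts for both tools,
* the published sensitivity/specificity/PPV/NPV/accuracy table,
* the published paired McNemar comparisons, together with the discordant
  pairs (b, c) *reconstructed* from the printed marginal counts and odds
  ratios (the study did not print b and c directly; the reconstruction is
  unique given the marginal difference b - c and the printed ratio b/c,
  and reproduces every printed p-value and confidence bound),
* the cohort-composition marginals used to calibrate the synthetic
  generator.

Note on precision: the source tables truncate (rather than round)
decimals, so a recomputed value can sit up to one unit of the last
printed digit above the printed one (e.g. 56/68 = 82.35% printed as
82.3).  Comparisons therefore use agreement at the printed decimal
(absolute difference < 0.1 percentage points), not half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import (
    BinaryConfusion,
    DiagnosticMetrics,
    McNemarResult,
    PairedDiscordance,
    diagnostic_metrics,
    mcnemar_exact,
)

COHORT_N = 117

OUTCOMES = ("grade34_ae", "ed_visit", "hospital_admission", "discontinued_chemo")

#: Outcome (yes, no) counts by Index4 group: {outcome: {"score0": (yes, no), ...}}
INDEX4_OUTCOME_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "grade34_ae": {"score0": (31, 30), "score_ge1": (36, 20)},
    "ed_visit": {"score0": (20, 41), "score_ge1": (34, 22)},
    "hospital_admission": {"score0": (12, 49), "score_ge1": (22, 34)},
    "discontinued_chemo": {"score0": (16, 45), "score_ge1": (33, 23)},
}

#: Outcome (yes, no) counts by CARG risk category.
CARG_OUTCOME_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "grade34_ae": {"low": (9, 14), "intermediate": (27, 27), "high": (31, 9)},
    "ed_visit": {"low": (7, 16), "intermediate": (18, 36), "high": (29, 11)},
    "hospital_admission": {"low": (4, 19), "intermediate": (11, 43), "high": (19, 21)},
    "discontinued_chemo": {"low": (6, 17), "intermediate": (15, 39), "high": (28, 12)},
}

#: Published diagnostic metrics, percent: {(outcome, rule): (sens, spec, ppv, npv, acc)}
PUBLISHED_METRICS: dict[tuple[str, str], tuple[float, float, float, float, float]] = {
    ("grade34_ae", "carg_high"): (46.3, 82.0, 77.5, 53.2, 61.5),
    ("grade34_ae", "carg_int_high"): (86.6, 28.0, 61.7, 60.9, 61.5),
    ("grade34_ae", "index4_ge1"): (53.7, 60.0, 64.3, 49.2, 56.4),
    ("ed_visit", "carg_high"): (53.7, 82.5, 72.5, 67.5, 69.2),
    ("ed_visit", "index4_ge1"): (63.0, 65.1, 60.7, 67.2, 64.1),
    ("hospital_admission", "carg_high"): (55.9, 74.7, 47.5, 80.5, 69.2),
    ("hospital_admission", "index4_ge1"): (64.7, 59.0, 39.3, 80.3, 60.7),
    ("discontinued_chemo", "carg_high"): (57.1, 82.3, 70.0, 72.7, 71.8),
    ("discontinued_chemo", "index4_ge1"): (67.3, 66.2, 58.9, 73.8, 66.7),
}

#: Published paired comparisons (CARG standard vs Index4 experimental):
#: {(outcome, stratum, carg_rule): (b, c, printed_p, printed_or, printed_ci)}.
#: The Index4 rule is index4_ge1 in the present-stratum and index4_eq0 in
#: the absent-stratum.  (b, c) are reconstructed, see module docstring.
PUBLISHED_MCNEMAR: dict[tuple[str, str, str], tuple[int, int, float, float, tuple[float, float]]] = {
    ("grade34_ae", "outcome_present_only", "carg_high"): (16, 11, 0.44, 1.45, (0.63, 3.46)),
    ("grade34_ae", "outcome_present_only", "carg_int_high"): (3, 25, 0.0001, 0.12, (0.02, 0.39)),
    ("grade34_ae", "outcome_absent_only", "carg_low"): (20, 4, 0.002, 5.0, (1.67, 20.11)),
    ("grade34_ae", "outcome_absent_only", "carg_low_int"): (2, 13, 0.01, 0.15, (0.01, 0.68)),
    ("ed_visit", "outcome_present_only", "carg_high"): (13, 8, 0.38, 1.62, (0.62, 4.52)),
    ("ed_visit", "outcome_absent_only", "carg_low"): (28, 3, 0.0001, 9.33, (2.88, 47.9)),
    ("hospital_admission", "outcome_present_only", "carg_high"): (10, 7, 0.62, 1.42, (0.49, 4.42)),
    ("hospital_admission", "outcome_absent_only", "carg_low"): (34, 4, 0.0001, 8.5, (3.03, 32.9)),
    ("discontinued_chemo", "outcome_present_only", "carg_high"): (13, 8, 0.38, 1.62, (0.62, 4.5)),
    ("discontinued_chemo", "outcome_absent_only", "carg_low"): (32, 4, 0.0001, 8.0, (2.83, 31.1)),
}

#: Cohort composition marginals (counts out of 117) used as simulator
#: calibration targets.
COHORT_COMPOSITION = {
    "index4_score_counts": (61, 28, 15, 13, 0),  # scores 0..4
    "carg_category_counts": (23, 54, 40),  # low / intermediate / high
    "index4_item_counts": {  # ecog>1, CrCl<40, albumin<35, stage 4
        "ecog_gt1": 16,
        "crcl_lt40": 11,
        "albumin_lt35": 30,
        "stage4": 43,
    },
    "age_mean": 76.6,
    "age_sd": 5.0,
    "p_male": 60 / 117,
    "cancer_type_counts": {"GI": 55, "breast": 18, "lung": 22, "GU_GYN": 12, "other": 10},
    "nonstage4_stage_counts": {"1": 11, "2": 25, "3": 30, "localized_NOS": 8},
    "anemia_descriptive_count": 28,  # < 12 g/dL men / < 11 women
    "ldh_elevated_count": 18,  # > 210 U/L, of 113 measured
    "ldh_missing_count": 4,
    "mean_los_days": {"score0": 12.3, "score_ge1": 18.5},
}


@dataclass(frozen=True)
class ReferenceTables:
    """The published aggregates, exposed as typed containers."""

    index4_counts: dict[str, dict[str, tuple[int, int]]]
    carg_counts: dict[str, dict[str, tuple[int, int]]]
    published_metrics: dict[tuple[str, str], tuple[float, ...]]
    published_mcnemar: dict[tuple[str, str, str], tuple]
    composition: dict
    n: int = COHORT_N


def load_reference_tables() -> ReferenceTables:
    """Return the packaged reference aggregates."""
    return ReferenceTables(
        index4_counts=INDEX4_OUTCOME_COUNTS,
        carg_counts=CARG_OUTCOME_COUNTS,
        published_metrics=PUBLISHED_METRICS,
        published_mcnemar=PUBLISHED_MCNEMAR,
        composition=COHORT_COMPOSITION,
    )


def confusion_for(outcome: str, rule: str) -> BinaryConfusion:
    """Build the 2x2 table for a dichotomisation rule from the reference counts.

    Only the positive-classification rules appear in the published
    metric table; mirrored rules give the transposed assignment of
    test-positive.
    """
    if rule.startswith("index4"):
        counts = INDEX4_OUTCOME_COUNTS[outcome]
        positive_groups = {"index4_ge1": ("score_ge1",), "index4_eq0": ("score0",)}[rule]
    else:
        counts = CARG_OUTCOME_COUNTS[outcome]
        positive_groups = {
            "carg_high": ("high",),
            "carg_int_high": ("intermediate", "high"),
            "carg_low": ("low",),
            "carg_low_int": ("low", "intermediate"),
        }[rule]
    tp = sum(counts[g][0] for g in positive_groups)
    fp = sum(counts[g][1] for g in positive_groups)
    fn = sum(yes for g, (yes, no) in counts.items() if g not in positive_groups)
    tn = sum(no for g, (yes, no) in counts.items() if g not in positive_groups)
    return BinaryConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def reproduce_reference(tol_pp: float = 0.1) -> "pd.DataFrame":
    """Recompute every published metric cell from the packaged counts.

    Returns a tidy DataFrame with one row per (outcome, rule, metric)
    holding the recomputed percentage, the published value and a match
    flag (agreement at the printed decimal, |diff| < ``tol_pp``).
    """
    import pandas as pd

    rows = []
    metric_names = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
    for (outcome, rule), published in PUBLISHED_METRICS.items():
        m = diagnostic_metrics(confusion_for(outcome, rule))
        for name, pub in zip(metric_names, published):
            recomputed = getattr(m, name) * 100
            rows.append(
                {
                    "outcome": outcome,
                    "rule": rule,
                    "metric": name,
                    "recomputed_pct": recomputed,
                    "published_pct": pub,
                    "match": abs(recomputed - pub) < tol_pp,
                }
            )
    return pd.DataFrame(rows)


def reference_mcnemar_results() -> dict[tuple[str, str, str], McNemarResult]:
    """Exact McNemar results recomputed from the reconstructed pairs."""
    return {
        key: mcnemar_exact(PairedDiscordance(b=b, c=c))
        for key, (b, c, *_rest) in PUBLISHED_MCNEMAR.items()
    }
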