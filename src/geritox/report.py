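"""Cohort-level evaluation reports.

Ties scoring and evaluation together for one outcome: confusion metrics
for every applicable dichotomisation rule, ROC/AUC per tool on the raw
ordinal totals, and the paired Index4-vs-CARG McNemar comparisons in both
outcome strata.
"""

from __future__ import annotations

import math
from typing import Sequence

from .evaluation import (
    confusion_from_labels,
    diagnostic_metrics,
    paired_tool_comparison,
    roc_auc,
)
from .records import OutcomeRecord, PatientRecord
from .scoring import ScoreResult, carg_score, dichotomize, index4_score

OUTCOME_ALIASES = {
    "grade34": "grade34_ae",
    "ed": "ed_visit",
    "admission": "hospital_admission",
    "discontinuation": "discontinued_chemo",
}

#: (positivity rule, tool) pairs evaluated per outcome.
POSITIVE_RULES = ("carg_high", "carg_int_high", "index4_ge1")

#: Paired comparisons: (stratum, index4 rule, carg rules)
PAIRED_LAYOUT = (
    ("outcome_present_only", "index4_ge1", ("carg_high", "carg_int_high")),
    ("outcome_absent_only", "index4_eq0", ("carg_low", "carg_low_int")),
)


def _json_num(x: float) -> float | str | None:
    if x is None:
        return None
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return None
    return x


def evaluate_outcome(
    patients: Sequence[PatientRecord],
    outcomes: Sequence[OutcomeRecord],
    outcome: str,
    roc_on: str = "totals",
    ci_method: str = "delong",
    seed: int = 0,
) -> dict:
    """Full evaluation of one outcome; returns a JSON-serialisable dict.

    ``roc_on`` selects the ROC predictor scale: ``"totals"`` (raw ordinal
    scores, default) or ``"categories"`` (Index4 0/>=1; CARG low/int/high
    coded 0/1/2).
    """
    column = OUTCOME_ALIASES.get(outcome, outcome)
    y = [bool(getattr(o, column)) for o in outcomes]
    if not any(y) or all(y):
        raise ValueError(f"outcome {column!r} has a single class; cannot evaluate")

    i4: list[ScoreResult] = [index4_score(p) for p in patients]
    cg: list[ScoreResult] = [carg_score(p) for p in patients]

    rules = []
    for rule in POSITIVE_RULES:
        scores = i4 if rule.startswith("index4") else cg
        pred = [dichotomize(s, rule) for s in scores]
        conf = confusion_from_labels(pred, y)
        m = diagnostic_metrics(conf)
        rules.append(
            {
                "rule": rule,
                "confusion": {"tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn},
                "metrics_pct": m.as_percent(),
            }
        )

    def _roc_scores(scores, tool):
        if roc_on == "totals":
            return [s.total for s in scores]
        if tool == "index4":
            return [0 if s.group == "score0" else 1 for s in scores]
        return [("low", "intermediate", "high").index(s.group) for s in scores]

    auc = {}
    for tool, scores in (("index4", i4), ("carg", cg)):
        r = roc_auc(_roc_scores(scores, tool), y, ci_method=ci_method, seed=seed)
        auc[tool] = {"value": r.auc, "ci": [r.ci_low, r.ci_high], "method": r.ci_method}

    mcnemar = []
    for stratum, i4_rule, carg_rules in PAIRED_LAYOUT:
        for carg_rule in carg_rules:
            d, res = paired_tool_comparison(i4_rule, carg_rule, i4, cg, y, stratum)
            mcnemar.append(
                {
                    "stratum": stratum,
                    "index4_rule": i4_rule,
                    "carg_rule": carg_rule,
                    "b": res.b,
                    "c": res.c,
                    "p": res.p_value,
                    "or": _json_num(res.odds_ratio),
                    "ci": [_json_num(res.ci_low), _json_num(res.ci_high)],
                }
            )

    return {"outcome": column, "n": len(patients), "rules": rules, "auc": auc, "mcnemar": mcnemar}
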