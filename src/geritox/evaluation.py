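"""Diagnostic-accuracy evaluation of the two risk tools.

Implements the full statistical battery used to compare an ordinal risk
score against binary tolerability outcomes in a single cohort:

* 2x2 cross-tabulation and the five classical confusion metrics
  (sensitivity, specificity, PPV, NPV, accuracy);
* empirical ROC curves and the trapezoidal AUC, with a DeLong
  (asymptotic) or bootstrap 95% CI;
* the exact (central binomial) McNemar test for paired classifiers that
  share the same subjects, with the discordant-pair odds ratio b/c and an
  exact conditional CI;
* Fisher's exact / chi-square tests for categorical group differences and
  t-test / one-way ANOVA for continuous ones;
* descriptive cohort summaries by risk group.

Percentages are rounded half-up to one decimal at the reporting layer
only; all comparisons and downstream computation use unrounded values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def percent(x: float | None, decimals: int = 1) -> float | None:
    """Render a fraction as a percentage rounded half-up."""
    if x is None:
        return None
    scale = 10 ** decimals
    return math.floor(x * 100 * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# Confusion tables and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryConfusion:
    """2x2 table of a dichotomised score against a binary outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five confusion metrics as fractions; ``None`` marks an undefined
    metric (zero denominator)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: percent(getattr(self, k))
            for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        }


def confusion_from_labels(predicted_positive, outcome_present) -> BinaryConfusion:
    """Cross-tabulate per-patient test results against outcomes."""
    pred = np.asarray(predicted_positive, dtype=bool)
    outc = np.asarray(outcome_present, dtype=bool)
    if pred.shape != outc.shape or pred.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if pred.size == 0:
        raise ValueError("empty input vectors")
    return BinaryConfusion(
        tp=int(np.sum(pred & outc)),
        fp=int(np.sum(pred & ~outc)),
        fn=int(np.sum(~pred & outc)),
        tn=int(np.sum(~pred & ~outc)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostic_metrics(c: BinaryConfusion) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2x2 table."""
    if c.n == 0:
        raise ValueError("empty confusion table")
    return DiagnosticMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        accuracy=_ratio(c.tp + c.tn, c.n),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC points, trapezoidal AUC and a 95% CI."""

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from case/control score vectors.

    Uses the placement-value (structural component) decomposition: the
    variance of the Mann-Whitney estimator is var(V10)/m + var(V01)/n for
    m cases and n controls.
    """
    m, n = len(cases), len(controls)
    allx = np.concatenate([cases, controls])
    r_all = _midranks(allx)
    r_cases = _midranks(cases)
    r_controls = _midranks(controls)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_cases) / n          # placement of each case among controls
    v01 = 1.0 - (r_all[m:] - r_controls) / m  # placement of each control among cases
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(
    scores,
    outcome_present,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> ROCResult:
    """Empirical ROC over all observed thresholds with a 95% AUC CI.

    The AUC equals the trapezoidal area under the empirical curve, which
    for an ordinal score is the Mann-Whitney probability of concordance
    with ties counted one half.  ``ci_method`` is ``"delong"`` (default)
    or ``"bootstrap"`` (seeded, ``n_boot`` resamples); CIs are clipped to
    [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome_present, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if y.all() or (~y).all():
        raise ValueError("both outcome classes must be present for ROC analysis")

    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(y, s)
    cases, controls = s[y], s[~y]
    auc, var = _delong_auc_variance(cases, controls)

    if ci_method == "delong":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * math.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(s)
        boots = []
        while len(boots) < n_boot:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.all() or (~yb).all():
                continue
            a, _ = _delong_auc_variance(s[idx][yb], s[idx][~yb])
            boots.append(a)
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return ROCResult(
        thresholds=tuple(thresholds),
        fpr=tuple(fpr),
        tpr=tuple(tpr),
        auc=auc,
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# McNemar paired comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedDiscordance:
    """Discordant-pair decomposition of one outcome stratum.

    ``b`` counts patients classified correctly by the experimental tool
    (Index4) only, ``c`` those correct under the standard (CARG) only.
    """

    b: int
    c: int
    concordant_correct: int = 0
    concordant_wrong: int = 0

    def __post_init__(self):
        for name in ("b", "c", "concordant_correct", "concordant_wrong"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_stratum(self) -> int:
        return self.b + self.c + self.concordant_correct + self.concordant_wrong


@dataclass(frozen=True)
class McNemarResult:
    """Exact McNemar p-value with the discordant odds ratio b/c and CI.

    An odds ratio above 1 favours the experimental tool (Index4); below 1
    favours the standard (CARG).  ``odds_ratio`` is ``inf`` when c = 0 and
    ``nan`` for the undefined 0/0 case.
    """

    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    b: int
    c: int
    method: str = "exact"


def mcnemar_exact(
    d: PairedDiscordance | tuple[int, int], method: str = "exact", alpha: float = 0.05
) -> McNemarResult:
    """McNemar test on discordant counts (b, c).

    ``method="exact"`` (default) is the central two-sided exact binomial
    test of b ~ Binomial(b + c, 1/2); ``method="chi2"`` is the
    continuity-corrected chi-square approximation.  The 95% CI for the
    odds ratio is exact conditional: a Clopper-Pearson interval for
    p = b/(b + c) mapped to odds p/(1 - p).  With b + c = 0 the p-value
    is 1 and the odds ratio undefined.
    """
    if isinstance(d, tuple):
        d = PairedDiscordance(*d)
    b, c = d.b, d.c
    n = b + c

    if n == 0:
        return McNemarResult(1.0, float("nan"), float("nan"), float("nan"), b, c, method)

    if method == "exact":
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
    elif method == "chi2":
        chi2 = (abs(b - c) - 1) ** 2 / n
        p = float(stats.chi2.sf(chi2, 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    odds_ratio = b / c if c > 0 else float("inf")
    # Clopper-Pearson bounds on p = b/n, transformed to odds.
    if b == 0:
        p_lo = 0.0
    else:
        p_lo = float(stats.beta.ppf(alpha / 2, b, c + 1))
    if c == 0:
        p_hi = 1.0
    else:
        p_hi = float(stats.beta.ppf(1 - alpha / 2, b + 1, c))
    ci_low = p_lo / (1 - p_lo) if p_lo < 1 else float("inf")
    ci_high = p_hi / (1 - p_hi) if p_hi < 1 else float("inf")
    return McNemarResult(p, odds_ratio, ci_low, ci_high, b, c, method)


def paired_tool_comparison(
    index4_rule: str,
    carg_rule: str,
    index4_scores,
    carg_scores,
    outcome_present,
    stratum: str,
    method: str = "exact",
) -> tuple[PairedDiscordance, McNemarResult]:
    """Compare the two tools on the same patients within an outcome stratum.

    ``stratum`` is ``"outcome_present_only"`` or ``"outcome_absent_only"``.
    Within the stratum a patient is *correct* under a tool when the given
    dichotomisation rule fires: positivity rules are paired with the
    present-stratum, negative-classification rules (``*_eq0`` / ``*_low``)
    with the absent-stratum.  Index4 is the experimental comparison and
    CARG the standard, so b counts patients correct under Index4 only.
    """
    from .scoring import dichotomize

    y = np.asarray(outcome_present, dtype=bool)
    if stratum == "outcome_present_only":
        mask = y
    elif stratum == "outcome_absent_only":
        mask = ~y
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    if not mask.any():
        raise ValueError(f"stratum {stratum!r} is empty")

    i4 = np.array([dichotomize(s, index4_rule) for s in index4_scores], dtype=bool)
    cg = np.array([dichotomize(s, carg_rule) for s in carg_scores], dtype=bool)
    i4, cg = i4[mask], cg[mask]

    d = PairedDiscordance(
        b=int(np.sum(i4 & ~cg)),
        c=int(np.sum(~i4 & cg)),
        concordant_correct=int(np.sum(i4 & cg)),
        concordant_wrong=int(np.sum(~i4 & ~cg)),
    )
    return d, mcnemar_exact(d, method=method)


# ---------------------------------------------------------------------------
# Group comparisons and cohort summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float


def group_comparison_suite(data, kind: str) -> GroupTestResult:
    """Dispatch the appropriate two-sided test for a group comparison.

    ``kind="categorical"``: ``data`` is an r x c contingency table —
    Fisher's exact test for 2x2, Pearson chi-square otherwise.
    ``kind="continuous"``: ``data`` is a sequence of per-group value
    arrays — two-sample t-test for 2 groups, one-way ANOVA for 3 or more.
    """
    if kind == "categorical":
        table = np.asarray(data, dtype=int)
        if table.ndim != 2:
            raise ValueError("contingency table must be 2-d")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("degenerate contingency table (empty row or column)")
        if table.shape == (2, 2):
            res = stats.fisher_exact(table, alternative="two-sided")
            return GroupTestResult("fisher_exact", float(res[0]), float(res[1]))
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupTestResult("chi2", float(chi2), float(p))
    if kind == "continuous":
        groups = [np.asarray(g, dtype=float) for g in data]
        if len(groups) < 2 or any(len(g) == 0 for g in groups):
            raise ValueError("need >= 2 non-empty groups")
        if len(groups) == 2:
            t, p = stats.ttest_ind(groups[0], groups[1])
            return GroupTestResult("t_test", float(t), float(p))
        f, p = stats.f_oneway(*groups)
        return GroupTestResult("anova", float(f), float(p))
    raise ValueError(f"unknown kind {kind!r}")


def cohort_summary(df: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Descriptive table of a scored cohort by risk group.

    ``df`` must hold patient attributes plus ``index4_group`` /
    ``carg_group`` columns (and optionally outcome columns).  Returns one
    row per summary line: group sizes, percentages (one decimal), mean
    (SD) age, per-group outcome rates and the matching comparison
    p-values.  Among admitted patients a mean length-of-stay comparison
    across Index4 groups is appended when the data are present.
    """
    if grouping not in ("index4", "carg"):
        raise ValueError("grouping must be 'index4' or 'carg'")
    gcol = f"{grouping}_group"
    order = ["score0", "score_ge1"] if grouping == "index4" else ["low", "intermediate", "high"]
    groups = [g for g in order if (df[gcol] == g).any()]
    rows = []

    sizes = {g: int((df[gcol] == g).sum()) for g in groups}
    rows.append(
        {"parameter": "n", "p_value": None, "test": None,
         **{g: sizes[g] for g in groups}}
    )

    if "age" in df.columns:
        by = [df.loc[df[gcol] == g, "age"].to_numpy() for g in groups]
        testable = len(groups) >= 2 and all(len(v) >= 2 for v in by)
        res = group_comparison_suite(by, "continuous") if testable else None
        rows.append(
            {"parameter": "mean_age_sd",
             **{g: f"{np.mean(v):.1f} ({np.std(v, ddof=1):.1f})" if len(v) > 1 else f"{np.mean(v):.1f}" for g, v in zip(groups, by)},
             "p_value": res.p_value if res else None,
             "test": res.test if res else None}
        )

    binary_cols = [
        c for c in ("grade34_ae", "ed_visit", "hospital_admission", "discontinued_chemo")
        if c in df.columns
    ]
    for col in binary_cols:
        counts = {g: int((df.loc[df[gcol] == g, col]).sum()) for g in groups}
        table = np.array([[counts[g], sizes[g] - counts[g]] for g in groups]).T
        res = group_comparison_suite(table, "categorical") if len(groups) >= 2 else None
        rows.append(
            {"parameter": f"{col}_rate_pct",
             **{g: percent(counts[g] / sizes[g]) for g in groups},
             "p_value": res.p_value if res else None,
             "test": res.test if res else None}
        )

    if (
        grouping == "index4"
        and "length_of_stay" in df.columns
        and "hospital_admission" in df.columns
    ):
        adm = df[df["hospital_admission"].astype(bool) & df["length_of_stay"].notna()]
        by = [adm.loc[adm[gcol] == g, "length_of_stay"].to_numpy() for g in groups]
        if all(len(v) > 1 for v in by) and len(by) == 2:
            res = group_comparison_suite(by, "continuous")
            rows.append(
                {"parameter": "mean_length_of_stay_days",
                 **{g: round(float(np.mean(v)), 1) for g, v in zip(groups, by)},
                 "p_value": res.p_value, "test": res.test}
            )

    return pd.DataFrame(rows)
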