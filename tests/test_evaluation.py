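"""Tests for confusion metrics, ROC/AUC, McNemar and group comparisons.

Each statistical routine is checked against an independent oracle:
exhaustive pair counting for the AUC, exact binomial tail enumeration for
McNemar, hypergeometric enumeration for Fisher's test, and the R pROC
package for the DeLong confidence interval.
"""

import math
import subprocess
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geritox import (
    BinaryConfusion,
    PairedDiscordance,
    confusion_from_labels,
    cohort_summary,
    diagnostic_metrics,
    group_comparison_suite,
    mcnemar_exact,
    paired_tool_comparison,
    roc_auc,
)
from geritox.evaluation import percent


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def auc_pair_counting(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive case-control pair enumeration."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if c > d else (0.5 if c == d else 0.0) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


def mcnemar_tail_enumeration(b, c) -> Fraction:
    """Central two-sided exact binomial p as an exact rational."""
    n = b + c
    tail = sum(Fraction(math.comb(n, k)) for k in range(min(b, c) + 1))
    return min(Fraction(1), 2 * tail / Fraction(2**n))


def fisher_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher p by summing hypergeometric tables as extreme as observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = math.comb(r1, a) * math.comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = math.comb(r1, x) * math.comb(r2, c1 - x) / denom
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


# ---------------------------------------------------------------------------
# confusion tables and metrics
# ---------------------------------------------------------------------------


class TestConfusion:
    def test_all_correct(self):
        c = confusion_from_labels([1, 1, 1, 0, 0], [1, 1, 1, 0, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 2)

    def test_inverted_predictions_swap_cells(self):
        y = [1, 0, 1, 0, 1]
        pred = [1, 1, 0, 0, 1]
        c = confusion_from_labels(pred, y)
        ci = confusion_from_labels([not p for p in pred], y)
        assert (ci.tp, ci.fn) == (c.fn, c.tp) and (ci.tn, ci.fp) == (c.fp, c.tn)

    def test_reference_grade34_counts(self):
        # 56 test-positive patients of whom 36 had the outcome; 61 negative of whom 31 did
        pred = [True] * 56 + [False] * 61
        y = [True] * 36 + [False] * 20 + [True] * 31 + [False] * 30
        c = confusion_from_labels(pred, y)
        assert (c.tp, c.fp, c.fn, c.tn) == (36, 20, 31, 30)

    def test_empty_and_mismatched_inputs(self):
        with pytest.raises(ValueError):
            confusion_from_labels([], [])
        with pytest.raises(ValueError):
            confusion_from_labels([1], [1, 0])


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "conf,expected",
        [
            # Index4 >= 1 and CARG-high against grade 3-4 toxicity in the published cohort
            ((36, 20, 31, 30), (53.7, 60.0, 64.3, 49.2, 56.4)),
            ((31, 9, 36, 41), (46.3, 82.0, 77.5, 53.2, 61.5)),
        ],
    )
    def test_published_metric_rows(self, conf, expected):
        m = diagnostic_metrics(BinaryConfusion(*conf)).as_percent()
        got = tuple(m[k] for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"))
        assert got == expected

    def test_perfect_classifier(self):
        m = diagnostic_metrics(BinaryConfusion(tp=5, fp=0, fn=0, tn=7))
        assert all(v == 1.0 for v in (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy))

    def test_zero_denominator_is_undefined_not_zero(self):
        m = diagnostic_metrics(BinaryConfusion(tp=0, fp=0, fn=3, tn=4))
        assert m.ppv is None and m.sensitivity == 0.0

    def test_sensitivity_complements_false_negative_fraction(self):
        c = BinaryConfusion(tp=13, fp=5, fn=7, tn=11)
        m = diagnostic_metrics(c)
        assert m.sensitivity == pytest.approx(1 - c.fn / (c.tp + c.fn))

    def test_percent_rounds_half_up(self):
        assert percent(0.56410) == 56.4
        assert percent(0.82350) == 82.4  # half-up, not banker's
        assert percent(0.005449) == 0.5


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 3, 3], [False, False, True, True]).auc == 1.0

    def test_uninformative_score(self):
        assert roc_auc([2, 2, 2, 2], [False, True, False, True]).auc == 0.5

    def test_ties_counted_half(self):
        r = roc_auc([1, 2, 2, 3], [False, False, True, True])
        assert r.auc == auc_pair_counting([1, 2, 2, 3], [False, False, True, True]) == 0.875

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [True, True, True])

    @given(st.data())
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_auc_equals_pair_counting_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=50))
        scores = data.draw(st.lists(st.integers(0, 23), min_size=n, max_size=n))
        k = data.draw(st.integers(min_value=1, max_value=n - 1))
        labels = [True] * k + [False] * (n - k)
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12
        )

    def test_roc_points_monotone(self, small_cohort):
        y = [o.grade34_ae for o in small_cohort.outcomes]
        r = roc_auc([s.total for s in small_cohort.carg], y)
        assert all(x2 >= x1 for x1, x2 in zip(r.fpr, r.fpr[1:]))
        assert all(y2 >= y1 for y1, y2 in zip(r.tpr, r.tpr[1:]))
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-12)

    def test_delong_ci_brackets_auc_and_narrows_with_n(self):
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.integers(0, 10, 40), rng.integers(5, 15, 40)])
        labels = np.array([False] * 40 + [True] * 40)
        r_small = roc_auc(scores[::4], labels[::4])
        r_big = roc_auc(scores, labels)
        for r in (r_small, r_big):
            assert r.ci_low <= r.auc <= r.ci_high
        assert (r_big.ci_high - r_big.ci_low) < (r_small.ci_high - r_small.ci_low)

    def test_delong_ci_matches_r_proc(self):
        """Cross-check AUC and DeLong CI against the independent pROC implementation."""
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.integers(0, 12, 20), rng.integers(4, 18, 15)])
        labels = [0] * 20 + [1] * 15
        r = roc_auc(scores, labels)
        rcode = (
            "suppressMessages(library(pROC));"
            f"y <- c({','.join(map(str, labels))});"
            f"s <- c({','.join(map(str, scores.tolist()))});"
            "r <- roc(y, s, quiet=TRUE, direction='<');"
            "ci <- ci.auc(r, method='delong');"
            "cat(sprintf('%.10f %.10f %.10f', ci[1], ci[2], ci[3]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        ).stdout.split()
        lo, auc, hi = map(float, out)
        assert r.auc == pytest.approx(auc, abs=1e-9)
        assert r.ci_low == pytest.approx(lo, abs=1e-6)
        assert r.ci_high == pytest.approx(hi, abs=1e-6)

    def test_bootstrap_ci_close_to_delong(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.integers(0, 10, 60), rng.integers(3, 13, 60)])
        labels = [False] * 60 + [True] * 60
        d = roc_auc(scores, labels, ci_method="delong")
        b = roc_auc(scores, labels, ci_method="bootstrap", seed=0)
        assert b.ci_low == pytest.approx(d.ci_low, abs=0.05)
        assert b.ci_high == pytest.approx(d.ci_high, abs=0.05)


class TestMcNemar:
    def test_symmetric_discordance(self):
        r = mcnemar_exact((5, 5))
        assert r.p_value == 1.0 and r.odds_ratio == 1.0

    def test_exact_tail_example(self):
        assert mcnemar_exact((8, 2)).p_value == pytest.approx(0.109375, abs=1e-12)

    def test_zero_discordance(self):
        r = mcnemar_exact((0, 0))
        assert r.p_value == 1.0 and math.isnan(r.odds_ratio)

    def test_infinite_or_when_c_zero(self):
        r = mcnemar_exact((4, 0))
        assert math.isinf(r.odds_ratio) and r.ci_low > 0

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(16, 11), (20, 4), (3, 25), (7, 7), (1, 12)]:
            table = [[0, b], [c, 0]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact((b, c)).p_value == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_swap_symmetry_and_reciprocal_or(self, b, c):
        r1, r2 = mcnemar_exact((b, c)), mcnemar_exact((c, b))
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        if b > 0 and c > 0:
            assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio)

    def test_p_decreases_with_asymmetry_at_fixed_n(self):
        ps = [mcnemar_exact((b, 20 - b)).p_value for b in range(10, 21)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_or_ci_brackets_estimate_and_widens_with_less_data(self):
        wide = mcnemar_exact((5, 1))
        narrow = mcnemar_exact((20, 4))
        for r in (wide, narrow):
            assert r.ci_low < r.odds_ratio < r.ci_high
        assert (wide.ci_high / wide.ci_low) > (narrow.ci_high / narrow.ci_low)

    def test_chi2_option(self):
        r = mcnemar_exact((30, 12), method="chi2")
        from scipy.stats import chi2

        assert r.p_value == pytest.approx(chi2.sf((abs(30 - 12) - 1) ** 2 / 42, 1))


class TestPairedComparison:
    def test_all_correct_means_no_discordance(self):
        from geritox import carg_score, index4_score
        from conftest import make_patient

        y = [True] * 5 + [False] * 3
        pos = index4_score(make_patient(albumin=30))  # total 1 -> test positive
        high = carg_score(make_patient(age=80, hemoglobin=9, sex="male",
                                       creatinine_clearance=30, falls_past_6mo=True))
        i4, cg = [pos] * 8, [high] * 8
        d, res = paired_tool_comparison("index4_ge1", "carg_high", i4, cg, y,
                                        "outcome_present_only")
        assert d.b == d.c == 0 and res.p_value == 1.0
        assert d.n_stratum == 5

    def test_swapping_tools_inverts_or(self, small_cohort):
        y = [o.grade34_ae for o in small_cohort.outcomes]
        d, res = paired_tool_comparison(
            "index4_ge1", "carg_high", small_cohort.index4, small_cohort.carg, y,
            "outcome_present_only",
        )
        swapped = mcnemar_exact((d.c, d.b))
        assert swapped.p_value == pytest.approx(res.p_value, abs=1e-12)
        if d.b and d.c:
            assert swapped.odds_ratio == pytest.approx(1 / res.odds_ratio)

    def test_discordance_partition_sums_to_stratum(self, small_cohort):
        y = [o.ed_visit for o in small_cohort.outcomes]
        d, _ = paired_tool_comparison(
            "index4_eq0", "carg_low", small_cohort.index4, small_cohort.carg, y,
            "outcome_absent_only",
        )
        assert d.n_stratum == sum(not v for v in y)

    def test_empty_stratum_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty"):
            paired_tool_comparison(
                "index4_ge1", "carg_high", small_cohort.index4, small_cohort.carg,
                [True] * len(small_cohort), "outcome_absent_only",
            )


class TestGroupComparisons:
    def test_radiation_therapy_fisher_example(self):
        # 23/61 vs 11/56 treated with radiation across the two Index4 groups
        res = group_comparison_suite([[23, 38], [11, 45]], "categorical")
        assert res.test == "fisher_exact"
        assert res.p_value == pytest.approx(0.0415, abs=5e-4)

    def test_identical_groups_p_one(self):
        assert group_comparison_suite([[10, 10], [10, 10]], "categorical").p_value == 1.0

    def test_tiny_table_enumeration(self):
        assert group_comparison_suite([[1, 0], [0, 1]], "categorical").p_value == 1.0

    def test_fisher_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 15, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            got = group_comparison_suite([[a, b], [c, d]], "categorical").p_value
            assert got == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-9)

    def test_larger_tables_use_chi2(self):
        res = group_comparison_suite([[10, 20, 30], [15, 15, 30]], "categorical")
        assert res.test == "chi2"

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            group_comparison_suite([[0, 0], [3, 4]], "categorical")

    def test_continuous_dispatch(self):
        two = group_comparison_suite([[1.0, 2, 3], [2.0, 3, 4]], "continuous")
        three = group_comparison_suite([[1.0, 2], [2.0, 3], [4.0, 5]], "continuous")
        assert two.test == "t_test" and three.test == "anova"


class TestCohortSummary:
    def test_counts_and_rates(self, small_cohort):
        df = small_cohort.to_dataframe()
        scores = small_cohort.scores_dataframe()
        merged = df.assign(index4_group=scores["index4_group"], carg_group=scores["carg_group"])
        table = cohort_summary(merged, grouping="index4")
        n_row = table[table.parameter == "n"].iloc[0]
        assert n_row["score0"] + n_row["score_ge1"] == len(small_cohort)
        g34 = table[table.parameter == "grade34_ae_rate_pct"].iloc[0]
        expect = percent(
            merged[merged.index4_group == "score0"]["grade34_ae"].mean()
        )
        assert g34["score0"] == expect

    def test_two_patient_toy_cohort(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "age": [72, 80],
                "index4_group": ["score0", "score_ge1"],
                "grade34_ae": [False, True],
            }
        )
        table = cohort_summary(df, grouping="index4")
        rates = table[table.parameter == "grade34_ae_rate_pct"].iloc[0]
        assert rates["score0"] == 0.0 and rates["score_ge1"] == 100.0

    def test_single_group_cohort_omits_other_columns(self):
        import pandas as pd

        df = pd.DataFrame({"age": [75, 76], "carg_group": ["high", "high"], "ed_visit": [True, False]})
        table = cohort_summary(df, grouping="carg")
        assert "low" not in table.columns and "high" in table.columns
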