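import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score
from statsmodels.stats.proportion import proportion_confint

from raterbench import (
    CategorySet,
    UndefinedStatistic,
    assign_credit,
    classification_metrics,
    confusion_matrix,
    credit_matrix,
    labels_to_credit,
    score_case,
    tie_aware_kappa,
    wald_interval,
    weighted_f1,
    wilson_interval,
)
from raterbench.scoring import FractionalConfusionMatrix
from tests.conftest import random_table


class TestAssignCredit:
    def test_unique_maximum_gets_full_credit(self):
        p = np.array([0.10, 0.743, 0.03, 0.03, 0.03, 0.034, 0.033])
        credit = assign_credit(p)
        assert credit[1] == 1.0 and credit.sum() == 1.0

    def test_three_way_tie_splits_equally(self):
        p = np.array([0.30, 0.30, 0.02, 0.02, 0.02, 0.30, 0.04])
        credit = assign_credit(p)
        np.testing.assert_array_equal(np.sort(credit)[-3:], [1 / 3] * 3)
        assert credit.sum() == 1.0

    def test_tolerance_merges_near_ties(self):
        p = np.array([0.3000000001, 0.3, 0.2, 0.1999999999])
        credit = assign_credit(p, tie_tolerance=1e-3)
        assert credit[0] == credit[1] == 0.5

    def test_reported_precision_mode_rounds_before_comparison(self):
        credit = assign_credit(np.array([0.3004, 0.2996, 0.2, 0.2]), decimals=2)
        assert credit[0] == credit[1] == 0.5
        # without rounding the first entry wins outright
        assert assign_credit(np.array([0.3004, 0.2996, 0.2, 0.2]))[0] == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_credit_always_sums_to_one(self, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(7))
        assert assign_credit(p).sum() == 1.0


class TestScoreCase:
    def test_unique_correct_scores_one(self):
        credit = assign_credit(np.array([0.1, 0.743, 0.157]))
        assert score_case(credit, 1) == 1.0

    def test_tied_truth_scores_half(self):
        credit = assign_credit(np.array([0.4, 0.4, 0.2]))
        assert score_case(credit, 1) == 0.5

    def test_tie_excluding_truth_scores_zero(self):
        credit = assign_credit(np.array([0.3, 0.1, 0.3, 0.3]))
        assert score_case(credit, 1) == 0.0


class TestConfusionMatrix:
    def test_tie_produces_fractional_row(self, cats):
        from raterbench import AssessmentTable

        probs = np.array(
            [
                [0.1, 0.8, 0.02, 0.02, 0.02, 0.02, 0.02],  # firm AD
                [0.45, 0.45, 0.02, 0.02, 0.02, 0.02, 0.02],  # CN/AD tie
            ]
        )
        table = AssessmentTable.from_arrays(
            ["a", "b"], ["m"], {"a": "AD", "b": "AD"}, {"m": probs}, cats
        )
        cm = confusion_matrix(table, "m")
        assert cm.cell("AD", "AD") == 1.5
        assert cm.cell("AD", "CN") == 0.5

    def test_perfect_rater_is_diagonal(self, cats):
        rng = np.random.default_rng(0)
        table = random_table(rng, 10, 1)
        # overwrite with unit mass on the truth
        probs = labels_to_credit(table.truth_labels(), cats)
        from raterbench import AssessmentTable

        table = AssessmentTable.from_arrays(
            table.subjects, ["r0"], dict(table.truth), {"r0": probs}, cats
        )
        cm = confusion_matrix(table, "r0")
        frame = cm.to_frame()
        for code in cm.truth_codes:
            assert frame.loc[code, code] == cm.row_total(code)

    def test_matches_per_case_brute_force(self, cats):
        rng = np.random.default_rng(42)
        table = random_table(rng, 10, 1, tie_rate=0.5)
        cm = confusion_matrix(table, "r0")
        # independent per-case loop oracle
        expected = {
            (t, c): 0.0 for t in cm.truth_codes for c in cats.codes
        }
        for subject, label in zip(table.subjects, table.truth_labels()):
            vec = table.rater_probs("r0")[table.subjects.index(subject)]
            top = vec.max()
            tied = [k for k in range(cats.n) if vec[k] >= top - 1e-9]
            for k in tied:
                expected[(label, cats.codes[k])] += 1 / len(tied)
        for (t, c), val in expected.items():
            assert cm.cell(t, c) == pytest.approx(val, abs=1e-12)
        assert cm.total == pytest.approx(table.n_subjects, abs=1e-9)

    def test_unknown_rater_rejected(self, cats):
        table = random_table(np.random.default_rng(1), 6, 1)
        with pytest.raises(KeyError):
            confusion_matrix(table, "nobody")


class TestIntervals:
    def test_wilson_matches_statsmodels_on_integer_counts(self):
        for successes, n in [(5, 10), (1, 38), (30, 38)]:
            lo, hi = wilson_interval(successes, n, 0.95)
            ref_lo, ref_hi = proportion_confint(successes, n, 0.05, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-10)
            assert hi == pytest.approx(ref_hi, abs=1e-10)

    def test_wilson_boundary_cases(self):
        z = norm.ppf(0.975)
        lo, hi = wilson_interval(0, 10, 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(z**2 / (10 + z**2), abs=1e-12)
        assert wilson_interval(10, 10, 0.95)[1] == 1.0

    def test_wilson_accepts_fractional_successes(self):
        lo, hi = wilson_interval(1.5, 2, 0.95)
        assert 0 <= lo < 0.75 < hi <= 1

    def test_wald_symmetric_about_estimate(self):
        lo, hi = wald_interval(19, 38, 0.95)
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=1e-12)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestClassificationMetrics:
    def test_perfect_rater_all_ones(self, cats):
        counts = np.zeros((2, 7))
        counts[0, 0] = 20  # CN row
        counts[1, 1] = 18  # AD row
        cm = FractionalConfusionMatrix(("CN", "AD"), cats.codes, counts)
        m = classification_metrics(cm, cats)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0
        assert m.weighted_f1 == 1.0

    def test_fractional_tie_counts_toward_sensitivity(self, cats):
        counts = np.zeros((1, 7))
        # 2 AD subjects: one firm AD, one CN/AD tie
        counts[0, 1] = 1.5
        counts[0, 0] = 0.5
        cm = FractionalConfusionMatrix(("AD",), cats.codes, counts)
        assert cm.row_total("AD") == 2.0
        # sensitivity = 1.5/2 via the full metric path
        counts2 = np.zeros((2, 7))
        counts2[0, 0] = 3  # CN correct
        counts2[1] = counts[0]
        cm2 = FractionalConfusionMatrix(("CN", "AD"), cats.codes, counts2)
        m = classification_metrics(cm2, cats)
        assert m.sensitivity == pytest.approx(0.75)

    def test_off_binary_mass_counts_against_everything(self, cats):
        counts = np.zeros((2, 7))
        counts[0, 0] = 2.0
        counts[1, 6] = 1.0  # AD case called DLB
        counts[1, 1] = 1.0
        cm = FractionalConfusionMatrix(("CN", "AD"), cats.codes, counts)
        m = classification_metrics(cm, cats)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.accuracy == pytest.approx(3 / 4)

    def test_ci_contains_estimate(self, cats):
        table = random_table(np.random.default_rng(3), 12, 1, tie_rate=0.4)
        cm = confusion_matrix(table, "r0")
        m = classification_metrics(cm, cats)
        for est, (lo, hi) in [
            (m.accuracy, m.accuracy_ci),
            (m.sensitivity, m.sensitivity_ci),
            (m.specificity, m.specificity_ci),
        ]:
            assert lo <= est <= hi
            assert 0 <= lo and hi <= 1


class TestWeightedF1:
    def test_worked_example(self, cats):
        counts = np.zeros((2, 7))
        counts[0, 0], counts[0, 1] = 15, 5  # CN row
        counts[1, 0], counts[1, 1] = 5, 13  # AD row
        cm = FractionalConfusionMatrix(("CN", "AD"), cats.codes, counts)
        f1_cn = 0.75
        f1_ad = 13 / 18  # precision = recall = 13/18
        expected = (20 * f1_cn + 18 * f1_ad) / 38
        assert weighted_f1(cm, cats) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7368, abs=5e-4)

    def test_all_mass_off_binary_gives_zero(self, cats):
        counts = np.zeros((2, 7))
        counts[0, 5] = 20
        counts[1, 5] = 18
        cm = FractionalConfusionMatrix(("CN", "AD"), cats.codes, counts)
        assert weighted_f1(cm, cats) == 0.0


class TestTieAwareKappa:
    def test_textbook_contingency_example(self, cats):
        a = labels_to_credit(["CN", "CN", "AD", "AD"], cats)
        b = labels_to_credit(["CN", "AD", "AD", "AD"], cats)
        # p_o = 0.75, p_e = 0.5
        assert tie_aware_kappa(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_identical_labelings_give_one(self, cats):
        a = labels_to_credit(["CN", "AD", "DLB", "CN"], cats)
        assert tie_aware_kappa(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_half_tie_contributes_half_agreement(self, cats):
        a = np.zeros((2, 7))
        a[0, [0, 1]] = 0.5  # CN/AD tie
        a[1, 0] = 1.0
        b = np.zeros((2, 7))
        b[0, 1] = 1.0
        b[1, 1] = 1.0
        p_o = np.mean(np.sum(a * b, axis=1))
        assert p_o == 0.25  # the tied case contributes 0.5, the other 0

    def test_degenerate_agreement_undefined(self, cats):
        a = labels_to_credit(["CN", "CN", "CN"], cats)
        with pytest.raises(UndefinedStatistic):
            tie_aware_kappa(a, a)

    def test_matches_sklearn_without_ties(self, cats):
        rng = np.random.default_rng(11)
        labels_a = rng.choice(["CN", "AD", "DLB"], size=40)
        labels_b = rng.choice(["CN", "AD", "DLB"], size=40)
        ours = tie_aware_kappa(
            labels_to_credit(labels_a, cats), labels_to_credit(labels_b, cats)
        )
        ref = cohen_kappa_score(labels_a, labels_b)
        assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        cats = CategorySet()
        table = random_table(rng, 8, 2, tie_rate=0.5, cats=cats)
        a = credit_matrix(table, "r0")
        b = credit_matrix(table, "r1")
        assert tie_aware_kappa(a, b) == pytest.approx(tie_aware_kappa(b, a), abs=1e-14)


class TestNoTieReduction:
    def test_metrics_equal_classical_formulas_without_ties(self, cats):
        """With unique maxima everywhere, fractional metrics collapse to the
        classical integer-count versions."""
        rng = np.random.default_rng(7)
        table = random_table(rng, 20, 1, tie_rate=0.0)
        cm = confusion_matrix(table, "r0")
        hard = [cats.codes[int(np.argmax(v))] for v in table.rater_probs("r0")]
        truth = list(table.truth_labels())
        m = classification_metrics(cm, cats)
        assert m.accuracy == pytest.approx(
            np.mean([h == t for h, t in zip(hard, truth)]), abs=1e-12
        )
        ref_f1 = f1_score(truth, hard, labels=["CN", "AD"], average="weighted")
        assert m.weighted_f1 == pytest.approx(ref_f1, abs=1e-12)
        ours_kappa = tie_aware_kappa(
            credit_matrix(table, "r0"), labels_to_credit(truth, cats)
        )
        assert ours_kappa == pytest.approx(
            cohen_kappa_score(hard, truth), abs=1e-12
        )
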