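"""Confusion-matrix construction and the weighted one-vs-all metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trisent.evaluation import (
    ConfusionMatrix3,
    UndefinedMetricError,
    accuracy,
    confusion_matrix,
    misclassification_report,
    round_percent,
    truncate_percent,
    weighted_one_vs_all,
)
from trisent.labels import CLASSES, NEGATIVE, NEUTRAL, POSITIVE
from trisent.synthetic_data import Testimony

# Reference-study matrices (rows = predicted, columns = real).
MLP_STUDENTS = ((165, 8, 2), (1, 22, 6), (6, 2, 13))
MLP_STAFF = ((70, 3, 5), (0, 22, 4), (1, 3, 32))
SVM_STUDENTS = ((160, 11, 3), (8, 18, 9), (4, 3, 9))
SVM_STAFF = ((66, 5, 11), (3, 15, 9), (2, 8, 21))

matrices3 = st.lists(st.integers(0, 40), min_size=9, max_size=9).map(
    lambda xs: ConfusionMatrix3.from_array(np.asarray(xs).reshape(3, 3))
)


class TestConfusionMatrix:
    def test_empty_input_gives_zero_matrix(self):
        assert confusion_matrix([]).total == 0

    def test_all_correct_negatives(self):
        cm = confusion_matrix([(NEGATIVE, NEGATIVE)] * 10)
        assert cm.counts[0][0] == 10
        assert cm.total == 10

    def test_marginals_match_independent_tallies(self, rng):
        labels = [CLASSES[i] for i in rng.integers(0, 3, 100)]
        preds = [CLASSES[i] for i in rng.integers(0, 3, 100)]
        cm = confusion_matrix(list(zip(preds, labels)))
        assert cm.total == 100
        for k, cls in enumerate(CLASSES):
            assert cm.array[:, k].sum() == labels.count(cls)  # real marginals
            assert cm.array[k, :].sum() == preds.count(cls)  # predicted marginals

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown sentiment label"):
            confusion_matrix([("good", NEGATIVE)])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionMatrix3.from_array([[-1, 0, 0], [0, 0, 0], [0, 0, 0]])


class TestAccuracy:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            (MLP_STUDENTS, 88.888888),
            (MLP_STAFF, 88.571428),
            (SVM_STUDENTS, 83.111111),
            (SVM_STAFF, 72.857142),
        ],
        ids=["mlp-students", "mlp-staff", "svm-students", "svm-staff"],
    )
    def test_reference_matrices(self, matrix, expected):
        assert accuracy(ConfusionMatrix3(matrix)) == pytest.approx(expected, abs=1e-4)

    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix3.from_array(np.diag([5, 5, 5]))
        assert accuracy(cm) == 100.0

    def test_empty_matrix_undefined(self):
        with pytest.raises(UndefinedMetricError):
            accuracy(ConfusionMatrix3.from_array(np.zeros((3, 3))))


class TestWeightedOneVsAll:
    @pytest.mark.parametrize(
        "matrix,expected",
        [(MLP_STUDENTS, 92.49), (MLP_STAFF, 92.59), (SVM_STUDENTS, 88.42), (SVM_STAFF, 82.55)],
        ids=["mlp-students", "mlp-staff", "svm-students", "svm-staff"],
    )
    def test_weighted_accuracy_reproduces_reference(self, matrix, expected):
        report = weighted_one_vs_all(ConfusionMatrix3(matrix))
        assert round_percent(report.weighted_accuracy) == expected

    def test_collapsed_tables_each_sum_to_n(self):
        cm = ConfusionMatrix3(SVM_STAFF)
        report = weighted_one_vs_all(cm)
        for m in report.per_class:
            assert m.tp + m.fp + m.fn + m.tn == cm.total

    def test_zero_predicted_class_warns_and_zeroes_precision(self):
        cm = ConfusionMatrix3.from_array([[3, 1, 0], [0, 0, 0], [0, 1, 2]])
        with pytest.warns(UserWarning, match="neutral"):
            report = weighted_one_vs_all(cm)
        neutral = report.per_class[1]
        assert neutral.precision == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(matrices3)
    def test_support_weighted_recall_equals_accuracy(self, cm):
        """Weighted recall == trace/total: an identity, on every matrix."""
        if cm.total == 0:
            return
        report = weighted_one_vs_all(cm)
        assert report.weighted_recall == pytest.approx(accuracy(cm), abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(matrices3)
    def test_weighted_accuracy_transpose_invariant_with_pinned_supports(self, cm):
        """Per-class one-vs-all accuracy only swaps FP and FN under
        transposition, so with the support weights pinned to the dataset's
        class sizes the weighted accuracy is unchanged."""
        if cm.total == 0:
            return
        supports = cm.supports
        if (supports == 0).any():
            supports = supports + 1  # keep weights well-defined
        a = weighted_one_vs_all(cm, supports=supports)
        b = weighted_one_vs_all(cm.transpose(), supports=supports)
        assert a.weighted_accuracy == pytest.approx(b.weighted_accuracy, abs=1e-9)


class TestMisclassificationReport:
    @staticmethod
    def _corpus():
        return [
            Testimony(id=f"t{i}", text="some text", country="Spain", role="staff", gold=g)
            for i, g in enumerate([NEGATIVE, NEUTRAL, POSITIVE, NEGATIVE])
        ]

    def test_all_correct_is_empty(self):
        corpus = self._corpus()
        report = misclassification_report(corpus, [t.gold for t in corpus])
        assert len(report) == 0

    def test_planted_error_lands_in_matching_cell(self):
        corpus = self._corpus()
        preds = [t.gold for t in corpus]
        preds[2] = NEGATIVE  # gold positive -> predicted negative
        report = misclassification_report(corpus, preds)
        assert len(report) == 1
        cells = report.by_cell()
        assert list(cells) == [(POSITIVE, NEGATIVE)]
        assert cells[(POSITIVE, NEGATIVE)][0].id == "t2"

    def test_entry_count_complements_matrix_trace(self, rng):
        corpus = [
            Testimony(id=f"t{i}", text="x y", country="C", role="student", gold=CLASSES[g])
            for i, g in enumerate(rng.integers(0, 3, 60))
        ]
        preds = [CLASSES[i] for i in rng.integers(0, 3, 60)]
        report = misclassification_report(corpus, preds)
        cm = confusion_matrix([(p, t.gold) for p, t in zip(preds, corpus)])
        assert len(report) == cm.total - int(np.trace(cm.array))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="predictions"):
            misclassification_report(self._corpus(), [NEGATIVE])


def test_display_rounding_conventions():
    assert round_percent(88.888888) == 88.89
    assert truncate_percent(88.888888) == 88.88
    assert round_percent(72.857142) == 72.86
    assert truncate_percent(72.857142) == 72.85
    assert round_percent(0.125) == 0.13  # exact half goes up
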