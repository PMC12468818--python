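"""Confusion-matrix metrics, including the published worked examples."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from painspeech.metrics import (
    ConfusionMatrix,
    confusion_matrix,
    metrics_report,
    parse_report,
    render_report,
)

# published evaluation counts for the three tasks (rows = true class)
PAIN_CM = np.array([[740, 94], [130, 424]])
THERMAL_CM = np.array([[534, 124], [62, 689]])
INTENSITY_CM = np.array([[757, 61, 16], [112, 189, 33], [56, 64, 100]])


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_matrix(["a", "b", "a"], ["a", "b", "a"], ("a", "b"))
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_hand_counted_example(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], ("neg", "pos"))
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_count_conservation(self, rng):
        y = rng.integers(0, 3, size=50)
        p = rng.integers(0, 3, size=50)
        cm = confusion_matrix(y, p, ("a", "b", "c"))
        assert cm.total == 50

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            confusion_matrix(["a", "x"], ["a", "a"], ("a", "b"))


@pytest.fixture(scope="module")
def pain_report():
    return metrics_report(ConfusionMatrix(PAIN_CM, ("non-pain", "pain")))


@pytest.fixture(scope="module")
def thermal_report():
    return metrics_report(ConfusionMatrix(THERMAL_CM, ("cold", "warm")))


@pytest.fixture(scope="module")
def intensity_report():
    return metrics_report(
        ConfusionMatrix(INTENSITY_CM, ("mild", "moderate", "severe"))
    )


class TestPainBinaryReport:
    """Binary pain task: 740 correct non-pain, 424 correct pain,
    94 false alarms, 130 misses."""

    @pytest.mark.parametrize(
        "field,value",
        [
            ("precision", (0.8506, 0.8185)),
            ("recall", (0.8873, 0.7653)),
            ("f1", (0.8685, 0.7910)),
        ],
    )
    def test_class_metrics(self, pain_report, field, value):
        report = pain_report
        np.testing.assert_allclose(np.round(getattr(report, field), 4), value)

    def test_aggregates(self, pain_report):
        report = pain_report
        assert round(report.accuracy, 4) == 0.8386
        assert round(report.macro_precision, 4) == 0.8346
        assert round(report.macro_recall, 4) == 0.8263
        assert round(report.macro_f1, 4) == 0.8298
        assert round(report.weighted_precision, 4) == 0.8378
        assert round(report.weighted_recall, 4) == 0.8386
        assert round(report.weighted_f1, 4) == 0.8376


class TestThermalReport:
    def test_published_values(self, thermal_report):
        report = thermal_report
        assert round(report.precision[0], 4) == 0.8960
        assert round(report.recall[0], 4) == 0.8116
        assert round(report.f1[0], 4) == 0.8517
        assert round(report.precision[1], 4) == 0.8475
        assert round(report.recall[1], 4) == 0.9174
        assert round(report.f1[1], 4) == 0.8811
        assert round(report.macro_f1, 4) == 0.8664
        assert round(report.accuracy, 4) == 0.8680


class TestIntensityReport:
    def test_published_values(self, intensity_report):
        report = intensity_report
        assert round(report.precision[0], 4) == 0.8184
        assert round(report.recall[0], 4) == 0.9077
        assert round(report.f1[0], 4) == 0.8607
        assert round(report.f1[1], 4) == 0.5833
        assert round(report.f1[2], 4) == 0.5420
        assert round(report.macro_f1, 4) == 0.6620
        assert round(report.weighted_f1, 4) == 0.7435
        assert round(report.accuracy, 4) == 0.7536


class TestProperties:
    def test_perfect_classifier_all_ones(self):
        report = metrics_report(ConfusionMatrix(np.eye(2, dtype=int) * 5, ("a", "b")))
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(report.f1, [1.0, 1.0])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_weighted_recall_equals_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(3, 3))
        counts[0, 0] += 1  # non-empty
        report = metrics_report(ConfusionMatrix(counts, ("a", "b", "c")))
        assert report.weighted_recall == pytest.approx(report.accuracy, abs=1e-12)

    def test_macro_f1_bounded_by_class_f1(self, rng):
        counts = rng.integers(1, 50, size=(3, 3))
        report = metrics_report(ConfusionMatrix(counts, ("a", "b", "c")))
        assert report.f1.min() - 1e-12 <= report.macro_f1 <= report.f1.max() + 1e-12

    def test_label_permutation_consistency(self, rng):
        counts = rng.integers(1, 50, size=(3, 3))
        perm = np.array([2, 0, 1])
        r1 = metrics_report(ConfusionMatrix(counts, ("a", "b", "c")))
        r2 = metrics_report(
            ConfusionMatrix(counts[np.ix_(perm, perm)], ("c", "a", "b"))
        )
        np.testing.assert_allclose(r1.precision[perm], r2.precision, atol=1e-12)
        np.testing.assert_allclose(r1.recall[perm], r2.recall, atol=1e-12)
        assert r1.accuracy == pytest.approx(r2.accuracy)

    def test_agreement_with_sklearn(self, rng):
        """Independent cross-check of every metric on random label vectors."""
        from sklearn.metrics import accuracy_score, precision_recall_fscore_support

        for _ in range(100):
            y = rng.integers(0, 3, size=40)
            p = rng.integers(0, 3, size=40)
            while len(set(p)) < 3:
                p = rng.integers(0, 3, size=40)
            report = metrics_report(confusion_matrix(y, p, ("a", "b", "c")))
            prec, rec, f1, support = precision_recall_fscore_support(
                y, p, labels=[0, 1, 2], zero_division=0
            )
            np.testing.assert_allclose(report.precision, prec, atol=1e-12)
            np.testing.assert_allclose(report.recall, rec, atol=1e-12)
            np.testing.assert_allclose(report.f1, f1, atol=1e-12)
            assert report.accuracy == pytest.approx(accuracy_score(y, p), abs=1e-12)

    def test_never_predicted_class_warns(self):
        counts = np.array([[5, 0], [3, 0]])
        with pytest.warns(UserWarning, match="never predicted"):
            report = metrics_report(ConfusionMatrix(counts, ("a", "b")))
        assert report.precision[1] == 0.0


class TestRendering:
    def test_accuracy_cell_formatting(self):
        report = metrics_report(ConfusionMatrix(PAIN_CM, ("non-pain", "pain")))
        text = render_report(report)
        assert "0.8386" in text.splitlines()[-1]

    def test_render_parse_round_trip(self):
        report = metrics_report(ConfusionMatrix(THERMAL_CM, ("cold", "warm")))
        text = render_report(report)
        parsed = parse_report(text)
        assert parsed["accuracy"] == round(report.accuracy, 4)
        assert parsed["classes"]["cold"]["precision"] == round(report.precision[0], 4)
        assert parsed["macro_avg"]["f1"] == round(report.macro_f1, 4)
        # a second render of the same report is a fixed point
        assert render_report(report) == text

    def test_symmetric_report_identical_class_rows(self):
        counts = np.array([[10, 2], [2, 10]])
        text = render_report(metrics_report(ConfusionMatrix(counts, ("x", "y"))))
        rows = text.splitlines()[1:3]
        assert rows[0].split()[1:] == rows[1].split()[1:]
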