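"""Metric arithmetic, proportion confidence intervals, ROC vs the
all-pairs oracle, and timing."""

import math

import numpy as np
import pytest

import hbscreen as hb
from hbscreen.classify import PredictionRecord
from hbscreen.errors import ClockError, ParameterError
from oracles import auc_all_pairs


def records_from_counts(tp, fn, fp, tn):
    """Expand confusion counts into individual prediction records."""
    recs = []
    recs += [PredictionRecord(i, "thalassaemia", "thalassaemia", 0.9)
             for i in range(tp)]
    recs += [PredictionRecord(1000 + i, "thalassaemia", "normal", 0.1)
             for i in range(fn)]
    recs += [PredictionRecord(2000 + i, "normal", "thalassaemia", 0.9)
             for i in range(fp)]
    recs += [PredictionRecord(3000 + i, "normal", "normal", 0.1)
             for i in range(tn)]
    return recs


class TestConfusion:
    def test_all_correct(self):
        cm = hb.confusion(records_from_counts(3, 0, 0, 4))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 0, 0, 4)

    def test_best_model_counts(self):
        """15 of 262 carrier lanes and 7 of 262 normal lanes
        misclassified gives the reference confusion matrix."""
        cm = hb.confusion(records_from_counts(247, 15, 7, 255))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (247, 15, 7, 255)
        assert cm.total == 524

    def test_swapping_positive_class_swaps_roles(self):
        recs = records_from_counts(5, 2, 3, 7)
        cm_t = hb.confusion(recs, positive="thalassaemia")
        cm_n = hb.confusion(recs, positive="normal")
        assert (cm_n.tp, cm_n.tn, cm_n.fp, cm_n.fn) == (
            cm_t.tn, cm_t.tp, cm_t.fn, cm_t.fp
        )

    def test_empty_or_unknown_rejected(self):
        with pytest.raises(ParameterError):
            hb.confusion([])
        with pytest.raises(ParameterError):
            hb.confusion(records_from_counts(1, 0, 0, 1), positive="severe")


class TestMetrics:
    def test_reference_confusion_matrix_metrics(self):
        m = hb.metrics(hb.ConfusionMatrix(tp=247, tn=255, fp=7, fn=15))
        assert m["accuracy"] == pytest.approx(95.80, abs=0.005)
        assert m["macro"]["precision"] == pytest.approx(95.84, abs=0.005)
        assert m["macro"]["recall"] == pytest.approx(95.80, abs=0.005)
        assert m["macro"]["f1"] == pytest.approx(95.80, abs=0.005)
        assert m["macro"]["specificity"] == pytest.approx(95.80, abs=0.005)

    def test_perfect_classifier_all_100(self):
        m = hb.metrics(hb.ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert m["accuracy"] == 100.0
        assert all(v == 100.0 for v in m["macro"].values())

    def test_macro_invariant_to_class_relabeling(self):
        cm = hb.ConfusionMatrix(tp=40, tn=55, fp=5, fn=10)
        m1, m2 = hb.metrics(cm), hb.metrics(cm.swapped())
        assert m1["macro"] == m2["macro"]
        assert m1["accuracy"] == m2["accuracy"]

    def test_zero_denominator_marks_undefined(self):
        m = hb.metrics(hb.ConfusionMatrix(tp=0, tn=5, fp=0, fn=5))
        assert math.isnan(m["positive"]["precision"])
        assert not math.isnan(m["accuracy"])


class TestConfidenceInterval:
    @pytest.mark.parametrize(
        "metric,n,expected",
        [(95.80, 524, 1.72), (95.80, 262, 2.43), (95.84, 262, 2.42)],
    )
    def test_reference_half_widths(self, metric, n, expected):
        assert hb.confidence_interval(metric, n) == pytest.approx(
            expected, abs=0.005
        )

    def test_boundaries_have_zero_width(self):
        assert hb.confidence_interval(100.0, 50) == 0.0
        assert hb.confidence_interval(0.0, 50) == 0.0

    def test_decreasing_in_n_and_maximal_at_50(self):
        widths = [hb.confidence_interval(80.0, n) for n in (10, 50, 500)]
        assert widths[0] > widths[1] > widths[2]
        at_50 = hb.confidence_interval(50.0, 100)
        for m in (10.0, 30.0, 70.0, 95.0):
            assert hb.confidence_interval(m, 100) < at_50

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            hb.confidence_interval(50.0, 0)
        with pytest.raises(ParameterError):
            hb.confidence_interval(120.0, 10)

    def test_metric_report_uses_pooled_and_per_class_n(self):
        rows = hb.metric_report(hb.ConfusionMatrix(tp=247, tn=255,
                                                   fp=7, fn=15))
        by_name = {r.name: r for r in rows}
        assert by_name["accuracy"].n == 524
        assert by_name["precision"].n == 262
        assert by_name["accuracy"].half_width == pytest.approx(1.72,
                                                               abs=0.005)
        assert by_name["recall"].half_width == pytest.approx(2.43,
                                                             abs=0.005)
        assert by_name["precision"].half_width == pytest.approx(2.42,
                                                                abs=0.005)


class TestROC:
    def _records(self, ys, scores):
        return [
            PredictionRecord(i, "thalassaemia" if y else "normal",
                             "thalassaemia" if s > 0.5 else "normal", s)
            for i, (y, s) in enumerate(zip(ys, scores))
        ]

    def test_perfect_separation_auc_1(self):
        recs = self._records([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert hb.roc_auc(recs).auc == pytest.approx(1.0)

    def test_constant_scores_auc_half(self):
        recs = self._records([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert hb.roc_auc(recs).auc == pytest.approx(0.5)

    def test_hand_example_matches_all_pairs_oracle(self):
        ys = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.6, 0.4, 0.6, 0.3, 0.1]
        curve = hb.roc_auc(self._records(ys, scores))
        assert curve.auc == pytest.approx(auc_all_pairs(ys, scores))

    @pytest.mark.parametrize("seed", range(12))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        ys = rng.integers(0, 2, n)
        if ys.all() or not ys.any():
            ys[0] = 1 - ys[0]
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        curve = hb.roc_auc(self._records(ys, scores))
        assert curve.auc == pytest.approx(auc_all_pairs(ys, scores))
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            hb.roc_auc(self._records([1, 1], [0.9, 0.8]))

    def test_fold_averaging_on_fixed_grid(self):
        folds = [
            self._records([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]),
            self._records([1, 0, 1, 0], [0.7, 0.4, 0.9, 0.2]),
        ]
        mean = hb.average_roc(folds)
        assert len(mean.fpr) == 101
        assert mean.tpr[0] == 0.0 and mean.tpr[-1] == 1.0
        assert 0.5 <= mean.auc <= 1.0


class TestTiming:
    def test_per_image_share(self):
        assert hb.elapsed_per_image(0.0, 10.0, 10) == 1.0
        assert hb.elapsed_per_image(5.0, 5.0, 3) == 0.0

    def test_additive_over_batches(self):
        total = hb.elapsed_per_image(0.0, 6.0, 3) * 3 + \
            hb.elapsed_per_image(0.0, 4.0, 2) * 2
        assert total == pytest.approx(10.0)

    def test_negative_span_rejected(self):
        with pytest.raises(ClockError):
            hb.elapsed_per_image(2.0, 1.0, 1)
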