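import json
from dataclasses import dataclass

import numpy as np
import pytest

import gaitmode as gm
from gaitmode.evaluation import PipelineConfig


@dataclass(frozen=True)
class FakeTrial:
    subject_id: int
    trial_id: int


class TestLoocvSplit:
    def test_ten_trials_ten_folds(self):
        trials = [FakeTrial(0, i) for i in range(10)]
        folds = gm.loocv_split(trials)
        assert len(folds) == 10
        assert all(len(f.train) == 9 for f in folds)

    def test_two_trials_two_folds(self):
        folds = gm.loocv_split([FakeTrial(0, 0), FakeTrial(0, 1)])
        assert len(folds) == 2

    def test_partition_property(self):
        trials = [FakeTrial(s, t) for s in range(2) for t in range(4)]
        folds = gm.loocv_split(trials)
        tests = [(f.subject_id, f.test_trial_id) for f in folds]
        assert sorted(tests) == sorted((t.subject_id, t.trial_id) for t in trials)
        for f in folds:
            assert all(tr.subject_id == f.subject_id for tr in f.train)
            assert f.test not in f.train

    def test_single_trial_subject_rejected(self):
        with pytest.raises(ValueError):
            gm.loocv_split([FakeTrial(0, 0)])


class TestConfusionMatrix:
    def test_hand_counted(self):
        cm = gm.confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_perfect_predictions_diagonal(self):
        cm = gm.confusion_matrix(["A", "B", "B"], ["A", "B", "B"], ["A", "B"])
        assert np.trace(cm.counts) == cm.counts.sum()

    def test_empty_zero_matrix(self):
        cm = gm.confusion_matrix([], [], ["A", "B"])
        assert not cm.counts.any()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            gm.confusion_matrix(["C"], ["A"], ["A", "B"])


class TestMetrics:
    def test_hand_computed_metrics(self):
        cm = gm.confusion_matrix(
            ["A", "A", "B", "B"], ["A", "A", "A", "B"], ["A", "B"]
        )
        np.testing.assert_array_equal(cm.counts, [[2, 0], [1, 1]])
        assert gm.aggregate_accuracy(cm) == 0.75
        metrics = gm.precision_recall_f1(cm)
        assert metrics["A"]["precision"] == pytest.approx(2 / 3)
        assert metrics["A"]["recall"] == 1.0
        assert metrics["A"]["f1"] == pytest.approx(0.8)

    def test_diagonal_all_ones(self):
        cm = gm.confusion_matrix(["A", "B"], ["A", "B"], ["A", "B"])
        metrics = gm.precision_recall_f1(cm)
        assert all(m["f1"] == 1.0 for m in metrics.values())
        assert gm.aggregate_accuracy(cm) == 1.0

    def test_f1_harmonic_mean(self):
        # precision 1.0, recall 0.5 -> F1 = 2/3
        cm = gm.confusion_matrix(
            ["A", "A", "B"], ["A", "B", "B"], ["A", "B"]
        )
        assert gm.precision_recall_f1(cm)["A"]["f1"] == pytest.approx(2 / 3)

    def test_zero_denominator_flagged(self):
        cm = gm.confusion_matrix(["A", "A"], ["A", "A"], ["A", "B"])
        metrics = gm.precision_recall_f1(cm)
        assert metrics["B"]["precision"] == 0.0
        assert metrics["B"].get("undefined") is True

    def test_empty_matrix_rejected(self):
        cm = gm.confusion_matrix([], [], ["A", "B"])
        with pytest.raises(ValueError):
            gm.aggregate_accuracy(cm)

    def test_recall_equals_row_normalized_diagonal(self):
        rng = np.random.default_rng(0)
        classes = ["x", "y", "z"]
        actual = rng.choice(classes, 200)
        predicted = rng.choice(classes, 200)
        cm = gm.confusion_matrix(actual, predicted, classes)
        metrics = gm.precision_recall_f1(cm)
        row_norm = cm.counts / cm.counts.sum(axis=1, keepdims=True)
        for i, c in enumerate(classes):
            assert metrics[c]["recall"] == pytest.approx(row_norm[i, i])

    def test_micro_accuracy_identity(self):
        """accuracy = sum(recall_i * n_i) / N for random confusion matrices."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 20, size=(3, 3))
            counts[0, 0] += 1  # ensure non-empty
            cm = gm.ConfusionMatrix(("a", "b", "c"), counts)
            metrics = gm.precision_recall_f1(cm)
            rows = counts.sum(axis=1)
            expected = sum(
                metrics[c]["recall"] * rows[i] for i, c in enumerate(cm.classes)
            ) / counts.sum()
            assert gm.aggregate_accuracy(cm) == pytest.approx(expected)

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        classes = ["a", "b", "c"]
        actual = list(rng.choice(classes, 150))
        predicted = list(rng.choice(classes, 150))
        cm = gm.confusion_matrix(actual, predicted, classes)
        ours = gm.precision_recall_f1(cm)
        p, r, f, _ = sk.precision_recall_fscore_support(
            actual, predicted, labels=classes, zero_division=0
        )
        for i, c in enumerate(classes):
            assert ours[c]["precision"] == pytest.approx(p[i])
            assert ours[c]["recall"] == pytest.approx(r[i])
            assert ours[c]["f1"] == pytest.approx(f[i])
        assert gm.aggregate_accuracy(cm) == pytest.approx(
            sk.accuracy_score(actual, predicted)
        )


@pytest.fixture(scope="module")
def tiny_report():
    """A fast single-subject experiment for report-shape checks."""
    cfg = gm.SimulationConfig(
        seed=9,
        n_subjects=1,
        n_trials_per_subject=2,
        mode_sequence=["W", "W", "RA2", "RA2", "W", "RD2", "RD2", "W", "ST"],
    )
    dataset = gm.generate_dataset(cfg)
    pipe = PipelineConfig(seed=9, max_epochs=25, early_stop_patience=8)
    return gm.run_experiment(dataset, pipe)


class TestRunExperiment:
    def test_report_shape(self, tiny_report):
        d = tiny_report.to_dict()
        assert tiny_report.n_folds == 2
        for fam, offs in d["transition_accuracy"].items():
            assert set(offs) == {"350", "250", "150", "50"}
        assert set(d["event_recall"]) == {"FC", "TO"}

    def test_accuracies_in_unit_interval(self, tiny_report):
        for offs in tiny_report.transition_accuracy.values():
            for vals in offs.values():
                assert 0.0 <= vals["accuracy"] <= 1.0

    def test_report_serializable(self, tiny_report):
        text = json.dumps(tiny_report.to_dict(), sort_keys=True)
        assert "transition_accuracy" in text

    def test_single_model_mode(self):
        """One shared 19-class classifier instead of three family models."""
        cfg = gm.SimulationConfig(
            seed=9,
            n_subjects=1,
            n_trials_per_subject=2,
            mode_sequence=["W", "W", "RA2", "RA2", "W", "RD2", "RD2", "W", "ST"],
        )
        pipe = PipelineConfig(
            seed=9, max_epochs=25, early_stop_patience=8, single_model=True
        )
        rep = gm.run_experiment(gm.generate_dataset(cfg), pipe)
        for cm in rep.confusions.values():
            assert cm.classes == gm.TRANSITIONS
        for offs in rep.transition_accuracy.values():
            for vals in offs.values():
                assert 0.0 <= vals["accuracy"] <= 1.0
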