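"""Metrics: confusion tables, max-F1 sweep, AUC-ROC, benchmark summaries."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from gibbonpam import (
    auc_one_vs_all,
    auc_roc,
    confusion_metrics,
    evaluate_scores,
    max_f1_sweep,
    run_benchmark,
)
from gibbonpam.evaluate import SWEEP_THRESHOLDS, benchmark_grid


def brute_force_confusion(scores, labels, thr):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= thr
        if pred and y:
            tp += 1
        elif pred:
            fp += 1
        elif y:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def all_pairs_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0], 0.5)
        assert (m.precision, m.recall, m.f1, m.fpr) == (1.0, 1.0, 1.0, 0.0)

    def test_precision_from_deployment_counts(self):
        # 2761 verified true of 3046 detections
        scores = [1.0] * 3046
        labels = [1] * 2761 + [0] * 285
        m = confusion_metrics(scores, labels, 0.9)
        assert m.precision == pytest.approx(2761 / 3046)
        assert m.precision == pytest.approx(0.906, abs=5e-4)

    def test_random_case_matches_brute_force(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        for thr in (0.2, 0.5, 0.8):
            m = confusion_metrics(scores, labels, thr)
            assert (m.tp, m.fp, m.tn, m.fn) == brute_force_confusion(scores, labels, thr)

    def test_degenerate_zero_over_zero_flagged(self):
        m = confusion_metrics([0.1, 0.2], [0, 1], 0.9)  # nothing predicted positive
        assert m.precision == 0.0 and m.degenerate

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [], 0.5)

    def test_recall_times_positives_is_tp(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        m = confusion_metrics(scores, labels, 0.4)
        assert m.recall * labels.sum() == pytest.approx(m.tp)


class TestMaxF1Sweep:
    def test_separable_scores_reach_f1_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        max_f1, best_thr, table = max_f1_sweep(scores, labels)
        assert max_f1 == 1.0
        assert best_thr == 0.3  # lowest separating threshold on the grid
        assert len(table) == 10

    def test_constant_scores_tie_break_to_lowest(self):
        scores = [0.5] * 6
        labels = [1, 0, 1, 0, 1, 0]
        max_f1, best_thr, _ = max_f1_sweep(scores, labels)
        assert best_thr == 0.1
        assert max_f1 == pytest.approx(2 * 3 / (6 + 3))  # all predicted positive

    def test_matches_grid_maximum_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            max_f1, _, _ = max_f1_sweep(scores, labels)
            brute = max(
                confusion_metrics(scores, labels, t).f1 for t in SWEEP_THRESHOLDS
            )
            assert max_f1 == pytest.approx(brute)

    def test_coarse_grid_never_beats_dense_sweep(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=80)
        labels = rng.integers(0, 2, size=80)
        coarse, _, _ = max_f1_sweep(scores, labels)
        dense = max(confusion_metrics(scores, labels, t).f1 for t in np.linspace(0.001, 1, 1000))
        assert coarse <= dense + 1e-12


class TestAucRoc:
    def test_perfect_and_antiperfect_ranking(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc_roc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            scores = np.round(rng.uniform(size=20), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                continue
            assert auc_roc(scores, labels) == pytest.approx(all_pairs_auc(scores, labels))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, size=200)
        assert auc_roc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        assert auc_roc(scores, labels) == pytest.approx(auc_roc(np.exp(3 * scores), labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.9], [1, 1])


class TestAucOneVsAll:
    def test_one_hot_predictions_give_auc_one(self):
        names = ["a", "b", "c"]
        labels = ["a", "b", "c", "a"]
        probs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        out = auc_one_vs_all(probs, labels, names)
        assert all(out[n] == 1.0 for n in names)

    def test_uniform_probabilities_are_chance(self):
        names = ["a", "b", "c"]
        labels = ["a", "b", "c", "b"]
        probs = np.full((4, 3), 1 / 3)
        out = auc_one_vs_all(probs, labels, names)
        assert all(v == pytest.approx(0.5) for v in out.values())

    def test_reduces_to_binary_auc_per_class(self):
        rng = np.random.default_rng(7)
        names = ["x", "y", "z"]
        raw = rng.uniform(size=(30, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.choice(names, size=30)
        out = auc_one_vs_all(probs, labels, names)
        for j, n in enumerate(names):
            assert out[n] == pytest.approx(auc_roc(probs[:, j], (labels == n).astype(int)))

    def test_absent_class_is_nan_not_error(self):
        probs = np.array([[0.6, 0.4], [0.3, 0.7]])
        out = auc_one_vs_all(probs, ["a", "a"], ["a", "b"])
        assert np.isnan(out["a"]) and np.isnan(out["b"])


class TestEvaluateScores:
    def test_report_internally_consistent(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, size=100)
        rep = evaluate_scores(scores, labels)
        assert rep.max_f1 == max(rep.f1)
        assert rep.thresholds[rep.f1.index(rep.max_f1)] == rep.best_threshold
        tp, fp, tn, fn = rep.confusion_at_best
        assert tp + fp + tn + fn == 100


class TestRunBenchmark:
    def test_identical_seeds_give_zero_se(self):
        cells = [{"architecture": "alexnet", "epochs": 1}]
        summary = run_benchmark(cells, lambda cell, seed: {"f1": 0.8}, replicates=3, seeds=[1, 1, 1])
        assert (summary.table["se"].abs() < 1e-12).all()

    def test_se_is_sd_over_sqrt_n(self):
        vals = {1: 0.7, 2: 0.8, 3: 0.9}
        summary = run_benchmark(
            [{"cfg": "x"}], lambda cell, seed: {"f1": vals[seed]}, replicates=3, seeds=[1, 2, 3]
        )
        expected = np.std([0.7, 0.8, 0.9], ddof=1) / np.sqrt(3)
        assert summary.table.loc[0, "se"] == pytest.approx(expected)
        assert summary.table.loc[0, "mean"] == pytest.approx(0.8)

    def test_grid_bookkeeping(self):
        cells = benchmark_grid(architectures=("alexnet", "resnet50"), epochs=(1, 5), fine_tune=(True,))
        summary = run_benchmark(cells, lambda cell, seed: {"f1": 0.5}, replicates=1, seeds=[0])
        assert len(summary.table) == 4  # 2 archs x 2 epoch values x 1 metric

    def test_failures_recorded_not_dropped(self):
        def run_fn(cell, seed):
            if cell["bad"]:
                raise RuntimeError("boom")
            return {"f1": 1.0}

        summary = run_benchmark(
            [{"bad": True}, {"bad": False}], run_fn, replicates=1, seeds=[0]
        )
        assert len(summary.failures) == 1
        assert len(summary.table) == 1


class TestExternalScores:
    def test_csv_scores_feed_the_same_harness(self, tmp_path):
        import pandas as pd

        from gibbonpam.evaluate import read_scores_csv

        df = pd.DataFrame(
            {"window": ["w0", "w1", "w2", "w3"], "label": [1, 1, 0, 0], "score": [0.9, 0.8, 0.2, 0.1]}
        )
        df.to_csv(tmp_path / "s.csv", index=False)
        scores, labels, windows = read_scores_csv(tmp_path / "s.csv")
        assert auc_roc(scores, labels) == 1.0
        assert max_f1_sweep(scores, labels)[0] == 1.0

    def test_missing_columns_rejected(self, tmp_path):
        import pandas as pd

        pd.DataFrame({"a": [1]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="columns"):
            from gibbonpam.evaluate import read_scores_csv

            read_scores_csv(tmp_path / "bad.csv")
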