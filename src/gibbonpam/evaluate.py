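"""Detector evaluation: confusion metrics, max-F1 threshold sweep, AUC-ROC
(binary and one-vs-all), FPR, and replicate benchmark summaries.

Maximum F1 is taken over the fixed ten-threshold grid 0.1, 0.2, ..., 1.0
(ties broken toward the lowest threshold). AUC-ROC is computed as the
Mann-Whitney probability that a random positive outranks a random negative,
with ties counted one half — exactly the rank formulation, so it is invariant
under any strictly monotone rescaling of the scores. Degenerate 0/0 ratios
(e.g. no predicted positives at threshold 1.0) are reported as 0 with a flag
so sweeps never crash at extreme thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SWEEP_THRESHOLDS",
    "ConfusionMetrics",
    "EvalReport",
    "BenchmarkSummary",
    "confusion_metrics",
    "max_f1_sweep",
    "auc_roc",
    "auc_one_vs_all",
    "evaluate_scores",
    "run_benchmark",
]

SWEEP_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


@dataclass
class ConfusionMetrics:
    precision: float
    recall: float
    f1: float
    fpr: float
    tp: int
    fp: int
    tn: int
    fn: int
    degenerate: bool = False  # some 0/0 ratio was defined as 0


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def confusion_metrics(scores, labels, threshold: float) -> ConfusionMetrics:
    """Standard confusion-table metrics at one threshold (predict positive
    when score >= threshold). FPR = 1 - specificity = FP / (FP + TN)."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = ratio(2 * precision * recall, precision + recall) if (precision + recall) else 0.0
    if precision + recall == 0:
        degenerate = True
    fpr = ratio(fp, fp + tn)
    return ConfusionMetrics(precision, recall, f1, fpr, tp, fp, tn, fn, degenerate)


def max_f1_sweep(scores, labels, thresholds=SWEEP_THRESHOLDS):
    """Maximum F1 over the threshold grid.

    Returns ``(max_f1, best_threshold, table)`` where the table holds
    precision/recall/F1/FPR per threshold in threshold order; F1 ties go to
    the lowest threshold.
    """
    scores, labels = _validate(scores, labels)
    rows = []
    for thr in thresholds:
        m = confusion_metrics(scores, labels, thr)
        rows.append(
            {"threshold": thr, "precision": m.precision, "recall": m.recall, "f1": m.f1, "fpr": m.fpr}
        )
    table = pd.DataFrame(rows)
    best_idx = int(table["f1"].to_numpy().argmax())  # argmax takes the first = lowest threshold
    return float(table.loc[best_idx, "f1"]), float(table.loc[best_idx, "threshold"]), table


def auc_roc(scores, labels) -> float:
    """AUC-ROC via the Mann-Whitney rank statistic (ties count one half)."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_one_vs_all(class_scores, labels, class_names) -> dict:
    """Per-class AUC: each class's probability column against membership.

    ``class_scores`` rows are probability vectors over ``class_names``.
    A class absent from (or covering all of) ``labels`` gets ``nan`` rather
    than raising.
    """
    probs = np.asarray(class_scores, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim != 2 or probs.shape[1] != len(class_names):
        raise ValueError("class_scores must be (n_samples, n_classes)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of class_scores must sum to 1")
    out = {}
    for j, name in enumerate(class_names):
        member = (labels == name).astype(int)
        if member.sum() in (0, len(member)):
            out[name] = float("nan")
        else:
            out[name] = auc_roc(probs[:, j], member)
    return out


@dataclass
class EvalReport:
    thresholds: list
    precision: list
    recall: list
    f1: list
    max_f1: float
    best_threshold: float
    auc_roc: float
    fpr_at_best: float
    confusion_at_best: tuple  # (TP, FP, TN, FN)


def evaluate_scores(scores, labels) -> EvalReport:
    """Full single-class report: sweep table, max F1, AUC, FPR at the best
    threshold, and the confusion counts there."""
    max_f1, best_thr, table = max_f1_sweep(scores, labels)
    auc = auc_roc(scores, labels)
    best = confusion_metrics(scores, labels, best_thr)
    return EvalReport(
        thresholds=list(table["threshold"]),
        precision=list(table["precision"]),
        recall=list(table["recall"]),
        f1=list(table["f1"]),
        max_f1=max_f1,
        best_threshold=best_thr,
        auc_roc=auc,
        fpr_at_best=best.fpr,
        confusion_at_best=(best.tp, best.fp, best.tn, best.fn),
    )


@dataclass
class BenchmarkSummary:
    table: pd.DataFrame  # one row per (config cell, metric): mean, se, n
    failures: list = field(default_factory=list)


def run_benchmark(cells, run_fn, replicates: int, seeds) -> BenchmarkSummary:
    """Replicate-run benchmarking over a grid of configuration cells.

    ``cells`` is an iterable of dicts describing each configuration (e.g.
    architecture x epochs x fine-tune x augmentation); ``run_fn(cell, seed)``
    returns a metric dict for one run. Each cell runs ``replicates`` times
    with ``seeds[:replicates]``; per-metric mean and standard error
    (sample SD / sqrt(n)) are reported. Failed cells are recorded, never
    silently dropped.
    """
    seeds = list(seeds)
    if replicates < 1 or len(seeds) < replicates:
        raise ValueError("need at least `replicates` seeds")
    rows, failures = [], []
    for cell in cells:
        results = []
        for seed in seeds[:replicates]:
            try:
                results.append(run_fn(cell, seed))
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                failures.append({"cell": dict(cell), "seed": seed, "error": repr(exc)})
        if not results:
            continue
        metrics = sorted({k for r in results for k in r})
        for metric in metrics:
            vals = np.array([r[metric] for r in results if metric in r], dtype=float)
            n = len(vals)
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append({**cell, "metric": metric, "mean": float(vals.mean()), "se": se, "n": n})
    return BenchmarkSummary(table=pd.DataFrame(rows), failures=failures)


def read_scores_csv(path):
    """Load third-party detector output for scoring with the same harness.

    Expects columns ``window`` (identifier), ``label`` (0/1), ``score``
    (confidence in [0, 1]); returns (scores, labels, windows) arrays. Any
    detector whose per-window confidences can be dumped to this CSV can be
    evaluated with :func:`max_f1_sweep`/:func:`auc_roc` identically to the
    package's own models.
    """
    df = pd.read_csv(path)
    required = {"window", "label", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"scores CSV needs columns {sorted(required)}, found {list(df.columns)}")
    return (
        df["score"].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=int),
        df["window"].to_numpy(),
    )


def benchmark_grid(
    architectures=("alexnet", "vgg16", "vgg19", "resnet18", "resnet50", "resnet152"),
    epochs=(1, 2, 3, 4, 5, 20),
    fine_tune=(True, False),
    augmentations=("none",),
):
    """The standard benchmarking grid as a list of configuration cells."""
    return [
        {"architecture": a, "epochs": e, "fine_tune": ft, "augmentation": aug}
        for a in architectures
        for e in epochs
        for ft in fine_tune
        for aug in augmentations
    ]
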