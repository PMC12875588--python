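"""Classification metrics, repeated-seed stability summaries, and the
comparison arithmetic used in cross-domain reports.

Accuracy is the fraction of correct predictions; recall and F1 are
macro-averaged (equal class weights — the emulated dataset is close to
balanced, and per-class behavior is reported through the confusion matrix).
Repeated-run summaries use the sample standard deviation (n-1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, recall_score

__all__ = [
    "MetricsReport",
    "RunSummary",
    "compute_metrics",
    "repeat_runs",
    "relative_improvement",
    "point_margin",
]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    macro_recall: float
    macro_f1: float
    per_class_accuracy: dict
    confusion: np.ndarray = field(repr=False)
    class_labels: list = field(default_factory=list)
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "confusion": self.confusion.tolist(),
            "class_labels": [str(c) for c in self.class_labels],
            "n": self.n,
        }


def compute_metrics(predictions, labels, class_labels=None) -> MetricsReport:
    """Accuracy, macro recall, macro F1, per-class accuracy and the
    confusion matrix for one prediction run.

    A class present in ``class_labels`` but absent from ``labels``
    contributes recall 0 with a warning rather than an error.
    """
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if pred.shape != y.shape or y.size == 0:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    if class_labels is None:
        class_labels = sorted(np.unique(np.concatenate([y, pred])).tolist())
    missing = [c for c in class_labels if c not in y]
    if missing:
        warnings.warn(f"classes absent from labels contribute recall 0: {missing}")
    cm = confusion_matrix(y, pred, labels=class_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = recall_score(y, pred, labels=class_labels, average="macro", zero_division=0)
        f1 = f1_score(y, pred, labels=class_labels, average="macro", zero_division=0)
    row_sums = cm.sum(axis=1)
    per_class = {
        c: (cm[i, i] / row_sums[i] if row_sums[i] else 0.0) for i, c in enumerate(class_labels)
    }
    return MetricsReport(
        accuracy=float(np.trace(cm) / y.size),
        macro_recall=float(rec),
        macro_f1=float(f1),
        per_class_accuracy=per_class,
        confusion=cm,
        class_labels=list(class_labels),
        n=int(y.size),
    )


@dataclass(frozen=True)
class RunSummary:
    seeds: list
    values: dict  # metric name -> list of per-seed values
    mean: dict
    std: dict
    failures: list = field(default_factory=list)


def repeat_runs(experiment, seeds) -> RunSummary:
    """Run ``experiment(seed) -> dict[str, float]`` for every seed and
    aggregate mean and sample standard deviation per metric.

    Failed runs are recorded and excluded from the summary with a warning.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("repeat_runs needs at least 2 seeds")
    values: dict[str, list[float]] = {}
    ok_seeds, failures = [], []
    for s in seeds:
        try:
            out = experiment(s)
        except Exception as exc:  # noqa: BLE001 - failures are data, not fatal
            failures.append((s, repr(exc)))
            continue
        ok_seeds.append(s)
        for k, v in out.items():
            values.setdefault(k, []).append(float(v))
    if failures:
        warnings.warn(f"{len(failures)} run(s) failed; summary covers {len(ok_seeds)} runs")
    if not ok_seeds:
        raise RuntimeError("all runs failed")
    mean = {k: float(np.mean(v)) for k, v in values.items()}
    std = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in values.items()}
    return RunSummary(seeds=ok_seeds, values=values, mean=mean, std=std, failures=failures)


def relative_improvement(baseline: float, improved: float) -> float:
    """Percent change of ``improved`` over ``baseline``:
    100 * (improved - baseline) / baseline."""
    if baseline == 0:
        raise ZeroDivisionError("baseline must be nonzero")
    return 100.0 * (improved - baseline) / baseline


def point_margin(a: float, b: float) -> float:
    """Difference a - b in the units given (percentage points when the
    inputs are percentages)."""
    return a - b
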