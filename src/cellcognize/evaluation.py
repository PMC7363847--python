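"""Classifier performance: confusion matrices, precision/recall, ROC, spike-in recovery.

Evaluation follows the ensemble convention: metrics are computed per
classifier replicate and reported as mean +/- SD, never by pooling
confusion counts.  The in-silico mixing utilities reproduce the
spike-in design in which subsampled standard events are merged into a
background community of unknown cells and the recovery of each spiked
standard is expressed as a correct-predicted-classification (CPC)
percentage of the expected count — a quantity that can exceed 100% when
background cells are also attributed to the target class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .fcm import LOG10, ConfigError, EventTable, StandardDataset
from .ann import ClassificationResult

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_and_metrics",
    "roc_curve",
    "in_silico_mix",
    "correct_predicted_classification",
]

UNKNOWN_LABEL = "unknown"


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are true standards, columns predicted classes."""

    counts: np.ndarray
    class_labels: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.class_labels, columns=self.class_labels
        )


@dataclass
class ClassMetrics:
    """Per-class recall/precision (%) plus the two accuracy aggregates (%).

    ``mean_accuracy`` is the unweighted mean of per-class recall;
    ``overall_accuracy`` is the trace over the total count.  Both are
    reported because aggregate accuracy figures are ambiguous between
    the two conventions.
    """

    recall: pd.Series
    precision: pd.Series
    mean_accuracy: float
    overall_accuracy: float


def confusion_and_metrics(
    truth: Sequence[str] | np.ndarray,
    result: ClassificationResult,
    exclude: np.ndarray | None = None,
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Confusion matrix and per-class recall/precision for one classifier.

    ``truth`` gives the true standard label per event, aligned with the
    result.  Events flagged in ``exclude`` (e.g. anchors) and events
    whose truth label is not among the classifier's classes (e.g.
    background cells labelled "unknown") are left out.  Precision of a
    never-predicted class is reported as 0 with a warning.
    """
    truth = np.asarray(truth, dtype=object)
    if len(truth) != result.n_events:
        raise ValueError(
            f"truth has {len(truth)} labels but result has {result.n_events} events"
        )
    keep = np.isin(truth, result.class_labels)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    truth_k = truth[keep]
    pred_k = result.assigned_class[keep]
    labels = result.class_labels
    C = _skm.confusion_matrix(truth_k, pred_k, labels=labels)

    row = C.sum(axis=1)
    col = C.sum(axis=0)
    diag = np.diag(C)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, 100.0 * diag / row, 0.0)
        precision = np.where(col > 0, 100.0 * diag / col, 0.0)
    never = [labels[i] for i in range(len(labels)) if col[i] == 0]
    if never:
        warnings.warn(f"class(es) never predicted, precision reported as 0: {never}")
    total = C.sum()
    cm = ConfusionMatrix(counts=C, class_labels=list(labels))
    cmx = ClassMetrics(
        recall=pd.Series(recall, index=labels),
        precision=pd.Series(precision, index=labels),
        mean_accuracy=float(recall[row > 0].mean()) if (row > 0).any() else 0.0,
        overall_accuracy=float(100.0 * diag.sum() / total) if total else 0.0,
    )
    return cm, cmx


def roc_curve(
    truth: Sequence[bool] | np.ndarray, scores: Sequence[float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC for a single class: (fpr, tpr, area).

    ``truth`` is a per-event indicator of class membership; ``scores``
    the class's assignment probability.  Thresholds sweep the unique
    scores; the area is trapezoidal.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC requires at least one positive and one negative event")
    fpr, tpr, _ = _skm.roc_curve(truth.astype(int), np.asarray(scores, dtype=float))
    return fpr, tpr, float(_skm.auc(fpr, tpr))


def in_silico_mix(
    parts: Iterable[tuple[StandardDataset | EventTable, int]],
    seed: int,
) -> tuple[EventTable, np.ndarray]:
    """Merge subsampled datasets into one shuffled table with truth labels.

    Each part is subsampled (without replacement) to its requested
    count; standards contribute their own name as truth label while
    plain event tables (background communities) are labelled
    ``"unknown"``.  Parameter values are carried over bit-exactly.
    """
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    meta: EventTable | None = None
    for part, n in parts:
        if isinstance(part, StandardDataset):
            table, label = part.events, part.standard_name
        else:
            table, label = part, UNKNOWN_LABEL
        if table.scale != LOG10:
            raise ValueError("in_silico_mix expects log10-scale events")
        avail = table.n_events
        if avail == 0:
            raise ConfigError(f"part {label!r} has no events")
        if avail < n:
            warnings.warn(f"part {label!r}: only {avail} events available, requested {n}")
            idx = np.arange(avail)
        else:
            idx = rng.choice(avail, size=n, replace=False)
        frames.append(table.data.iloc[idx])
        labels.append(np.full(len(idx), label, dtype=object))
        meta = meta or table
    data = pd.concat(frames, ignore_index=True)
    truth = np.concatenate(labels)
    order = rng.permutation(len(data))
    mixed = meta.copy_with(data.iloc[order], scale=LOG10)
    mixed.sample_id = "in_silico_mix"
    return mixed, truth[order]


def correct_predicted_classification(
    assigned: pd.Series | dict,
    expected: int,
    target_classes: Iterable[str],
) -> float:
    """CPC: events attributed to the target class(es) as % of the expected count.

    ``target_classes`` may name a single subpopulation class or all the
    classes of one strain.  Values above 100% indicate over-attribution
    (background events pulled into the target classes).
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    assigned = pd.Series(assigned)
    targets = list(target_classes)
    unknown = [t for t in targets if t not in assigned.index]
    if unknown:
        raise ConfigError(f"target class(es) not among assigned classes: {unknown}")
    return float(100.0 * assigned.loc[targets].sum() / expected)
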