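"""High-recall retrieval metrics and distribution diagnostics.

The screening requirement is to miss almost nothing, so the headline
figure is precision at a fixed recall target (default 0.99): sweep every
decision threshold, keep those whose recall reaches the target, and
report the precision of the most conservative one (highest threshold,
fewest retrieved).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .classifier import FittedModel


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    recall: float
    precision: float
    f1: float
    precision_at_recall: float | None = None
    recall_target: float = 0.99
    degenerate: bool = False

    def rounded(self, ndigits: int = 2) -> "MetricsReport":
        """Display copy rounded the way results tables print metrics."""
        return MetricsReport(
            recall=round(self.recall, ndigits),
            precision=round(self.precision, ndigits),
            f1=round(self.f1, ndigits),
            precision_at_recall=(
                None
                if self.precision_at_recall is None
                else round(self.precision_at_recall, ndigits)
            ),
            recall_target=self.recall_target,
            degenerate=self.degenerate,
        )


def confusion(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Cell counts with POSITIVE (1) as the event class."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    return ConfusionMatrix(
        tp=int(np.sum((predicted == 1) & (truth == 1))),
        fp=int(np.sum((predicted == 1) & (truth == 0))),
        tn=int(np.sum((predicted == 0) & (truth == 0))),
        fn=int(np.sum((predicted == 0) & (truth == 1))),
    )


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """R = TP/(TP+FN), P = TP/(TP+FP), F1 = 2PR/(P+R); 0 on empty denominators."""
    degenerate = False
    if cm.tp + cm.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = cm.tp / (cm.tp + cm.fn)
    if cm.tp + cm.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(recall=recall, precision=precision, f1=f1, degenerate=degenerate)


def precision_at_recall(
    scores: Sequence[float], truth: Sequence[int], recall_target: float = 0.99
) -> float:
    """Precision of the most conservative threshold whose recall >= target.

    Candidate thresholds are the observed score values (retrieve means
    score >= threshold). Among feasible thresholds the highest wins; if
    two thresholds retrieve at the same cutoff the tie goes to the higher
    precision.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("precision_at_recall needs at least one true positive")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    cum_tp = np.cumsum(sorted_truth)
    ranks = np.arange(1, len(scores) + 1)
    # a threshold equal to sorted_scores[i] retrieves every doc scoring >= it:
    # the last index of each tied block
    is_block_end = np.append(sorted_scores[1:] != sorted_scores[:-1], True)
    tp_at = cum_tp[is_block_end]
    retrieved_at = ranks[is_block_end]
    recall_at = tp_at / n_pos
    precision_at = tp_at / retrieved_at
    feasible = recall_at >= recall_target
    if not feasible.any():  # unreachable: retrieving everything has recall 1
        raise AssertionError("no feasible threshold")
    first = int(np.argmax(feasible))  # highest threshold achieving the target
    return float(precision_at[first])


def evaluate_scores(
    scores: Sequence[float],
    truth: Sequence[int],
    threshold: float = 0.5,
    recall_target: float = 0.99,
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion + metrics at a hard threshold, plus precision at the recall target."""
    scores = np.asarray(scores, dtype=float)
    cm = confusion((scores >= threshold).astype(int), truth)
    report = metrics(cm)
    report.recall_target = recall_target
    if int(np.asarray(truth).sum()) > 0:
        report.precision_at_recall = precision_at_recall(scores, truth, recall_target)
    else:
        report.degenerate = True
    return cm, report


def evaluate_uncertainty_subset(
    model: FittedModel, X, truth: Sequence[int], threshold: float = 0.5
) -> MetricsReport:
    """Metrics of a model restricted to an acquired (hard) sample subset.

    Comparing successive rounds' models on round one's uncertainty
    samples shows whether retraining actually fixed the hard cases.
    A single-class subset yields a degenerate-flagged report.
    """
    truth = np.asarray(truth, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty uncertainty subset")
    preds = model.predict(X, threshold=threshold)
    report = metrics(confusion(preds, truth))
    if len(np.unique(truth)) < 2:
        report.degenerate = True
    return report


@dataclass
class DistributionDiagnostics:
    coordinates: pd.DataFrame  # columns: pc1, pc2, group
    centroids: pd.DataFrame  # index: group; columns pc1, pc2
    centroid_distances: pd.DataFrame  # pairwise Euclidean distances


def distribution_diagnostics(X, groups: Sequence[str]) -> DistributionDiagnostics:
    """Project documents onto the top-2 principal components, per-group centroids.

    Diagnostic only — no decision in the loop depends on it. Groups with
    fewer than 2 documents are kept with a warning.
    """
    groups = list(groups)
    if X.shape[0] != len(groups):
        raise ValueError("X rows and groups must align")
    if X.shape[0] < 3 or len(set(groups)) < 2:
        raise ValueError("need >= 3 documents and >= 2 groups")
    import logging

    for g in set(groups):
        if groups.count(g) < 2:
            logging.getLogger(__name__).warning("group %r has fewer than 2 documents", g)
    dense = np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)
    coords = PCA(n_components=2, random_state=0).fit_transform(dense)
    df = pd.DataFrame({"pc1": coords[:, 0], "pc2": coords[:, 1], "group": groups})
    centroids = df.groupby("group")[["pc1", "pc2"]].mean()
    names = centroids.index.tolist()
    dist = pd.DataFrame(
        np.linalg.norm(
            centroids.values[:, None, :] - centroids.values[None, :, :], axis=-1
        ),
        index=names,
        columns=names,
    )
    return DistributionDiagnostics(coordinates=df, centroids=centroids, centroid_distances=dist)
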