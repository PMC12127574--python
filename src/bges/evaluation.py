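"""Evaluation metrics and score post-processing.

Clustering quality on enrichment matrices is judged with the average
silhouette coefficient and the Adjusted Rand Index; classification quality
with sensitivity, specificity and balanced accuracy from a confusion table.
Min-max scaling maps scores to [0, 1] for downstream methods that need
non-negative input, and the coefficient of variation (sample SD as a
percentage of the mean) quantifies score stability under noise.

ARI and silhouette are delegated to scikit-learn. Note that ARI can be
negative (labelings worse than chance); the true value is returned rather
than truncated to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .errors import ConfigurationError, DataError

__all__ = [
    "ConfusionCounts",
    "min_max_scale",
    "confusion_metrics",
    "adjusted_rand_index",
    "silhouette_summary",
    "coefficient_of_variation",
    "classification_counts",
    "macro_confusion_metrics",
]


@dataclass
class ConfusionCounts:
    """True/false positive/negative counts of a binary classification."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise DataError("confusion counts are all zero")


def min_max_scale(scores: Sequence[float]) -> np.ndarray:
    """Map scores to [0, 1] via x -> (x - min) / (max - min).

    A constant input returns all zeros with a warning (the transform is
    undefined; zero is the documented convention). Idempotent on already
    scaled non-constant input, and order-preserving.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise DataError("empty input")
    if not np.isfinite(x).all():
        raise DataError("non-finite values in input")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant input to min-max scaling; returning zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) from confusion counts.

    sensitivity = TP/(TP+FN); specificity = TN/(FP+TN); balanced accuracy is
    their mean. A rate with a zero denominator is reported as NaN (with a
    warning), and propagates into balanced accuracy.
    """
    if c.tp + c.fn == 0:
        warnings.warn("no positive items; sensitivity undefined")
        sens = float("nan")
    else:
        sens = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        warnings.warn("no negative items; specificity undefined")
        spec = float("nan")
    else:
        spec = c.tn / (c.fp + c.tn)
    return sens, spec, (sens + spec) / 2


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement of two partitions of the same items.

    Identical partitions (up to relabeling) score 1; independent ones score
    near 0; the value can be negative for worse-than-chance agreement.
    """
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b):
        raise DataError("label vectors have different lengths")
    if len(a) < 2:
        raise DataError("need at least two items")
    return float(adjusted_rand_score(a, b))


def silhouette_summary(
    scores: pd.DataFrame | np.ndarray,
    cluster_labels: Sequence,
    metric: str = "euclidean",
) -> float:
    """Average silhouette coefficient of samples in enrichment-score space.

    ``scores`` is features x samples (e.g. an enrichment matrix: sets as
    features, columns as samples); samples are the clustered items. Clusters
    of size 1 contribute a silhouette of 0. Result lies in [-1, 1].
    """
    X = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    X = X.T  # samples as rows
    labels = np.asarray(list(cluster_labels))
    if labels.shape[0] != X.shape[0]:
        raise DataError("label vector length does not match sample count")
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("silhouette needs at least two clusters")
    return float(silhouette_samples(X, labels, metric=metric).mean())


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation as a percentage of the mean.

    Uses the n-1 (sample) SD. A zero mean is flagged and reported as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("need at least two values")
    mean = x.mean()
    if mean == 0:
        warnings.warn("zero mean; coefficient of variation undefined")
        return float("nan")
    return float(100.0 * x.std(ddof=1) / mean)


def classification_counts(
    true_labels: Sequence, predicted_clusters: Sequence
) -> dict[str, ConfusionCounts]:
    """Per-class one-vs-rest confusion counts for a clustering result.

    Cluster identifiers carry no class meaning, so clusters are first matched
    to true classes by maximizing the total overlap (Hungarian assignment on
    the contingency table); unmatched clusters (when there are more clusters
    than classes) predict no class. Each true class then gets one-vs-rest
    TP/FP/TN/FN counts.
    """
    t = pd.Series(list(true_labels))
    p = pd.Series(list(predicted_clusters))
    if len(t) != len(p):
        raise DataError("label vectors have different lengths")
    cont = pd.crosstab(t, p)
    rows, cols = linear_sum_assignment(-cont.to_numpy())
    cluster_to_class = {cont.columns[c]: cont.index[r] for r, c in zip(rows, cols)}
    mapped = p.map(cluster_to_class)  # NaN for unmatched clusters

    out = {}
    n = len(t)
    for cls in cont.index:
        tp = int(((t == cls) & (mapped == cls)).sum())
        fp = int(((t != cls) & (mapped == cls)).sum())
        fn = int(((t == cls) & (mapped != cls)).sum())
        out[cls] = ConfusionCounts(tp=tp, fp=fp, tn=n - tp - fp - fn, fn=fn)
    return out


def macro_confusion_metrics(
    true_labels: Sequence, predicted_clusters: Sequence
) -> tuple[float, float, float]:
    """Macro-averaged (sensitivity, specificity, balanced accuracy).

    One-vs-rest reduction of a multi-class clustering: per-class metrics from
    :func:`classification_counts`, averaged over classes with equal weight.
    """
    per_class = classification_counts(true_labels, predicted_clusters)
    metrics = np.array([confusion_metrics(c) for c in per_class.values()])
    return tuple(float(x) for x in metrics.mean(axis=0))
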