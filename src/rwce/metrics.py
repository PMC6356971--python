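"""Clustering quality metrics: silhouette, adjusted Rand, log-rank survival test.

Thin, validated wrappers around the standard implementations
(scikit-learn for silhouette and ARI, lifelines for the log-rank test)
presenting the conventions used throughout this package: 1-based crisp
labels, Euclidean silhouette with the singleton-cluster value set to 0, and
the (k-1)-degree-of-freedom chi-squared generalization of the log-rank test
for more than two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .ensemble import DataView
from .errors import ParameterError

__all__ = ["EvaluationReport", "silhouette_mean", "adjusted_rand", "logrank_test", "evaluate"]


@dataclass
class EvaluationReport:
    silhouette_mean: float | None = None
    ari: float | None = None
    logrank_stat: float | None = None
    logrank_p: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def silhouette_mean(view: DataView | np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette value of a labelling over Euclidean feature space.

    Per instance, s = (b - a) / max(a, b) with a the mean distance to its
    own cluster and b the smallest mean distance to another cluster;
    singleton clusters contribute s = 0 by convention.
    """
    X = view.values if isinstance(view, DataView) else np.asarray(view, dtype=float)
    labels = np.asarray(labels)
    if labels.size != X.shape[0]:
        raise ParameterError("labels length must match the number of instances")
    if np.unique(labels).size < 2:
        raise ParameterError("silhouette is undefined for a single cluster")
    return float(silhouette_samples(X, labels, metric="euclidean").mean())


def adjusted_rand(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index; 1 iff the partitions agree up to renaming."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ParameterError(f"label vectors differ in length: {a.size} vs {b.size}")
    return float(adjusted_rand_score(a, b))


def logrank_test(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Log-rank test for equal survival distributions across label groups.

    Two groups give the classical 1-df chi-squared statistic; k groups give
    the (k-1)-df generalization.  Returns (statistic, p_value).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    if not (times.size == events.size == labels.size):
        raise ParameterError("times, events and labels must have equal lengths")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ParameterError("log-rank needs at least two groups")
    for g in groups:
        sel = labels == g
        if events[sel].sum() == 0 and times[sel].sum() == 0:
            raise ParameterError(f"group {g!r} has no events and no at-risk time")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def evaluate(
    labels: np.ndarray,
    view: DataView | None = None,
    truth: np.ndarray | None = None,
    survival: tuple[np.ndarray, np.ndarray] | None = None,
) -> EvaluationReport:
    """Score one labelling against whichever references are available."""
    report = EvaluationReport()
    if view is not None:
        report.silhouette_mean = silhouette_mean(view, labels)
    if truth is not None:
        report.ari = adjusted_rand(labels, truth)
    if survival is not None:
        times, events = survival
        stat, p = logrank_test(times, events, labels)
        report.logrank_stat, report.logrank_p = stat, p
    return report
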