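"""Base-clustering ensembles and the pooled instance-cluster membership matrix.

A cluster ensemble is an ordered collection of M crisp partitions
("base clusterings") of the same n instances.  Pooling the indicator vectors
of every cluster from every base clustering column-wise yields the binary
instance-cluster (IC) matrix: n rows, one column per cluster, with exactly
one 1 per (instance, clustering) pair.  The IC matrix is the raw material
that the downstream random-walk refinement operates on.

Base clusterings are produced by k-means with the number of clusters K drawn
uniformly at random per run; randomising K is what makes the ensemble
diverse enough for consensus to be meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import EnsembleStructureError, ParameterError

__all__ = [
    "DataView",
    "Clustering",
    "Ensemble",
    "ICMatrix",
    "generate_base_clusterings",
    "pool_to_ic",
    "ensemble_from_label_table",
]


@dataclass
class DataView:
    """One instance-by-feature numeric matrix (e.g. one omics data type).

    Parameters
    ----------
    values
        n x m real matrix, rows are instances (patients, samples),
        columns are features (genes, probes, ...).
    instance_ids
        n unique identifiers, aligned with the rows of ``values``.
    view_name
        Human-readable name of the data type ("mrna", "methylation", ...).
    """

    values: np.ndarray
    instance_ids: list[str]
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("view values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 3:
            raise ParameterError(f"a view needs at least 3 instances, got {n}")
        if m < 1:
            raise ParameterError("a view needs at least 1 feature")
        if not np.isfinite(self.values).all():
            raise ParameterError(
                f"view {self.view_name!r} contains missing or non-finite values; "
                "impute or drop them before loading"
            )
        self.instance_ids = [str(i) for i in self.instance_ids]
        if len(self.instance_ids) != n:
            raise ParameterError("instance_ids length does not match row count")
        if len(set(self.instance_ids)) != n:
            raise ParameterError("instance_ids must be unique")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class Clustering:
    """A crisp partition of n instances into K clusters, labels in 1..K."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise EnsembleStructureError("labels must be a 1-D vector")
        present = np.unique(self.labels)
        expected = np.arange(1, self.K + 1)
        if not np.array_equal(present, expected):
            raise EnsembleStructureError(
                f"labels must cover every value in 1..{self.K} exactly; found {present}"
            )

    @property
    def n_instances(self) -> int:
        return self.labels.size

    @classmethod
    def from_raw_labels(cls, raw: np.ndarray) -> "Clustering":
        """Build a Clustering from arbitrary integer labels.

        Labels are relabelled to contiguous 1..K preserving sorted order of
        the original values, so empty clusters (which k-means can produce)
        never survive into the ensemble.
        """
        raw = np.asarray(raw)
        _, contiguous = np.unique(raw, return_inverse=True)
        labels = contiguous + 1
        return cls(labels=labels, K=int(labels.max()))


@dataclass
class Ensemble:
    """An ordered collection of M clusterings over the same instances."""

    clusterings: list[Clustering]
    offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clusterings:
            raise EnsembleStructureError("ensemble must contain at least one clustering")
        n = self.clusterings[0].n_instances
        for i, c in enumerate(self.clusterings):
            if c.n_instances != n:
                raise EnsembleStructureError(
                    f"clustering {i} has {c.n_instances} instances, expected {n}"
                )
        offs, acc = [], 0
        for c in self.clusterings:
            offs.append(acc)
            acc += c.K
        self.offsets = offs

    @property
    def M(self) -> int:
        return len(self.clusterings)

    @property
    def n_instances(self) -> int:
        return self.clusterings[0].n_instances

    @property
    def K_total(self) -> int:
        return sum(c.K for c in self.clusterings)


@dataclass
class ICMatrix:
    """Binary instance-cluster membership matrix pooled over an ensemble.

    Column j is the indicator vector of one cluster; ``cluster_index[j]``
    records which (clustering m, within-clustering cluster k) it came from.
    Every row sums to exactly M (one membership per clustering).
    """

    values: np.ndarray
    cluster_index: list[tuple[int, int]]
    M: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, K = self.values.shape
        if len(self.cluster_index) != K:
            raise EnsembleStructureError("cluster_index length must equal column count")
        if not np.isin(self.values, (0, 1)).all():
            raise EnsembleStructureError("IC matrix must be binary")
        if (self.values.sum(axis=0) < 1).any():
            raise EnsembleStructureError("every IC column must be non-empty")
        if (self.values.sum(axis=1) != self.M).any():
            raise EnsembleStructureError("every IC row must sum to M")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def K_total(self) -> int:
        return self.values.shape[1]

    def blocks(self):
        """Yield (clustering index m, column index array) per clustering block."""
        idx = np.asarray([m for m, _ in self.cluster_index])
        for m in np.unique(idx):
            yield int(m), np.flatnonzero(idx == m)


def default_k_max(n: int, mode: str = "sqrt") -> int:
    """Upper bound for the random cluster number of base k-means runs.

    ``sqrt`` caps K at ceil(sqrt(n)); K close to n produces near-singleton
    partitions that carry no consensus information.  ``linear`` allows any
    K up to n - 1.
    """
    if mode == "sqrt":
        return max(2, math.ceil(math.sqrt(n)))
    if mode == "linear":
        return n - 1
    raise ParameterError(f"unknown k_range_mode {mode!r}")


def generate_base_clusterings(
    view: DataView,
    M: int,
    k_min: int = 2,
    k_max: int | None = None,
    seed: int = 0,
    zscore: bool = True,
) -> Ensemble:
    """Run M seeded k-means base clusterings with random K on one view.

    Parameters
    ----------
    view
        The data view to cluster.
    M
        Ensemble size (number of base clusterings), at least 2.
    k_min, k_max
        K is drawn uniformly from [k_min, k_max] per run.  ``k_max`` defaults
        to ceil(sqrt(n)).
    seed
        Seeds both the K draws and each k-means run; the result is
        deterministic given all arguments.
    zscore
        Standardise each feature to zero mean / unit variance first
        (k-means is scale-sensitive; expression-like features vary over
        wildly different ranges).  Constant features are left at zero.
    """
    n = view.n_instances
    if M < 2:
        raise ParameterError(f"ensemble size M must be >= 2, got {M}")
    if k_max is None:
        k_max = default_k_max(n)
    if not (2 <= k_min <= k_max <= n - 1):
        raise ParameterError(
            f"need 2 <= k_min <= k_max <= n-1; got k_min={k_min}, k_max={k_max}, n={n}"
        )

    X = view.values
    if zscore:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    rng = np.random.default_rng(seed)
    ks = rng.integers(k_min, k_max + 1, size=M)
    clusterings = []
    for K in ks:
        km = KMeans(
            n_clusters=int(K),
            init="k-means++",
            n_init=10,
            max_iter=300,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(X)
        clusterings.append(Clustering.from_raw_labels(km.labels_))
    return Ensemble(clusterings=clusterings)


def pool_to_ic(ensemble: Ensemble) -> ICMatrix:
    """Pool an ensemble into the binary instance-cluster matrix.

    Columns are ordered by clustering, then by within-clustering cluster id.
    """
    n = ensemble.n_instances
    values = np.zeros((n, ensemble.K_total), dtype=np.uint8)
    cluster_index: list[tuple[int, int]] = []
    col = 0
    for m, clustering in enumerate(ensemble.clusterings):
        for k in range(1, clustering.K + 1):
            values[clustering.labels == k, col] = 1
            cluster_index.append((m, k))
            col += 1
    return ICMatrix(values=values, cluster_index=cluster_index, M=ensemble.M)


def ensemble_from_label_table(table: np.ndarray) -> Ensemble:
    """Build an Ensemble from an n x M integer label table (precomputed runs).

    Each column is one base clustering; labels are relabelled to contiguous
    1..K per column.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[1] < 1:
        raise EnsembleStructureError("label table must be n x M with M >= 1")
    return Ensemble(
        clusterings=[Clustering.from_raw_labels(table[:, j]) for j in range(table.shape[1])]
    )
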