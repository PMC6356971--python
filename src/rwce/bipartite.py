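"""Bipartite instance-cluster graph and normalized-cut spectral partitioning.

The RIC matrix is read as a weighted bipartite graph: one vertex per
instance, one per pooled cluster, and an edge of weight RIC(i, j) between
instance i and cluster j (no instance-instance or cluster-cluster edges).
Stacking instances first, the weight matrix is

    W = [[0,      RIC],
         [RIC^T,  0  ]].

The consensus partition is the normalized cut of this graph: form the
symmetric normalized Laplacian L_sym = I - D^{-1/2} W D^{-1/2}, take the
eigenvectors of its k smallest eigenvalues, row-normalise them and run
k-means on the embedded vertices.  Only the instance vertices' labels are
returned.  When k is not given it is chosen by the eigengap heuristic:
k = argmax_{i > 1} (lambda_{i+1} - lambda_i) over a bounded search range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .errors import IsolatedInstanceError, ParameterError
from .ric import RICMatrix

__all__ = ["BipartiteGraph", "SpectralResult", "build_bipartite", "spectral_partition"]

# Ceiling of the eigengap search: consensus cluster counts beyond this are
# outside the intended operating range (cancer subtype counts are single
# digit), and a bounded search keeps degenerate tails of the spectrum from
# hijacking the choice.
DEFAULT_K_CEILING = 15


@dataclass
class BipartiteGraph:
    """Symmetric vertex weight matrix with instance vertices first."""

    weights: np.ndarray
    n_instances: int
    kept_columns: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


@dataclass
class SpectralResult:
    """Eigen-spectrum, selected k and per-instance consensus labels."""

    eigenvalues: np.ndarray
    chosen_k: int
    labels: np.ndarray


def build_bipartite(ric: RICMatrix) -> BipartiteGraph:
    """Assemble the bipartite weight matrix from a RIC matrix.

    Raises on instances with zero total association (their normalized-cut
    degree is undefined); cluster columns with zero weight carry no instance
    information and are dropped with a warning.
    """
    R = np.asarray(ric.values, dtype=float)
    n, K = R.shape
    zero_rows = np.flatnonzero(R.sum(axis=1) == 0)
    if zero_rows.size:
        raise IsolatedInstanceError(
            f"instances with zero association weight: rows {zero_rows.tolist()}"
        )
    col_w = R.sum(axis=0)
    keep = np.flatnonzero(col_w > 0)
    if keep.size < K:
        warnings.warn(
            f"dropping {K - keep.size} isolated cluster vertices with zero weight",
            stacklevel=2,
        )
        R = R[:, keep]
        K = keep.size
    W = np.zeros((n + K, n + K), dtype=float)
    W[:n, n:] = R
    W[n:, :n] = R.T
    return BipartiteGraph(weights=W, n_instances=n, kept_columns=keep)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    _, inv = np.unique(labels, return_inverse=True)
    out = inv + 1
    return out, int(out.max())


def spectral_partition(
    graph: BipartiteGraph,
    k: int | str = "auto",
    kmeans_seed: int = 0,
    k_ceiling: int = DEFAULT_K_CEILING,
) -> SpectralResult:
    """Partition the bipartite graph by normalized-cut spectral clustering.

    Parameters
    ----------
    graph
        Bipartite instance-cluster graph.
    k
        Number of consensus clusters, or ``"auto"`` to select it by the
        largest eigengap of the normalized Laplacian (ties broken toward the
        smaller k).
    kmeans_seed
        Seed for the k-means step on the spectral embedding (20 restarts).
    k_ceiling
        Upper bound of the eigengap search range; the effective range is
        [2, min(k_ceiling, n_instances - 1)].

    Returns
    -------
    SpectralResult
        Ascending eigenvalues (clipped into the theoretical [0, 2] band of
        the normalized Laplacian), selected k, and 1-based consensus labels
        for the instance vertices only.
    """
    W = graph.weights
    N = graph.n_vertices
    n = graph.n_instances
    k_upper = max(2, min(k_ceiling, n - 1))

    if k != "auto":
        k = int(k)
        if k < 2:
            raise ParameterError(f"k must be >= 2, got {k}")
        if k > n:
            raise ParameterError(f"k={k} exceeds the number of instances {n}")

    n_comp, comp = connected_components(W > 0, directed=False)
    if k != "auto" and n_comp > k:
        warnings.warn(
            f"graph has {n_comp} connected components but k={k}; "
            "labels follow the components",
            stacklevel=2,
        )
        labels, K = _relabel(comp[:n])
        return SpectralResult(eigenvalues=np.zeros(n_comp), chosen_k=K, labels=labels)

    d = W.sum(axis=1)
    # build_bipartite guarantees positive instance degrees and drops
    # zero-weight cluster vertices, so d > 0 throughout
    dinv = 1.0 / np.sqrt(d)
    L = -dinv[:, None] * W * dinv[None, :]
    np.fill_diagonal(L, 1.0)
    L = (L + L.T) / 2.0

    q = min(k_upper + 1, N) - 1  # highest eigenvalue index needed (0-based)
    vals, vecs = scipy.linalg.eigh(L, subset_by_index=[0, q])
    vals = np.clip(vals, 0.0, 2.0)

    if k == "auto":
        # eigengap(i) = lambda_{i+1} - lambda_i for i in [2, k_upper] (1-based)
        hi = min(k_upper, vals.size - 1)
        gaps = vals[2 : hi + 1] - vals[1:hi]
        chosen_k = int(np.argmax(gaps)) + 2  # first max -> smallest k on ties
    else:
        chosen_k = k

    U = vecs[:, :chosen_k]
    norms = np.linalg.norm(U, axis=1)
    nz = norms > 0
    if not nz.all():
        warnings.warn("zero rows in the spectral embedding left unnormalized", stacklevel=2)
    U = U.copy()
    U[nz] /= norms[nz, None]

    km = KMeans(n_clusters=chosen_k, n_init=20, random_state=kmeans_seed).fit(U)
    labels, K = _relabel(km.labels_[:n])
    return SpectralResult(eigenvalues=vals, chosen_k=K, labels=labels)
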