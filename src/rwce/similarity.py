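"""Cluster-cluster similarity via a Jaccard network and random walk with restart.

The pooled IC matrix treats clusters as unrelated columns.  In reality
clusters from different base runs overlap heavily; the overlap structure is
captured as a weighted network whose nodes are clusters and whose edges are
Jaccard indices of the clusters' instance sets.  Diffusing the IC matrix
over this network with a random walk with restart (RWR),

    F_{t+1} = alpha * F_t @ A_hat + (1 - alpha) * F_0,

spreads each instance's memberships onto similar clusters while the restart
term anchors the walk at the observed memberships.  The converged columns of
F are dense per-cluster profiles; a scaled exponential kernel on their
pairwise distances gives the refined cluster-cluster similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .ensemble import ICMatrix
from .errors import ConvergenceError, EnsembleStructureError, ParameterError

__all__ = [
    "ClusterGraph",
    "jaccard_network",
    "random_walk_restart",
    "kernel_similarity",
    "build_cluster_graph",
]


def jaccard_network(ic: ICMatrix, self_loops: bool = True) -> np.ndarray:
    """Jaccard similarity network over all pooled clusters.

    Entry (x, y) is |L_x & L_y| / |L_x | L_y| where L_x is the instance set
    of cluster column x.  Clusters within one crisp clustering are disjoint,
    so each within-clustering off-diagonal block is zero.

    Parameters
    ----------
    self_loops
        Keep the set-theoretic diagonal of 1 (default).  ``False`` zeroes the
        diagonal for experiments with loop-free networks.
    """
    B = ic.values.astype(float)
    sizes = B.sum(axis=0)
    if (sizes == 0).any():
        raise EnsembleStructureError("Jaccard undefined for an empty cluster column")
    inter = B.T @ B
    union = sizes[:, None] + sizes[None, :] - inter
    J = inter / union
    np.fill_diagonal(J, 1.0 if self_loops else 0.0)
    return J


def random_walk_restart(
    ic: ICMatrix,
    adjacency: np.ndarray,
    alpha: float = 0.9,
    tol: float = 1e-6,
    max_iter: int = 1000,
    normalize: bool = True,
) -> np.ndarray:
    """Diffuse the IC matrix over the cluster network to a fixed point.

    Iterates ``F <- alpha * F @ A_hat + (1 - alpha) * F0`` with ``F0 = IC``
    until the maximum absolute entrywise change drops below ``tol``.

    By default the adjacency is row-normalised to a stochastic transition
    matrix ``A_hat = D^-1 A`` before iterating, which guarantees convergence
    for any alpha < 1 (the raw adjacency can have spectral radius above
    1/alpha, making the plain iteration diverge).  ``normalize=False`` keeps
    the raw matrix for fidelity experiments.

    Returns the converged n x K_total matrix F.

    Raises
    ------
    ConvergenceError
        If the residual is still above ``tol`` after ``max_iter`` sweeps;
        the error carries the final residual.
    """
    if not (0 <= alpha < 1):
        raise ParameterError(f"alpha must be in [0, 1), got {alpha}")
    if tol <= 0:
        raise ParameterError("tol must be positive")
    A = np.asarray(adjacency, dtype=float)
    if A.shape != (ic.K_total, ic.K_total):
        raise ParameterError("adjacency shape must be K_total x K_total")
    if normalize:
        rows = A.sum(axis=1)
        safe = np.where(rows > 0, rows, 1.0)
        A = A / safe[:, None]

    F0 = ic.values.astype(float)
    if alpha == 0:
        return F0.copy()
    F = F0.copy()
    delta = np.inf
    for _ in range(max_iter):
        F_next = alpha * (F @ A) + (1 - alpha) * F0
        delta = float(np.abs(F_next - F).max())
        F = F_next
        if delta < tol:
            return F
    raise ConvergenceError(
        f"random walk did not converge in {max_iter} iterations "
        f"(final residual {delta:.3e} > tol {tol:.3e})",
        residual=delta,
    )


def kernel_similarity(walked: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Scaled exponential similarity kernel over walked cluster profiles.

    ``sim(i, j) = exp(-rho2(z_i, z_j) / (2 sigma^2))`` where z_i is the i-th
    column of the walked matrix and rho2 the squared Euclidean distance.
    Symmetric, diagonal exactly 1, entries in (0, 1] (very distant profiles
    may underflow to 0).
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    Z = np.asarray(walked, dtype=float).T  # clusters as rows
    d2 = squareform(pdist(Z, metric="sqeuclidean"))
    S = np.exp(-d2 / (2.0 * sigma**2))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


@dataclass
class ClusterGraph:
    """Jaccard network plus the converged walk state over it."""

    adjacency: np.ndarray
    walked: np.ndarray
    alpha: float
    sigma: float

    def similarity(self) -> np.ndarray:
        return kernel_similarity(self.walked, self.sigma)


def build_cluster_graph(
    ic: ICMatrix,
    alpha: float = 0.9,
    sigma: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    normalize: bool = True,
) -> ClusterGraph:
    """Convenience wrapper: Jaccard network then RWR, packaged together."""
    J = jaccard_network(ic)
    F = random_walk_restart(ic, J, alpha=alpha, tol=tol, max_iter=max_iter, normalize=normalize)
    return ClusterGraph(adjacency=J, walked=F, alpha=alpha, sigma=sigma)
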