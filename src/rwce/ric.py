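"""Refined instance-cluster (RIC) association matrix.

The binary IC matrix records only observed memberships; every other
instance-cluster association is a flat zero.  The RIC matrix replaces those
hidden zeros with the refined cluster-cluster similarity, normalised within
each base clustering: for instance x_i whose cluster in clustering m is C*,

    RIC(x_i, C) = 1                                        if C == C*
                = dc * sim(C, C*) / sum_{C' != C*} sim(C', C*)   otherwise,

where the sum runs over the other clusters of the same clustering m.  The
decay hyperparameter ``dc`` scales how much total association mass the
non-member clusters of each block receive (default 1; results are robust to
it).  Note the degenerate corner: in a two-cluster block the single
non-member ratio is 1, so with dc = 1 the non-member entry equals the member
entry and the block carries no contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ICMatrix
from .errors import ParameterError

__all__ = ["RICMatrix", "build_ric"]

# Denominators at or below this are treated as all-zero similarity; the
# exponential kernel cannot produce them but injected raw similarities can.
_ZERO_DENOM = 1e-300


@dataclass
class RICMatrix:
    """Real-valued refined instance-cluster associations in [0, 1]."""

    values: np.ndarray
    cluster_index: list[tuple[int, int]]
    M: int
    dc: float = 1.0

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def K_total(self) -> int:
        return self.values.shape[1]


def build_ric(ic: ICMatrix, sim: np.ndarray, dc: float = 1.0) -> RICMatrix:
    """Fill the IC matrix's zero entries with normalised cluster similarity.

    Parameters
    ----------
    ic
        Pooled binary membership matrix.
    sim
        K_total x K_total cluster similarity (from :func:`kernel_similarity`).
    dc
        Decay hyperparameter: each (instance, clustering) block's non-member
        entries sum to ``dc`` (blocks with a single cluster, or with all-zero
        similarities to the member, keep their non-members at 0).  Entries
        are clipped to [0, 1].
    """
    if dc <= 0:
        raise ParameterError(f"dc must be positive, got {dc}")
    sim = np.asarray(sim, dtype=float)
    if sim.shape != (ic.K_total, ic.K_total):
        raise ParameterError("similarity matrix shape must be K_total x K_total")

    n = ic.n_instances
    values = np.zeros((n, ic.K_total), dtype=float)
    B = ic.values
    for _, cols in ic.blocks():
        Km = cols.size
        member = np.argmax(B[:, cols], axis=1)  # exactly one 1 per row in a block
        if Km == 1:
            values[:, cols[0]] = 1.0
            continue
        S = sim[np.ix_(cols, cols)]
        # sum over C' != C* of sim(C', C*), per member column
        denom = S.sum(axis=0) - np.diag(S)
        block = S[:, member].T * dc  # rows: instances, cols: clusters of block
        d = denom[member]
        ok = d > _ZERO_DENOM
        block[ok] /= d[ok, None]
        block[~ok] = 0.0
        block[np.arange(n), member] = 1.0
        values[:, cols] = block
    np.clip(values, 0.0, 1.0, out=values)
    return RICMatrix(values=values, cluster_index=list(ic.cluster_index), M=ic.M, dc=dc)
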