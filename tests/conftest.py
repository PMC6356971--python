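import numpy as np
import pytest

from rwce import Clustering, DataView, Ensemble, ICMatrix, pool_to_ic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_blob_view(n=60, c=3, m=8, separation=10.0, seed=0, name="blobs"):
    """Well-separated Gaussian blobs with exactly n//c instances per blob."""
    assert n % c == 0
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, c + 1), n // c)
    centers = separation * np.eye(c, m)
    X = centers[labels - 1] + rng.standard_normal((n, m))
    ids = [f"s{i}" for i in range(n)]
    return DataView(values=X, instance_ids=ids, view_name=name), labels


def random_crisp_ensemble(n, M, k_max, rng):
    """Random crisp clusterings (every K in 2..k_max occupied contiguously)."""
    clusterings = []
    for _ in range(M):
        K = int(rng.integers(2, k_max + 1))
        labels = rng.integers(1, K + 1, size=n)
        clusterings.append(Clustering.from_raw_labels(labels))
    return Ensemble(clusterings=clusterings)


def identical_ensemble(labels, M):
    base = Clustering.from_raw_labels(np.asarray(labels))
    return Ensemble(
        clusterings=[Clustering(labels=base.labels.copy(), K=base.K) for _ in range(M)]
    )


@pytest.fixture
def blob_view():
    return make_blob_view()


@pytest.fixture
def small_ic(rng) -> ICMatrix:
    return pool_to_ic(random_crisp_ensemble(n=20, M=4, k_max=4, rng=rng))
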