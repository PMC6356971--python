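"""Synthetic multi-view data with a known latent partition.

Real multi-omics cohorts share one latent patient grouping that each data
type reflects imperfectly.  The generator emulates exactly that premise:
every view is a Gaussian mixture over the same latent labels, with
view-specific cluster centers, view-specific noise, and a configurable
fraction of pure-noise features.  ``separation`` is the between-center
Euclidean distance in within-cluster standard-deviation units (within-cluster
SD is 1), so separation >= ~4 means visually distinct blobs and separation 0
is the null model.

A companion generator draws exponential survival times with cluster-specific
hazards, so survival-based evaluation (log-rank) can be exercised without
clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import DataView
from .errors import ParameterError

__all__ = ["ViewSpec", "SyntheticSpec", "generate_multiview", "generate_survival"]


@dataclass
class ViewSpec:
    """Shape and signal strength of one synthetic view."""

    m: int = 50
    separation: float = 6.0
    noise_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("a view needs at least one feature")
        if self.separation < 0:
            raise ParameterError("separation must be >= 0")
        if not (0 <= self.noise_fraction <= 1):
            raise ParameterError("noise_fraction must be in [0, 1]")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic multi-view cohort."""

    n: int = 300
    c: int = 3
    cluster_proportions: tuple[float, ...] | None = None
    views: list[ViewSpec] = field(default_factory=lambda: [ViewSpec(), ViewSpec(), ViewSpec()])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ParameterError("need at least one latent cluster")
        if self.c > self.n:
            raise ParameterError(f"cannot split {self.n} instances into {self.c} clusters")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / self.c] * self.c)
        p = np.asarray(self.cluster_proportions, dtype=float)
        if p.size != self.c or (p <= 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("cluster_proportions must be a length-c positive simplex vector")


def _class_sizes(n: int, proportions: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder rounding of n * proportions."""
    raw = n * proportions
    sizes = np.floor(raw).astype(int)
    short = n - sizes.sum()
    order = np.argsort(-(raw - sizes))  # largest fractional part first
    sizes[order[:short]] += 1
    return sizes


def _centers(c: int, m_signal: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """Cluster centers with pairwise distance ``separation`` (within-SD = 1).

    When the signal subspace has at least c dimensions the centers sit on a
    scaled random orthonormal frame, so every pairwise distance is exactly
    ``separation``.  In fewer dimensions an equidistant layout may not exist;
    random directions are rescaled so the mean pairwise distance matches.
    """
    if m_signal >= c:
        G = rng.standard_normal((m_signal, c))
        Q, _ = np.linalg.qr(G)
        return (separation / np.sqrt(2.0)) * Q[:, :c].T
    G = rng.standard_normal((c, m_signal))
    d = np.sqrt(((G[:, None, :] - G[None, :, :]) ** 2).sum(-1))
    mean_d = d[np.triu_indices(c, 1)].mean()
    return G * (separation / mean_d) if mean_d > 0 else G


def generate_multiview(spec: SyntheticSpec) -> tuple[list[DataView], np.ndarray]:
    """Draw the views of one synthetic cohort plus its latent labels.

    Returns (views, true_labels) with labels in 1..c, deterministic given
    ``spec.seed``.  Each view draws independent centers and noise from its
    own child RNG stream, so views agree only through the shared labels.
    """
    p = np.asarray(spec.cluster_proportions, dtype=float)
    sizes = _class_sizes(spec.n, p)
    labels = np.repeat(np.arange(1, spec.c + 1), sizes)
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.views))
    ids = [f"sample{i:04d}" for i in range(spec.n)]
    views = []
    for v, (vs, ss) in enumerate(zip(spec.views, streams)):
        rng = np.random.default_rng(ss)
        m_noise = int(round(vs.m * vs.noise_fraction))
        m_signal = vs.m - m_noise
        X = rng.standard_normal((spec.n, vs.m))
        if m_signal > 0 and spec.c > 1:
            centers = _centers(spec.c, m_signal, vs.separation, rng)
            X[:, :m_signal] += centers[labels - 1]
        views.append(DataView(values=X, instance_ids=ids, view_name=f"view{v}"))
    return views, labels


def generate_survival(
    true_labels: np.ndarray,
    hazard_ratios: np.ndarray | list[float],
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival times with cluster-specific hazards.

    Each instance in cluster k draws an event time from an exponential
    distribution with rate ``baseline_hazard * hazard_ratios[k-1]``.
    Censoring is independent of cluster and of the event process: each
    instance is censored with probability ``censor_rate``, at a uniformly
    drawn fraction of its event time.

    Returns (time, event) with event = 1 for observed deaths, 0 for
    censored follow-up.
    """
    labels = np.asarray(true_labels, dtype=int)
    hr = np.asarray(hazard_ratios, dtype=float)
    if (hr <= 0).any():
        raise ParameterError("hazard ratios must be positive")
    if not (0 <= censor_rate < 1):
        raise ParameterError("censor_rate must be in [0, 1)")
    if hr.size < labels.max():
        raise ParameterError("need one hazard ratio per cluster")
    rng = np.random.default_rng(seed)
    rates = baseline_hazard * hr[labels - 1]
    times = rng.exponential(1.0 / rates)
    event = np.ones(labels.size, dtype=int)
    if censor_rate > 0:
        censored = rng.random(labels.size) < censor_rate
        times = np.where(censored, times * rng.random(labels.size), times)
        event[censored] = 0
    return times, event
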