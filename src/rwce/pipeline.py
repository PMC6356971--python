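"""Three-step consensus pipeline: per-view ensembles, per-view refinement,
cross-view integration.

Step 1 generates M randomized k-means base clusterings per data view.
Step 2 combines each view's ensemble into a consensus clustering by the
refinement chain

    IC -> Jaccard network -> random walk with restart -> kernel similarity
       -> RIC -> bipartite graph -> normalized-cut spectral partition.

Step 3 treats the per-view consensus clusterings themselves as a small
ensemble and applies the same refinement once more, yielding one integrated
partition across all data types.

Every stage is seeded.  Per-view work uses sub-seeds derived from the master
seed and the view name (splitmix-style, via ``numpy.random.SeedSequence``),
so each view's result does not depend on the order in which views are given.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .bipartite import DEFAULT_K_CEILING, build_bipartite, spectral_partition
from .ensemble import (
    Clustering,
    DataView,
    Ensemble,
    default_k_max,
    generate_base_clusterings,
    pool_to_ic,
)
from .errors import ParameterError, ViewAlignmentError
from .ric import build_ric
from .similarity import jaccard_network, kernel_similarity, random_walk_restart

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ConsensusClustering",
    "rwce_refine",
    "run_single_view",
    "run_integration",
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serializable to YAML.

    Attributes
    ----------
    M : ensemble size per view.
    alpha : random-walk retention probability in [0, 1); 1 - alpha is the
        restart probability.
    sigma : bandwidth of the exponential similarity kernel.
    dc : decay of the RIC refinement (mass given to non-member clusters).
    tol : convergence tolerance of the walk (max abs entrywise change).
    max_iter : iteration cap of the walk.
    k : consensus cluster count, or "auto" for eigengap selection.
    seed : master seed; every stage derives its randomness from it.
    k_range_mode : "sqrt" caps base-clustering K at ceil(sqrt(n)),
        "linear" allows up to n - 1.
    k_min : lower bound of the random base-clustering K.
    k_max : optional explicit upper bound (overrides k_range_mode).
    zscore : standardise features before base k-means.
    k_ceiling : upper bound of the eigengap search.
    normalize_walk : row-normalise the Jaccard network before walking.
    """

    M: int = 50
    alpha: float = 0.9
    sigma: float = 1.0
    dc: float = 1.0
    tol: float = 1e-6
    max_iter: int = 1000
    k: int | str = "auto"
    seed: int = 0
    k_range_mode: str = "sqrt"
    k_min: int = 2
    k_max: int | None = None
    zscore: bool = True
    k_ceiling: int = DEFAULT_K_CEILING
    normalize_walk: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ConsensusClustering:
    """A consensus partition with its provenance and selected k."""

    labels: np.ndarray
    source: str
    chosen_k: int
    eigenvalues: np.ndarray | None = None

    def as_clustering(self) -> Clustering:
        return Clustering(labels=self.labels, K=self.chosen_k)


def subseed(master: int, *keys) -> int:
    """Derive a stable 31-bit sub-seed from the master seed and string keys."""
    entropy = [int(master)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31 - 1))


def rwce_refine(
    ensemble: Ensemble,
    config: PipelineConfig | None = None,
    source: str = "ensemble",
    seed: int | None = None,
) -> ConsensusClustering:
    """Refine an ensemble into one consensus clustering.

    Composes the full chain: pool to IC, Jaccard network, random walk with
    restart, exponential kernel, RIC construction, bipartite modelling and
    normalized-cut spectral partitioning.  Deterministic given the seed.
    """
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    stage = "pool_to_ic"
    try:
        ic = pool_to_ic(ensemble)
        stage = "jaccard_network"
        J = jaccard_network(ic)
        stage = "random_walk_restart"
        F = random_walk_restart(
            ic, J, alpha=cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter,
            normalize=cfg.normalize_walk,
        )
        stage = "kernel_similarity"
        S = kernel_similarity(F, sigma=cfg.sigma)
        stage = "build_ric"
        ric = build_ric(ic, S, dc=cfg.dc)
        stage = "build_bipartite"
        graph = build_bipartite(ric)
        stage = "spectral_partition"
        result = spectral_partition(graph, k=cfg.k, kmeans_seed=seed, k_ceiling=cfg.k_ceiling)
    except Exception as err:
        err.add_note(f"refinement failed at stage {stage!r} (source={source!r})")
        raise
    logger.info(
        "refined %s: n=%d M=%d K_total=%d -> k=%d",
        source, ensemble.n_instances, ensemble.M, ensemble.K_total, result.chosen_k,
    )
    return ConsensusClustering(
        labels=result.labels,
        source=source,
        chosen_k=result.chosen_k,
        eigenvalues=result.eigenvalues,
    )


def run_single_view(
    view: DataView, config: PipelineConfig | None = None, seed: int | None = None
) -> ConsensusClustering:
    """Generate a base ensemble for one view and refine it to a consensus."""
    cfg = config or PipelineConfig()
    base = cfg.seed if seed is None else seed
    view_seed = subseed(base, "view", view.view_name)
    k_max = cfg.k_max if cfg.k_max is not None else default_k_max(view.n_instances, cfg.k_range_mode)
    ensemble = generate_base_clusterings(
        view, M=cfg.M, k_min=cfg.k_min, k_max=k_max, seed=view_seed, zscore=cfg.zscore
    )
    return rwce_refine(
        ensemble, cfg, source=view.view_name, seed=subseed(view_seed, "refine")
    )


def run_integration(
    views: list[DataView], config: PipelineConfig | None = None
) -> ConsensusClustering:
    """Integrate two or more matched data views into one consensus partition.

    Each view is processed independently (step 1 + 2); the per-view
    consensus clusterings form a T-member ensemble that is refined once more
    (step 3).  Views must share identical instance ids in identical order.
    """
    cfg = config or PipelineConfig()
    if len(views) < 2:
        raise ParameterError("integration needs at least 2 views; use run_single_view for one")
    ref_ids = views[0].instance_ids
    for v in views[1:]:
        if v.instance_ids != ref_ids:
            raise ViewAlignmentError(
                f"view {v.view_name!r} instance ids do not match view {views[0].view_name!r}"
            )
    per_view = [run_single_view(v, cfg) for v in views]
    second = Ensemble(clusterings=[c.as_clustering() for c in per_view])
    return rwce_refine(
        second, cfg, source="integration", seed=subseed(cfg.seed, "integration")
    )
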