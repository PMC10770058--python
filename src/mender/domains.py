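"""From context representation to spatial domains.

The context matrix M is treated exactly like an expression matrix:
total-count normalization, log1p, PCA, a kNN graph, and Leiden
community detection.  Because all slices contribute rows to one matrix
and one graph, the clustering is *joint*: a domain label means the same
thing on every slice, with no post-hoc label matching.

When the expected number of domains k is known, :func:`res_search`
bisects the Leiden resolution until exactly k communities appear
(cluster count is near-monotone in resolution); otherwise the
resolution defaults to 0.5.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .context import ContextRepresentation, build_rings, compute_representation
from .data import SpatialDataset
from .states import (
    CellStateAssignment,
    assign_cell_states,
    preprocess_expression,
    set_cell_states,
)
from ._graph import knn_graph, leiden_partition

logger = logging.getLogger("mender")


@dataclass
class DomainResult:
    """Joint spatial-domain labels plus the embeddings that produced them."""

    labels: np.ndarray                  # "D0", "D1", ... in size order
    resolution_used: float
    embedding: np.ndarray | None = None
    umap_coords: np.ndarray | None = None
    seed: int = 0
    inexact: bool | None = None         # set by res_search when k missed
    params: dict = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return len(set(self.labels.tolist()))


def _domain_names(codes: np.ndarray) -> np.ndarray:
    return np.array([f"D{c}" for c in codes], dtype=object)


def embed_representation(
    M: ContextRepresentation | sp.spmatrix | np.ndarray,
    target_total: float | None = None,
    n_components: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Normalize M per cell, log1p, and reduce to principal components.

    Row totals vary with local density, so each row is scaled to the
    median row total (or an explicit ``target_total``) before log1p.
    A cell whose row is entirely zero (an isolated cell with self
    excluded and no neighbor within reach) is passed through as zeros
    with a warning rather than dropped.
    """
    from .states import _pca, normalize_log1p

    X = M.M if isinstance(M, ContextRepresentation) else M
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    zero = X.sum(axis=1) == 0
    if zero.any():
        logger.warning("%d cells have empty context rows; left as zeros", int(zero.sum()))
    X = normalize_log1p(X, target_total)
    k = min(n_components, X.shape[1], X.shape[0] - 1)
    return _pca(X, k)


def cluster_domains(
    embedding: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
    graph=None,
) -> DomainResult:
    """Leiden clustering of the kNN graph on the reduced representation."""
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] <= n_neighbors:
        raise ValueError("need more cells than n_neighbors")
    if graph is None:
        graph = knn_graph(embedding, n_neighbors)
    codes = leiden_partition(graph, resolution=resolution, seed=seed)
    return DomainResult(
        labels=_domain_names(codes),
        resolution_used=float(resolution),
        embedding=embedding,
        seed=seed,
        params={"n_neighbors": n_neighbors, "resolution": resolution},
    )


def res_search(
    embedding: np.ndarray,
    target_k: int,
    n_neighbors: int = 15,
    seed: int = 0,
    max_iter: int = 30,
    res_bounds: tuple[float, float] = (0.01, 10.0),
) -> tuple[float, DomainResult]:
    """Bisect the Leiden resolution to reach ``target_k`` domains.

    Too few clusters raises the lower bound, too many lowers the upper
    bound.  If no evaluated resolution attains ``target_k`` within
    ``max_iter`` iterations, the run whose cluster count is closest
    (ties: smaller resolution) is returned with ``inexact=True``.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if target_k > n:
        raise ValueError(f"target_k={target_k} exceeds the number of cells {n}")
    graph = knn_graph(embedding, min(n_neighbors, n - 1))
    lo, hi = res_bounds
    best: tuple[int, float, DomainResult] | None = None  # (|k'-k|, res, result)
    for _ in range(max_iter):
        res = (lo + hi) / 2.0
        result = cluster_domains(
            embedding, n_neighbors=min(n_neighbors, n - 1),
            resolution=res, seed=seed, graph=graph,
        )
        k = result.n_domains
        key = (abs(k - target_k), res)
        if best is None or key < (best[0], best[1]):
            best = (abs(k - target_k), res, result)
        if k == target_k:
            result.inexact = False
            return res, result
        if k < target_k:
            lo = res
        else:
            hi = res
    assert best is not None
    _, res, result = best
    result.inexact = True
    logger.warning(
        "res_search: target %d domains unattained, returning %d at resolution %.4g",
        target_k, result.n_domains, res,
    )
    return res, result


def umap_embed(embedding: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP of the reduced representation, for visualization only."""
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] < 3:
        raise ValueError("need at least 3 cells for a 2-D embedding")
    import warnings

    from umap import UMAP

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, embedding.shape[0] - 1),
            random_state=int(seed),
        )
        return np.asarray(reducer.fit_transform(embedding), dtype=float)


@dataclass
class MenderParams:
    """Full parameter record for an end-to-end run."""

    mode: Literal["radius", "knn"] = "radius"
    R: float = 15.0
    nn: int = 6
    S: int = 6
    self_in_first_ring: bool = True
    state_source: Literal["compute", "provided"] = "compute"
    state_resolution: float = 2.0
    n_neighbors: int = 15
    n_components: int = 50
    target_total: float | None = None
    resolution: float | None = None
    target_k: int | None = None
    compute_umap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution is not None and self.target_k is not None:
            raise ValueError("set exactly one of resolution / target_k")
        if self.resolution is None and self.target_k is None:
            self.resolution = 0.5


def run_mender(
    ds: SpatialDataset,
    params: MenderParams | None = None,
    states: CellStateAssignment | None = None,
) -> DomainResult:
    """Run the full pipeline: cell states -> rings -> M -> domains.

    Domain labels are shared across slices (joint clustering), so
    "D0" on one slice and "D0" on another name the same tissue
    structure.  Pass ``states`` to supply a precomputed assignment, or
    set ``params.state_source='provided'`` to adopt ``ds.cell_state``.
    """
    params = params or MenderParams()
    t0 = time.perf_counter()

    def stage(name):
        logger.info("[%s] t=%.2fs", name, time.perf_counter() - t0)

    if states is None:
        if params.state_source == "provided":
            if ds.cell_state is None:
                raise ValueError("cell_states: state_source='provided' but dataset has no cell_state")
            states = set_cell_states(ds, ds.cell_state)
        else:
            try:
                emb = preprocess_expression(
                    ds, target_total=params.target_total,
                    n_components=params.n_components, seed=params.seed,
                )
                states = assign_cell_states(
                    emb, resolution=params.state_resolution,
                    n_neighbors=params.n_neighbors, seed=params.seed,
                )
            except Exception as e:  # pragma: no cover - error path decoration
                raise type(e)(f"cell_states: {e}") from e
    stage("cell_states")

    try:
        rings = build_rings(
            ds, mode=params.mode, R=params.R, nn=params.nn, S=params.S,
            self_in_first_ring=params.self_in_first_ring,
        )
        rep = compute_representation(rings, states)
    except ValueError as e:
        raise ValueError(f"context: {e}") from e
    stage("context")

    emb = embed_representation(
        rep, target_total=params.target_total,
        n_components=params.n_components, seed=params.seed,
    )
    if params.target_k is not None:
        res, result = res_search(
            emb, target_k=params.target_k, n_neighbors=params.n_neighbors,
            seed=params.seed,
        )
    else:
        result = cluster_domains(
            emb, n_neighbors=params.n_neighbors,
            resolution=params.resolution, seed=params.seed,
        )
    stage("domains")

    if params.compute_umap:
        result.umap_coords = umap_embed(emb, seed=params.seed)
        stage("umap")
    result.params = {
        "mode": params.mode, "R": params.R, "nn": params.nn, "S": params.S,
        "self_in_first_ring": params.self_in_first_ring,
        "state_source": states.provenance,
        "C": states.C, "seed": params.seed,
        "resolution": params.resolution, "target_k": params.target_k,
    }
    result.seed = params.seed
    return result
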