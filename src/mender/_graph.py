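"""Shared kNN-graph construction and seeded Leiden partitioning.

Both the cell-state step and the domain step cluster a kNN graph with
Leiden; this module keeps the two on one deterministic code path.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors


def knn_edges(points: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Symmetrized (union) kNN edge list, self excluded, deduplicated."""
    points = np.asarray(points, dtype=float)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, len(points)))
    nn.fit(points)
    _, idx = nn.kneighbors(points)
    rows = np.repeat(np.arange(len(points)), idx.shape[1])
    cols = idx.ravel()
    keep = rows != cols
    a, b = rows[keep], cols[keep]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return np.unique(np.stack([lo, hi], axis=1), axis=0)


def knn_graph(points: np.ndarray, n_neighbors: int):
    import igraph as ig

    edges = knn_edges(points, n_neighbors)
    return ig.Graph(n=len(points), edges=edges.tolist(), directed=False)


def leiden_partition(graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Leiden communities, relabeled by size (largest first).

    Ties in size are broken by the smallest member index, so the label
    assignment is a pure function of the partition.
    """
    import leidenalg

    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    return relabel_by_size(raw)


def relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels to 0..k-1 by descending cluster size."""
    raw = np.asarray(raw)
    values, first_idx, counts = np.unique(raw, return_index=True, return_counts=True)
    order = np.lexsort((first_idx, -counts))
    mapping = np.empty(len(values), dtype=np.int64)
    mapping[order] = np.arange(len(values))
    lookup = {v: mapping[i] for i, v in enumerate(values)}
    return np.fromiter((lookup[v] for v in raw), dtype=np.int64, count=len(raw))
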