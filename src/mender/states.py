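"""Per-cell discrete cell states (the "cell group" alphabet).

The context representation counts cells of each state inside each ring,
so before any spatial step every cell needs a discrete state label
``g_1 .. g_C``.  States are either computed from expression —
total-count normalization, log1p, PCA, kNN graph, Leiden community
detection at resolution 2 — or adopted verbatim from a provided
annotation (the recommended route whenever a reliable cell-type
annotation exists).

:func:`inject_label_noise` is the controlled corruption used to probe
robustness of downstream domain recovery to poor-quality state labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .data import SpatialDataset
from ._graph import knn_graph, leiden_partition


@dataclass
class CellStateAssignment:
    """Discrete per-cell state labels over an alphabet of C states."""

    labels: np.ndarray
    provenance: Literal["computed", "provided"]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self._alphabet = np.array(sorted(set(self.labels.tolist())), dtype=object)

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def C(self) -> int:
        return len(self._alphabet)

    @property
    def alphabet(self) -> np.ndarray:
        """State values in canonical (sorted) order g_1 .. g_C."""
        return self._alphabet

    def codes(self) -> np.ndarray:
        """Integer codes 0..C-1 aligned with :attr:`alphabet`."""
        lookup = {v: i for i, v in enumerate(self._alphabet)}
        return np.fromiter((lookup[v] for v in self.labels), dtype=np.int64, count=len(self.labels))


def normalize_log1p(X: np.ndarray, target_total: float | None = None) -> np.ndarray:
    """Total-count scaling then log(1+x).

    ``target_total=None`` scales each cell to the median of the raw
    per-cell totals (the single-cell toolkit convention); a positive
    number fixes the target explicitly.  All-zero rows pass through
    unchanged.
    """
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    target = float(np.median(totals[totals > 0])) if target_total is None else float(target_total)
    totals = np.where(totals == 0, 1.0, totals)
    return np.log1p(X / totals[:, None] * target)


def preprocess_expression(
    ds: SpatialDataset,
    target_total: float | None = None,
    n_components: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Normalize expression and project to principal components.

    Per-cell total-count scaling (to the median total by default), then
    ``log(1+x)``, then PCA to ``K = min(n_components, G, N-1)``
    dimensions.  The PCA uses a full SVD with a fixed sign convention
    (largest-magnitude loading of each component positive), so the
    result is bitwise reproducible.
    """
    X = ds.expression
    if X.shape[1] < 2:
        raise ValueError("too few features: need at least 2 genes")
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    X = normalize_log1p(X, target_total)
    return _pca(X, min(n_components, X.shape[1], X.shape[0] - 1))


def _pca(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic centered PCA via full SVD with sign fixing."""
    k = max(int(k), 1)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k, Vt.shape[0])
    comps = Vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    return Xc @ comps.T


def assign_cell_states(
    embedding: np.ndarray,
    resolution: float = 2.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> CellStateAssignment:
    """Cluster the expression embedding into cell states.

    Builds a symmetrized kNN graph on the embedding and partitions it
    with Leiden modularity optimization at the given resolution
    (default 2, intentionally fine-grained — over-splitting true cell
    types is harmless downstream, merging them is not).  Labels are
    contiguous integers ordered by cluster size, largest first; ties
    broken by smallest member index.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < number of cells {n}")
    if np.all(embedding == embedding[0]):
        # degenerate input: indistinguishable cells form a single state
        return CellStateAssignment(
            labels=np.zeros(n, dtype=np.int64), provenance="computed", seed=seed
        )
    g = knn_graph(embedding, n_neighbors)
    labels = leiden_partition(g, resolution=resolution, seed=seed)
    return CellStateAssignment(labels=labels, provenance="computed", seed=seed)


def set_cell_states(ds: SpatialDataset, labels) -> CellStateAssignment:
    """Adopt a provided per-cell annotation as the cell states."""
    labels = np.asarray(labels)
    if len(labels) != ds.n_cells:
        raise ValueError(f"labels length {len(labels)} != {ds.n_cells} cells")
    as_str = labels.astype(str)
    missing = np.where((as_str == "") | (as_str == "nan") | (as_str == "None"))[0]
    if missing.size:
        raise ValueError(f"missing labels at indices {missing.tolist()[:20]}")
    return CellStateAssignment(labels=labels, provenance="provided")


def inject_label_noise(
    states: CellStateAssignment, noise_level: float, seed: int = 0
) -> CellStateAssignment:
    """Randomly corrupt a ``noise_level`` fraction of state labels.

    Each cell is independently selected with probability ``noise_level``;
    a selected cell receives a label drawn uniformly from the other
    ``C - 1`` states, so the expected fraction of *changed* labels equals
    ``noise_level`` exactly.
    """
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError(f"noise_level must be in [0, 1], got {noise_level}")
    labels = states.labels.copy()
    if noise_level == 0:
        return CellStateAssignment(labels=labels, provenance=states.provenance, seed=seed)
    if states.C < 2:
        raise ValueError("need at least 2 states to inject noise")
    rng = np.random.default_rng(seed)
    hit = rng.random(len(labels)) < noise_level
    alphabet = states.alphabet
    codes = states.codes()
    # uniform over the other C-1 states: shift a draw in [0, C-2] past self
    draws = rng.integers(0, states.C - 1, size=int(hit.sum()))
    draws = np.where(draws >= codes[hit], draws + 1, draws)
    labels[hit] = alphabet[draws]
    return CellStateAssignment(labels=labels, provenance=states.provenance, seed=seed)
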