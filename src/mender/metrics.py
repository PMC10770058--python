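"""Evaluation metrics: NMI, ARI and PAS, with per-slice aggregation.

NMI (normalized mutual information) scores agreement between a
predicted partition P and a ground truth T,

    NMI = MI(P, T) / sqrt(H(P) * H(T)),

with entropies and mutual information taken from the empirical
contingency table (natural log; the base cancels in the ratio).  ARI is
the pair-counting adjusted Rand index.  Both are permutation-invariant:
label *names* never matter.

PAS (percentage of abnormal spots) scores spatial continuity without
any ground truth: a cell is abnormal when its domain label differs from
at least ``threshold`` (default 6) of its ``k`` (default 10) nearest
same-slice neighbors, and PAS is the abnormal fraction.  Lower is
better; a salt-and-pepper labeling scores near 1.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger("mender")


def _check_pair(P, T) -> tuple[np.ndarray, np.ndarray]:
    P, T = np.asarray(P), np.asarray(T)
    if len(P) != len(T):
        raise ValueError(f"label vectors differ in length: {len(P)} vs {len(T)}")
    if len(P) == 0:
        raise ValueError("empty label vectors")
    return P, T


def _contingency(P: np.ndarray, T: np.ndarray) -> np.ndarray:
    pi = pd.factorize(P)[0]
    ti = pd.factorize(T)[0]
    table = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(table, (pi, ti), 1)
    return table


def nmi(P, T, mask=None) -> float:
    """Normalized mutual information MI/sqrt(H(P)H(T)) in [0, 1].

    If either partition has a single cluster (zero entropy), returns
    1.0 when the two partitions are identical as set partitions and 0.0
    otherwise.
    """
    P, T = _check_pair(P, T)
    if mask is not None:
        P, T = P[np.asarray(mask)], T[np.asarray(mask)]
    table = _contingency(P, T)
    n = table.sum()
    pr = table.sum(axis=1) / n
    pc = table.sum(axis=0) / n
    hp = -np.sum(pr * np.log(pr, where=pr > 0, out=np.zeros_like(pr)))
    ht = -np.sum(pc * np.log(pc, where=pc > 0, out=np.zeros_like(pc)))
    if hp == 0.0 or ht == 0.0:
        same = (table > 0).sum() == max(table.shape) and table.shape[0] == table.shape[1]
        return 1.0 if same else 0.0
    pij = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pij / np.outer(pr, pc)
        terms = np.where(pij > 0, pij * np.log(ratio, where=pij > 0, out=np.zeros_like(ratio)), 0.0)
    mi = terms.sum()
    return float(mi / math.sqrt(hp * ht))


def ari(P, T, mask=None) -> float:
    """Adjusted Rand index (pair counting with chance correction)."""
    from sklearn.metrics import adjusted_rand_score

    P, T = _check_pair(P, T)
    if mask is not None:
        P, T = P[np.asarray(mask)], T[np.asarray(mask)]
    if len(P) < 2:
        raise ValueError("ARI needs at least 2 items")
    return float(adjusted_rand_score(T.astype(str), P.astype(str)))


def pas(
    labels,
    coordinates,
    slice_id=None,
    k: int = 10,
    threshold: int = 6,
) -> float:
    """Percentage of abnormal spots.

    Neighbor search is per slice, self-excluded, with distance ties
    broken by cell index.  Slices with fewer than k+1 cells fall back to
    k_eff = n-1 neighbors and a proportionally scaled threshold
    (ceil(threshold * k_eff / k)), with a warning.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coordinates, dtype=float)
    n = len(labels)
    if coords.shape[0] != n:
        raise ValueError("labels and coordinates differ in length")
    slice_id = np.full(n, "s0") if slice_id is None else np.asarray(slice_id)
    abnormal = 0
    for s in pd.unique(slice_id):
        idx = np.where(slice_id == s)[0]
        m = len(idx)
        if m < 2:
            continue
        k_eff = min(k, m - 1)
        thr = threshold if k_eff == k else math.ceil(threshold * k_eff / k)
        if k_eff < k:
            logger.warning(
                "pas: slice %r has %d cells; using k=%d, threshold=%d", s, m, k_eff, thr
            )
        pts = coords[idx]
        # full pairwise with lexsort gives deterministic tie-breaking by index
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(m), (m, m)), d2), axis=1)
        nbrs = order[:, :k_eff]
        lab = labels[idx]
        diff = (lab[nbrs] != lab[:, None]).sum(axis=1)
        abnormal += int((diff >= thr).sum())
    return abnormal / n


def per_slice_metrics(pred, truth, coordinates, slice_id, k: int = 10, threshold: int = 6) -> pd.DataFrame:
    """One row of (NMI, ARI, PAS) per slice, plus a pooled "joint" row."""
    pred, truth = _check_pair(pred, truth)
    coords = np.asarray(coordinates, dtype=float)
    slice_id = np.asarray(slice_id)
    rows = []
    for s in pd.unique(slice_id):
        m = slice_id == s
        rows.append(
            {
                "slice": s,
                "n": int(m.sum()),
                "NMI": nmi(pred[m], truth[m]),
                "ARI": ari(pred[m], truth[m]),
                "PAS": pas(pred[m], coords[m], k=k, threshold=threshold),
            }
        )
    rows.append(
        {
            "slice": "joint",
            "n": len(pred),
            "NMI": nmi(pred, truth),
            "ARI": ari(pred, truth),
            "PAS": pas(pred, coords, slice_id, k=k, threshold=threshold),
        }
    )
    return pd.DataFrame(rows)
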