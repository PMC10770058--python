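"""Spatial signatures: which (cell state, range) features define a domain.

Every column of the context matrix M is interpretable — "state g_c at
ring s" — so a one-vs-rest rank test per domain turns the clustering
into a readable description of tissue architecture: e.g. a domain
defined not by its own composition but by which states surround it two
rings away.

For each domain and each of the S*C features, a two-sided Wilcoxon
rank-sum (Mann-Whitney) test compares cells inside the domain against
all other cells.  The score is the signed standardized rank-sum
statistic (positive = enriched in the domain); p-values are exact when
both groups are small and the feature is tie-free, otherwise the
normal approximation with tie and continuity corrections is used.
Benjamini-Hochberg adjustment is applied across features within each
domain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .context import ContextRepresentation

logger = logging.getLogger("mender")

_EXACT_MAX = 25  # exact Mann-Whitney only when both groups are at most this size


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Signed z-score and two-sided p for x (domain) vs y (rest).

    z is the tie-corrected, continuity-corrected standardized
    Mann-Whitney U; p is exact (no ties, small groups) or asymptotic.
    """
    nx, ny = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:nx].sum()
    u1 = r1 - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return 0.0, 1.0
    num = u1 - mu
    z = (num - 0.5 * np.sign(num)) / np.sqrt(var)
    no_ties = len(tie_counts) == n
    if no_ties and nx <= _EXACT_MAX and ny <= _EXACT_MAX:
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    return adj


def rank_signatures(
    M: ContextRepresentation,
    domains,
    n_top: int = 5,
    adjust: str | None = "bh",
) -> pd.DataFrame:
    """Top ``n_top`` (state, range) features per domain, one-vs-rest.

    Returns a table with one block of rows per domain, sorted by
    descending score (signed standardized rank-sum statistic), with
    raw and BH-adjusted two-sided p-values and group means.
    """
    domains = np.asarray(domains)
    X = M.M
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    if X.shape[0] != len(domains):
        raise ValueError("domain labels and M disagree on the number of cells")
    uniq = pd.unique(domains)
    if len(uniq) < 2:
        raise ValueError("need at least 2 domains for one-vs-rest testing")
    rows = []
    for d in uniq:
        inside = domains == d
        if inside.sum() < 2:
            logger.warning("rank_signatures: domain %r has <2 cells, skipped", d)
            continue
        scores = np.empty(X.shape[1])
        pvals = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            scores[j], pvals[j] = _rank_sum_test(X[inside, j], X[~inside, j])
        padj = _bh_adjust(pvals) if adjust == "bh" else pvals.copy()
        top = np.argsort(-scores, kind="stable")[:n_top]
        for rank, j in enumerate(top, start=1):
            state, rng = M.decode_column(int(j))
            rows.append(
                {
                    "domain": d,
                    "column": int(j),
                    "state": state,
                    "range": rng,
                    "score": scores[j],
                    "pvalue": pvals[j],
                    "pvalue_adj": padj[j],
                    "mean_in_domain": float(X[inside, j].mean()),
                    "mean_in_rest": float(X[~inside, j].mean()),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


def decode_feature(column: int, M: ContextRepresentation) -> tuple[object, int]:
    """Column index -> (cell state, range s); inverts (s-1)*C + c."""
    return M.decode_column(column)
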