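"""Functional connectivity matrices and binary-graph global efficiency.

The regional functional measure is the Pearson correlation between each pair
of ROI time series.  The whole-brain measure is the global efficiency of the
binary graph obtained by keeping the strongest 30% of edges (proportional
threshold).  Global efficiency is the mean over ordered node pairs of the
inverse shortest-path length, with 1/inf = 0 for disconnected pairs, so it
is always finite and lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "FCMatrix",
    "BinaryGraph",
    "fc_matrix",
    "proportional_threshold",
    "global_efficiency",
    "DENSITY_DEFAULT",
]

DENSITY_DEFAULT = 0.3


@dataclass
class FCMatrix:
    """ROI x ROI Pearson correlation matrix (symmetric, unit diagonal)."""

    r: np.ndarray
    condition: int = 0


@dataclass
class BinaryGraph:
    """Symmetric boolean adjacency with zero diagonal and its edge density."""

    adjacency: np.ndarray
    density: float


def fc_matrix(ts: np.ndarray, condition: int = 0) -> FCMatrix:
    """Pairwise Pearson correlation of ROI rows.

    Rejects constant rows (undefined correlation); clips rounding spill
    outside [-1, 1].
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("expected >= 2 ROI rows")
    sd = ts.std(axis=1, ddof=0)
    if np.any(sd <= 1e-300):
        bad = np.nonzero(sd <= 1e-300)[0].tolist()
        raise ValueError(f"constant ROI rows: {bad}")
    r = np.clip(np.corrcoef(ts), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r=r, condition=condition)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(
    fc: FCMatrix | np.ndarray,
    density: float = DENSITY_DEFAULT,
    ranking: str = "signed",
) -> BinaryGraph:
    """Keep the top ``density`` fraction of unique off-diagonal edges.

    Edges are ranked by signed correlation by default (negative edges are
    effectively excluded at typical densities); ``ranking="absolute"`` ranks
    by |r| instead.  The retained edge count is round-half-away-from-zero of
    density * n(n-1)/2; ties at the cutoff break by lexicographic (i, j)
    order so the result is deterministic.  Self-loops are always excluded.
    """
    r = fc.r if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if ranking not in ("signed", "absolute"):
        raise ValueError("ranking must be 'signed' or 'absolute'")
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = r[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    n_pairs = len(vals)
    k = min(_round_half_away(density * n_pairs), n_pairs)
    # lexsort: last key is primary -> sort by descending value, then (i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=k / n_pairs if n_pairs else 0.0)


def global_efficiency(
    graph: BinaryGraph | np.ndarray, method: str = "average_inverse"
) -> float:
    """Global efficiency of an unweighted graph.

    ``method="average_inverse"`` (default, the standard graph-theory
    definition used by brain-connectivity toolboxes):
    E = (1/(n(n-1))) * sum_{i != j} 1/d_ij, with 1/inf = 0.

    ``method="inverse_average"`` is the literal "inverse of the average
    shortest path length" reading, computed over connected ordered pairs
    only (0 if no pair is connected).
    """
    adj = graph.adjacency if isinstance(graph, BinaryGraph) else np.asarray(graph)
    adj = adj.astype(bool)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    if method not in ("average_inverse", "inverse_average"):
        raise ValueError("unknown efficiency method")
    if not adj.any():
        return 0.0
    d = shortest_path(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    dv = d[off]
    if method == "average_inverse":
        with np.errstate(divide="ignore"):
            inv = np.where(np.isinf(dv), 0.0, 1.0 / dv)
        return float(inv.sum() / (n * (n - 1)))
    finite = dv[np.isfinite(dv)]
    if finite.size == 0:
        return 0.0
    return float(1.0 / finite.mean())
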