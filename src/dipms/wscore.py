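"""Specificity scoring of the combined probability network.

The combined probabilities are arranged as a square adjacency matrix that can
be read as a series of in-silico purification experiments: every column is a
bait, every row a prey. A CompPASS-style specificity score is computed per
column,

    W = X_j * (n / n0) * sqrt( sum_i (X_ji - mu)^2 + mu^2 * n1 )

where X_j is the j-th column, n its number of entries, n0 the count of
negatively predicted interactions (probability < 0.5), n1 the count of
positively predicted interactions (probability > 0.5 and passing the target
FDR), and mu the column mean — a proxy for the bait's promiscuity. A
bootstrap over column entries sets the retention threshold. Networks are
compared by a normalized edge-edit similarity (1 for identical graphs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "JointAdjacency",
    "WScoreResult",
    "build_adjacency",
    "wscore",
    "bootstrap_threshold",
    "ged_similarity",
]


@dataclass
class JointAdjacency:
    """Symmetric protein x protein matrix of combined probabilities.

    Columns are baits, rows are preys; the diagonal is zero.
    """

    proteins: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.proteins = np.asarray(self.proteins, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.proteins)
        if self.matrix.shape != (p, p):
            raise ValueError("matrix must be square over the protein universe")
        if np.any((self.matrix < 0) | (self.matrix > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def index(self) -> dict:
        return {str(p): i for i, p in enumerate(self.proteins)}


@dataclass
class WScoreResult:
    """Per-bait W scores plus the column summaries that produced them."""

    proteins: np.ndarray
    W: np.ndarray          # (prey, bait) matrix of scores
    mu: np.ndarray         # column means
    n0: np.ndarray         # negatively predicted per column
    n1: np.ndarray         # positively predicted (prob > 0.5 and FDR-passing)
    threshold: float | None = None
    retained: np.ndarray | None = field(default=None)


def build_adjacency(table, protein_universe) -> tuple[JointAdjacency, np.ndarray]:
    """Joint adjacency from a scored-pair table over a protein universe.

    Returns the adjacency plus a boolean matrix marking entries whose pair
    passed the FDR filter (needed for the n1 count). Absent pairs are 0.
    """
    proteins = np.asarray(sorted(str(p) for p in protein_universe), dtype=object)
    index = {p: i for i, p in enumerate(proteins)}
    p = len(proteins)
    X = np.zeros((p, p))
    fdr_ok = np.zeros((p, p), dtype=bool)
    targets = table.loc[~table["is_decoy"].astype(bool)]
    for _, row in targets.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        if a not in index or b not in index:
            continue
        i, j = index[a], index[b]
        X[i, j] = X[j, i] = row["combined_p"]
        passed = bool(row.get("fdr_pass", row["q_value"] <= 0.10))
        fdr_ok[i, j] = fdr_ok[j, i] = passed
    np.fill_diagonal(X, 0.0)
    return JointAdjacency(proteins, X), fdr_ok


def wscore(adjacency: JointAdjacency, fdr_flags: np.ndarray | None = None) -> WScoreResult:
    """Vectorized per-column W score.

    ``fdr_flags`` marks entries passing the target FDR; when omitted, every
    entry with probability > 0.5 counts as positively predicted. Entries at
    exactly 0.5 count in neither n0 nor n1. An all-positive column (n0 = 0)
    falls back to a pseudo-count of 1, with a warning.
    """
    X = adjacency.matrix
    n = X.shape[0]
    if fdr_flags is None:
        fdr_flags = X > 0.5
    fdr_flags = np.asarray(fdr_flags, dtype=bool)
    n0 = (X < 0.5).sum(axis=0)
    n1 = ((X > 0.5) & fdr_flags).sum(axis=0)
    mu = X.sum(axis=0) / n
    sq_err = ((X - mu[None, :]) ** 2).sum(axis=0)
    if np.any(n0 == 0) and n > 0:
        warnings.warn("column(s) with no negative predictions: using n0 = 1")
    denom = np.maximum(n0, 1)
    scale = (n / denom) * np.sqrt(sq_err + mu**2 * n1)
    W = X * scale[None, :]
    return WScoreResult(adjacency.proteins, W, mu, n0, n1)


def _column_w(column: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Scalar-form W for one column (used by the bootstrap resampler)."""
    n = column.size
    n0 = int((column < 0.5).sum())
    n1 = int(((column > 0.5) & flags).sum())
    mu = column.sum() / n
    sq = ((column - mu) ** 2).sum()
    return column * (n / max(n0, 1)) * np.sqrt(sq + mu**2 * n1)


def bootstrap_threshold(
    adjacency: JointAdjacency,
    fdr_flags: np.ndarray | None = None,
    n_boot: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> tuple[float, np.ndarray, WScoreResult]:
    """Bootstrap null threshold for W scores; returns (threshold, retained, result).

    Each bootstrap replicate resamples every column's (probability, FDR-flag)
    entries with replacement and recomputes W; the pooled null scores' stated
    quantile is the retention threshold. Edges with W >= threshold are kept.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    X = adjacency.matrix
    n = X.shape[0]
    if n * n < 10:
        raise ValueError("need at least 10 scores to bootstrap")
    if fdr_flags is None:
        fdr_flags = X > 0.5
    fdr_flags = np.asarray(fdr_flags, dtype=bool)
    result = wscore(adjacency, fdr_flags)
    rng = np.random.default_rng(seed)
    null_scores = np.empty((n_boot, n, n))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=(n, n))  # row indices per column
        Xb = X[idx, np.arange(n)[None, :]]
        Fb = fdr_flags[idx, np.arange(n)[None, :]]
        n0 = (Xb < 0.5).sum(axis=0)
        n1 = ((Xb > 0.5) & Fb).sum(axis=0)
        mu = Xb.sum(axis=0) / n
        sq = ((Xb - mu[None, :]) ** 2).sum(axis=0)
        scale = (n / np.maximum(n0, 1)) * np.sqrt(sq + mu**2 * n1)
        null_scores[b] = Xb * scale[None, :]
    threshold = float(np.quantile(null_scores.ravel(), quantile))
    retained = result.W >= threshold
    result.threshold = threshold
    result.retained = retained
    return threshold, retained, result


def _edge_set(graph, nodes=None) -> set[frozenset]:
    if isinstance(graph, nx.Graph):
        edges = graph.edges()
    else:
        edges = graph
    out = set()
    for a, b in edges:
        if a == b:
            continue
        if nodes is not None and (a not in nodes or b not in nodes):
            continue
        out.add(frozenset((a, b)))
    return out


def ged_similarity(network_a, network_b, nodes=None) -> float:
    """Normalized graph-edit similarity of two networks on a shared universe.

    Edits are edge insertions/deletions on the fixed node universe (the union
    of both node sets when not given):

        similarity = 1 - |E_a xor E_b| / (|E_a| + |E_b|)

    Identical graphs score 1; disjoint edge sets score 0; symmetric.
    """
    if nodes is None:
        na = set(network_a.nodes()) if isinstance(network_a, nx.Graph) else {x for e in network_a for x in e}
        nb = set(network_b.nodes()) if isinstance(network_b, nx.Graph) else {x for e in network_b for x in e}
        nodes = na | nb
    else:
        nodes = set(nodes)
    if not nodes:
        raise ValueError("empty node universe")
    ea = _edge_set(network_a, nodes)
    eb = _edge_set(network_b, nodes)
    denom = len(ea) + len(eb)
    if denom == 0:
        return 1.0  # two empty graphs are identical
    return 1.0 - len(ea ^ eb) / denom
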