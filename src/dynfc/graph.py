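"""Graph-theoretic integration and segregation metrics for FC matrices.

Two summary parameters characterize a weighted functional-connectivity
graph: **global efficiency** (mean inverse shortest-path length over node
pairs — rises with functional integration) and **modularity** Q (excess of
within-module edge weight over the configuration-model expectation — rises
with functional segregation).  Conventions follow the standard
weighted-network definitions: negative connectivity values are zeroed and
the remaining weights are max-normalized into [0, 1] before either metric is
computed, so efficiency lands in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .connectivity import FCMatrix

#: Louvain restarts used when none is given
DEFAULT_MODULARITY_RESTARTS = 20


@dataclass
class WeightedGraph:
    """Nonnegative symmetric weight matrix with zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        """Sum of undirected edge weights (each edge counted once)."""
        return float(self.weights.sum()) / 2.0


def to_graph(fc: FCMatrix | np.ndarray) -> WeightedGraph:
    """FC matrix -> weighted graph: negatives zeroed, then max-normalized.

    With all weights in [0, 1], inverse edge lengths are <= 1 and global
    efficiency is bounded by 1.  An all-nonpositive matrix yields the empty
    graph (all weights zero), which is allowed.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    w = np.where(values > 0, values, 0.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    peak = w.max()
    if peak > 0:
        w = w / peak
    return WeightedGraph(w)


def global_efficiency(g: WeightedGraph) -> float:
    """Mean over ordered node pairs of 1/d(i, j), edge length = 1/weight.

    Disconnected pairs contribute 0.  With max-normalized weights the result
    lies in [0, 1]; the complete unit-weight graph scores exactly 1.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(g.weights > 0, 1.0 / g.weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    d = dijkstra(lengths, directed=False)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].mean())


def _partition_to_labels(communities, n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(communities):
        for i in members:
            labels[i] = c
    return labels


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities in order of first appearance (tie-break canon)."""
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def partition_quality(g: WeightedGraph, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Newman's weighted modularity Q = sum_c (e_cc/W - gamma*(a_c/W)^2) for a
    given node -> module assignment."""
    w = g.weights
    total = w.sum()  # 2W: both triangles
    if total <= 0:
        raise ValueError("modularity undefined for zero total weight")
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_cc = w[np.ix_(mask, mask)].sum() / total
        a_c = w[mask, :].sum() / total
        q += e_cc - gamma * a_c**2
    return float(q)


def modularity(
    g: WeightedGraph,
    gamma: float = 1.0,
    n_repeats: int = DEFAULT_MODULARITY_RESTARTS,
    seed: int = 0,
):
    """Maximize weighted modularity with Louvain restarts.

    Runs ``n_repeats`` seeded Louvain passes (resolution ``gamma``) and keeps
    the best Q; ties broken toward the lexicographically smallest canonical
    label sequence so the result is deterministic given ``seed``.

    Returns ``(Q, labels)`` where ``labels[i]`` is node i's module.
    """
    if g.total_weight <= 0:
        raise ValueError("modularity undefined for a graph with zero total weight")
    nxg = nx.from_numpy_array(g.weights)
    best_q, best_labels = -np.inf, None
    for r in range(n_repeats):
        comms = nx.community.louvain_communities(
            nxg, weight="weight", resolution=gamma, seed=seed + r
        )
        labels = _canonical_labels(_partition_to_labels(comms, g.n_nodes))
        q = partition_quality(g, labels, gamma)
        if q > best_q + 1e-12 or (
            abs(q - best_q) <= 1e-12
            and best_labels is not None
            and tuple(labels) < tuple(best_labels)
        ):
            best_q, best_labels = q, labels
    return best_q, best_labels


def metrics_for_fc(fc: FCMatrix, gamma: float = 1.0, n_repeats: int = DEFAULT_MODULARITY_RESTARTS, seed: int = 0) -> dict:
    """Global efficiency and modularity of one FC matrix (shared conversion)."""
    g = to_graph(fc)
    eff = global_efficiency(g)
    if g.total_weight > 0:
        q, _ = modularity(g, gamma=gamma, n_repeats=n_repeats, seed=seed)
    else:
        warnings.warn("empty graph: modularity undefined, reported as NaN")
        q = float("nan")
    return {"global_efficiency": eff, "modularity": q}
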