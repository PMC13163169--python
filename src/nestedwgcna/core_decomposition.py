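"""Weighted k-core decomposition and CGM-core extraction.

The weighted k-core of a graph is the maximal induced subgraph in which
every node's sum of incident edge weights (within the subgraph) is at least
k. The core number c(u) of a node is the largest such k, and the graph
degeneracy is the largest core number present.

The decomposition runs the classic peeling algorithm generalized to
weights: repeatedly delete the node with the smallest current weighted
degree; c(u) is the running maximum of those minimal degrees up to u's
removal. Ties in the minimum are broken by lexicographic node id so the
whole procedure is deterministic.

A module's *core* is the maximum core (nodes at degeneracy) of the complete
weighted graph on its genes with adjacency values as edge weights — the
densest, most mutually correlated subset of the module.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ValidationError
from .network import AdjacencyMatrix

__all__ = ["WeightedGraph", "CoreDecomposition", "weighted_core_numbers", "extract_core"]

TOL = 1e-9  # removal-order tolerance for degeneracy comparisons


@dataclass
class WeightedGraph:
    """Undirected weighted graph as node list + symmetric weight matrix.

    A zero weight means no edge; self-weights (diagonal) are ignored.
    """

    node_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValidationError("weight matrix shape does not match node list")
        if not np.isfinite(w).all():
            raise ValidationError("non-finite edge weight")
        if (w < 0).any():
            raise ValidationError("negative edge weight")
        if not np.allclose(w, w.T):
            raise ValidationError("weight matrix must be symmetric")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w


@dataclass
class CoreDecomposition:
    core_number: dict[str, float]
    degeneracy: float
    max_core_nodes: set[str]

    def to_series(self) -> pd.Series:
        return pd.Series(self.core_number, name="core_number")


def weighted_core_numbers(g: WeightedGraph) -> CoreDecomposition:
    """Peel nodes by minimum weighted degree; assign running-max core numbers.

    Uses a lazy heap: stale entries are skipped when a fresher degree has
    been pushed for the same node. O(E log V) with E the number of nonzero
    weights.
    """
    n = len(g.node_ids)
    if n == 0:
        raise ValidationError("graph has no nodes")
    w = g.weights
    deg = w.sum(axis=1)
    alive = np.ones(n, dtype=bool)
    # heap entries: (degree, node_id, index); node_id string breaks ties
    heap = [(float(deg[i]), g.node_ids[i], i) for i in range(n)]
    heapq.heapify(heap)
    core = np.zeros(n, dtype=float)
    current = 0.0
    removed = 0
    while removed < n:
        d, _, i = heapq.heappop(heap)
        if not alive[i] or d > deg[i] + TOL:
            continue  # stale entry
        current = max(current, float(deg[i]))
        core[i] = current
        alive[i] = False
        removed += 1
        neighbors = np.nonzero((w[i] > 0) & alive)[0]
        for j in neighbors:
            deg[j] -= w[i, j]
            heapq.heappush(heap, (float(deg[j]), g.node_ids[j], int(j)))
    degeneracy = float(core.max())
    max_core = {g.node_ids[i] for i in range(n) if core[i] >= degeneracy - TOL}
    return CoreDecomposition(
        core_number={g.node_ids[i]: float(core[i]) for i in range(n)},
        degeneracy=degeneracy,
        max_core_nodes=max_core,
    )


def extract_core(module_genes: set[str] | list[str], adj: AdjacencyMatrix) -> set[str]:
    """Maximum weighted core of a module's complete co-expression subgraph.

    Edge weights are the adjacency values a_ij; no thresholding is applied.
    """
    genes = sorted(set(module_genes))
    index = {g: i for i, g in enumerate(adj.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValidationError(f"module genes absent from adjacency: {missing[:5]}")
    if len(genes) < 2:
        raise ValidationError("cannot extract a core from a singleton module")
    idx = [index[g] for g in genes]
    sub = adj.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    decomp = weighted_core_numbers(WeightedGraph(node_ids=genes, weights=sub))
    return decomp.max_core_nodes
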