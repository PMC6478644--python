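"""Minimum-spanning-tree topology metrics on 1/PLI weighted networks.

Strong synchronization means a light edge: the adjacency matrix is inverted
entry-wise (weight = 1/PLI, with PLI = 0 mapped to an infinite sentinel so
the graph stays structurally complete) and the minimum spanning tree is
extracted with Kruskal's algorithm.  On the resulting N-node, (N-1)-edge tree
three metrics are computed:

* **leaf fraction** ``L`` — fraction of nodes with degree 1; high values
  indicate an integrated, star-like backbone;
* **degree divergence** ``K = <k^2> / <k>`` — the ratio of the second to the
  first moment of the degree distribution, a broadness measure tied to
  resilience and synchronizability (for a tree the mean degree is fixed at
  ``2(N-1)/N``, so K is driven entirely by the second moment);
* **betweenness centrality** ``BC(v)`` — the number of (unique, since paths
  in a tree are unique) shortest paths passing through ``v`` divided by the
  total number of paths ``N(N-1)/2``.  Endpoints are excluded, so leaves have
  BC = 0.  Note this normalization differs by a constant factor from the
  common ``(N-1)(N-2)/2`` convention.

Per-epoch metrics are averaged across epochs for each subject separately.

Kruskal tie-breaking is a stable sort on (weight, min node index, max node
index) for bit-reproducible trees when weights tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpanningTree",
    "GlobalMetrics",
    "SubjectMetrics",
    "invert_weights",
    "kruskal_mst",
    "leaf_fraction",
    "degree_divergence",
    "betweenness",
    "subject_average",
    "tree_metrics",
]


@dataclass
class SpanningTree:
    """An N-node tree as an (N-1, 2) edge array."""

    n_nodes: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        if self.edges.shape != (self.n_nodes - 1, 2):
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs exactly "
                f"{self.n_nodes - 1} edges"
            )

    @property
    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)


@dataclass
class GlobalMetrics:
    leaf_fraction: float
    degree_divergence: float


@dataclass
class SubjectMetrics:
    """Epoch-averaged metrics for one subject in one band."""

    subject_id: str
    band: str
    leaf_fraction: float
    degree_divergence: float
    betweenness: np.ndarray
    n_epochs: int


def invert_weights(adjacency: np.ndarray) -> np.ndarray:
    """Entry-wise 1/PLI edge weights; PLI = 0 becomes an infinite sentinel.

    The sentinel keeps the graph structurally complete: a zero-synchrony pair
    is heavier than any finite edge but still available, so a spanning tree
    always exists.  The diagonal is set to the sentinel too (self-edges are
    never candidates).
    """
    adjacency = np.asarray(adjacency, dtype=float)
    weights = np.full(adjacency.shape, np.inf)
    mask = adjacency > 0
    weights[mask] = 1.0 / adjacency[mask]
    np.fill_diagonal(weights, np.inf)
    return weights


def kruskal_mst(weights: np.ndarray) -> SpanningTree:
    """Minimum spanning tree of a complete weighted graph via Kruskal.

    ``weights`` is a symmetric (N, N) matrix; infinite entries are valid
    sentinel edges (heavier than any finite weight).  Ties are broken by the
    stable order (weight, i, j) with i < j, so the result is deterministic.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    order = np.lexsort((ju, iu, vals))

    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    edges = np.empty((n - 1, 2), dtype=int)
    k = 0
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges[k] = (i, j)
            k += 1
            if k == n - 1:
                break
    if k < n - 1:
        raise ValueError("graph is disconnected; no spanning tree exists")
    return SpanningTree(n, edges)


def leaf_fraction(tree: SpanningTree) -> float:
    """Fraction of nodes with degree 1."""
    return float(np.mean(tree.degrees == 1))


def degree_divergence(tree: SpanningTree) -> float:
    """K = <k^2> / <k> over all nodes of the tree."""
    deg = tree.degrees.astype(float)
    return float(np.mean(deg**2) / np.mean(deg))


def betweenness(tree: SpanningTree) -> np.ndarray:
    """Fraction of the N(N-1)/2 unique paths passing through each node.

    Endpoints excluded: a path contributes only to its interior nodes, so
    every leaf scores 0.  Computed from subtree sizes in O(N).
    """
    n = tree.n_nodes
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in tree.edges:
        adj[i].append(j)
        adj[j].append(i)

    # iterative DFS from node 0: order and parents, then subtree sizes
    order = np.empty(n, dtype=int)
    parent = np.full(n, -1)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    k = 0
    while stack:
        v = stack.pop()
        order[k] = v
        k += 1
        for nb in adj[v]:
            if not seen[nb]:
                seen[nb] = True
                parent[nb] = v
                stack.append(nb)
    size = np.ones(n, dtype=int)
    for v in order[::-1]:
        if parent[v] >= 0:
            size[parent[v]] += size[v]

    total_pairs = n * (n - 1) // 2
    bc = np.empty(n)
    for v in range(n):
        parts = [size[c] for c in adj[v] if parent[c] == v]
        if parent[v] >= 0:
            parts.append(n - size[v])
        through = (n - 1) * (n - 2) // 2 - sum(p * (p - 1) // 2 for p in parts)
        bc[v] = through / total_pairs
    return bc


def subject_average(
    per_epoch: list[tuple[GlobalMetrics, np.ndarray]],
    subject_id: str,
    band: str,
) -> SubjectMetrics:
    """Arithmetic mean of L, K and element-wise BC across a subject's epochs."""
    if not per_epoch:
        raise ValueError("need at least one epoch")
    n_nodes = {bc.shape[0] for _, bc in per_epoch}
    if len(n_nodes) != 1:
        raise ValueError("inconsistent node counts across epochs")
    return SubjectMetrics(
        subject_id=subject_id,
        band=band,
        leaf_fraction=float(np.mean([g.leaf_fraction for g, _ in per_epoch])),
        degree_divergence=float(np.mean([g.degree_divergence for g, _ in per_epoch])),
        betweenness=np.mean([bc for _, bc in per_epoch], axis=0),
        n_epochs=len(per_epoch),
    )


def tree_metrics(adjacency: np.ndarray) -> tuple[GlobalMetrics, np.ndarray]:
    """Convenience: adjacency -> MST -> (global metrics, BC vector)."""
    tree = kruskal_mst(invert_weights(adjacency))
    return (
        GlobalMetrics(leaf_fraction(tree), degree_divergence(tree)),
        betweenness(tree),
    )
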