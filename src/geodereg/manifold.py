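"""Empirical manifold over frames: kNN graph, geodesics, template.

The frames of a DCE series are assumed to lie on a low-dimensional manifold;
a kNN graph with residual-complexity edge weights discretizes it.  k is the
smallest value for which the (union-)symmetrized graph is connected, so the
manifold stays as sparse as connectivity allows.  All-pairs geodesics come
from repeated Dijkstra runs; the template frame is the geodesic mean — the
node minimizing the summed geodesic distance to all others.  Registering each
frame hop-by-hop along its geodesic path to the template decomposes one large
deformation into a chain of small, anatomically plausible ones.

Determinism: every tie (neighbor selection, shortest path, template argmin)
breaks toward the smallest node index / lexicographically smallest node
sequence.  Paths are computed for i < j and reversed for j > i, so
paths[(j, i)] is exactly the reverse of paths[(i, j)].
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .io import FrameSeries
from .similarity import RCParams, rc_similarity

__all__ = [
    "ManifoldGraph",
    "pairwise_rc",
    "min_connecting_k",
    "build_graph",
    "geodesics",
    "select_template",
]


@dataclass
class ManifoldGraph:
    """Weighted undirected kNN graph over frame indices.

    ``edges`` maps (i, j) with i < j to the RC weight.  ``dist`` and ``paths``
    are filled by :func:`geodesics`; ``template`` by :func:`select_template`.
    """

    n_nodes: int
    k: int
    edges: dict[tuple[int, int], float]
    dist: np.ndarray | None = None
    paths: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    template: int | None = None

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for (a, b), w in self.edges.items():
            if a == i:
                out.append((b, w))
            elif b == i:
                out.append((a, w))
        return sorted(out)

    def to_json(self) -> str:
        payload = {
            "n_nodes": self.n_nodes,
            "k": self.k,
            "edges": [[a, b, w] for (a, b), w in sorted(self.edges.items())],
            "template": self.template,
            "paths": {f"{i}-{j}": p for (i, j), p in sorted(self.paths.items())},
        }
        return json.dumps(payload, indent=2)

    def to_dot(self) -> str:
        lines = ["graph manifold {"]
        for (a, b), w in sorted(self.edges.items()):
            lines.append(f'  {a} -- {b} [label="{w:.3g}"];')
        if self.template is not None:
            lines.append(f"  {self.template} [shape=box];")
        lines.append("}")
        return "\n".join(lines)


def pairwise_rc(series: FrameSeries | np.ndarray, params: RCParams = RCParams()) -> np.ndarray:
    """Symmetric zero-diagonal matrix of RC distances between all frame pairs.

    Computed on the frames as given (the manifold is built on original,
    not low-rank, frames).
    """
    frames = series.frames if isinstance(series, FrameSeries) else np.asarray(series, float)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rc_similarity(frames[i], frames[j], params)
    return d


def _check_dist(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=np.float64)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[1] != n or n < 2:
        raise ValueError(f"need a square distance matrix with n >= 2, got shape {dist.shape}")
    return dist


def _knn_edges(dist: np.ndarray, k: int) -> dict[tuple[int, int], float]:
    """Union-symmetrized kNN edge set with smallest-index tie-breaks."""
    n = dist.shape[0]
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        # stable sort on (distance, index): deterministic under ties
        order = sorted((dist[i, j], j) for j in range(n) if j != i)
        for _, j in order[:k]:
            key = (min(i, j), max(i, j))
            edges[key] = float(dist[key[0], key[1]])
    return edges


def _is_connected(edges: dict[tuple[int, int], float], n: int) -> bool:
    if not edges:
        return n == 1
    rows = [a for a, _ in edges] + [b for _, b in edges]
    cols = [b for _, b in edges] + [a for a, _ in edges]
    g = csr_array((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(g, directed=False)
    return n_comp == 1


def min_connecting_k(dist: np.ndarray) -> int:
    """Smallest k >= 1 whose union-symmetrized kNN graph is connected."""
    dist = _check_dist(dist)
    n = dist.shape[0]
    for k in range(1, n):
        if _is_connected(_knn_edges(dist, k), n):
            return k
    return n - 1  # complete graph is always connected


def build_graph(dist: np.ndarray, k: int) -> ManifoldGraph:
    """Union-symmetrized kNN graph with RC edge weights."""
    dist = _check_dist(dist)
    n = dist.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}, got {k}")
    return ManifoldGraph(n_nodes=n, k=k, edges=_knn_edges(dist, k))


def _dijkstra_lex(adj: list[list[tuple[int, float]]], src: int, n: int):
    """Single-source shortest paths; ties resolved to the lexicographically
    smallest node sequence by carrying the path in the heap key."""
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (src,))]
    while heap:
        d, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (d, path)
        for nb, w in adj[node]:
            if nb not in best:
                heapq.heappush(heap, (d + w, path + (nb,)))
    if len(best) < n:
        raise ValueError("graph is disconnected")
    return best


def geodesics(graph: ManifoldGraph) -> ManifoldGraph:
    """Fill all-pairs geodesic distances and paths by repeated Dijkstra."""
    n = graph.n_nodes
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (a, b), w in sorted(graph.edges.items()):
        adj[a].append((b, w))
        adj[b].append((a, w))
    for lst in adj:
        lst.sort()

    dist = np.zeros((n, n))
    paths: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        best = _dijkstra_lex(adj, i, n)
        for j in range(n):
            d, path = best[j]
            dist[i, j] = d
            if i < j:
                paths[(i, j)] = list(path)
                paths[(j, i)] = list(reversed(path))
    paths.update({(i, i): [i] for i in range(n)})
    # symmetric distances: i->j and j->i shortest lengths coincide
    dist = (dist + dist.T) / 2.0
    graph.dist = dist
    graph.paths = paths
    return graph


def select_template(graph: ManifoldGraph) -> int:
    """Geodesic-mean frame: argmin over nodes of the summed geodesic distance
    to all other nodes, ties to the smallest index."""
    if graph.dist is None:
        raise ValueError("geodesic distances not computed; call geodesics() first")
    sums = graph.dist.sum(axis=1)
    template = int(np.argmin(sums))  # argmin returns the first (smallest) index on ties
    graph.template = template
    return template
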