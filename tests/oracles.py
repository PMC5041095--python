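"""Independent reference implementations used only as test oracles.

Each deliberately avoids the code path it checks: the exact-ALM solver uses
inner-loop-to-convergence with a different mu schedule than the production
inexact solver; the DCT is an explicit cosine-basis matrix product rather
than an FFT; graph quantities come from exhaustive enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# RPCA: exact augmented Lagrange multipliers
# ---------------------------------------------------------------------------


def exact_alm_rpca(A: np.ndarray, lam: float, tol: float = 1e-10, inner_tol: float = 1e-9,
                   rho: float = 6.0, max_outer: int = 200):
    """Exact ALM: each augmented-Lagrangian subproblem is solved to
    convergence by alternating minimization before the dual update."""
    A = np.asarray(A, dtype=float)
    norm_f = np.linalg.norm(A)
    if norm_f == 0:
        return np.zeros_like(A), np.zeros_like(A)
    sigma1 = np.linalg.norm(A, 2)
    Y = A / max(sigma1, np.abs(A).max() / lam)
    mu = 0.5 / sigma1
    L = np.zeros_like(A)
    S = np.zeros_like(A)
    for _ in range(max_outer):
        while True:
            u, s, vt = np.linalg.svd(A - S + Y / mu, full_matrices=False)
            s2 = np.maximum(s - 1.0 / mu, 0.0)
            L_new = (u * s2) @ vt
            G = A - L_new + Y / mu
            S_new = np.sign(G) * np.maximum(np.abs(G) - lam / mu, 0.0)
            delta = max(np.linalg.norm(L_new - L), np.linalg.norm(S_new - S))
            L, S = L_new, S_new
            if delta < inner_tol * norm_f:
                break
        Z = A - L - S
        if np.linalg.norm(Z) / norm_f <= tol:
            return L, S
        Y = Y + mu * Z
        mu *= rho
    return L, S


# ---------------------------------------------------------------------------
# DCT: explicit orthonormal cosine basis
# ---------------------------------------------------------------------------


def dct2_matrix(n: int) -> np.ndarray:
    """Orthonormal type-II DCT matrix, row k = basis function k."""
    k = np.arange(n)[:, None]
    i = np.arange(n)[None, :]
    mat = np.cos(np.pi * k * (2 * i + 1) / (2 * n))
    mat *= np.sqrt(2.0 / n)
    mat[0] /= np.sqrt(2.0)
    return mat


def dct2_naive(x: np.ndarray) -> np.ndarray:
    h, w = x.shape
    return dct2_matrix(h) @ x @ dct2_matrix(w).T


def rc_naive(a: np.ndarray, b: np.ndarray, alpha: float) -> float:
    c = dct2_naive(np.asarray(a, float) - np.asarray(b, float))
    return float(np.sum(np.log1p(c * c / alpha)))


# ---------------------------------------------------------------------------
# Graphs: exhaustive enumeration
# ---------------------------------------------------------------------------


def knn_edges_bruteforce(dist: np.ndarray, k: int) -> set[tuple[int, int]]:
    n = dist.shape[0]
    edges = set()
    for i in range(n):
        order = sorted((dist[i, j], j) for j in range(n) if j != i)
        for _, j in order[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges


def connected_bruteforce(edges: set[tuple[int, int]], n: int) -> bool:
    seen = {0}
    frontier = [0]
    adj = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    while frontier:
        v = frontier.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                frontier.append(w)
    return len(seen) == n


def min_connecting_k_bruteforce(dist: np.ndarray) -> int:
    n = dist.shape[0]
    for k in range(1, n):
        if connected_bruteforce(knn_edges_bruteforce(dist, k), n):
            return k
    return n - 1


def shortest_paths_bruteforce(edges: dict[tuple[int, int], float], n: int, src: int, dst: int):
    """All-simple-path enumeration; returns (best distance, lexicographically
    smallest best path).  Exponential — for n <= 8 only."""
    adj = {i: {} for i in range(n)}
    for (a, b), w in edges.items():
        adj[a][b] = w
        adj[b][a] = w
    best = (np.inf, None)
    stack = [(src, [src], 0.0)]
    while stack:
        v, path, d = stack.pop()
        if v == dst:
            cand = (d, tuple(path))
            if d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and (best[1] is None or cand[1] < best[1])):
                best = (d, tuple(path))
            continue
        for w, wt in adj[v].items():
            if w not in path:
                stack.append((w, path + [w], d + wt))
    return best


def all_pairs_bruteforce(edges: dict[tuple[int, int], float], n: int):
    dist = np.zeros((n, n))
    paths = {}
    for i, j in itertools.combinations(range(n), 2):
        d, p = shortest_paths_bruteforce(edges, n, i, j)
        dist[i, j] = dist[j, i] = d
        paths[(i, j)] = list(p)
    return dist, paths
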