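"""Independent brute-force oracles for the weighted graph metrics.

Deliberately naive (pure-Python loops, exhaustive enumeration) so they share
no code path with the vectorized/scipy/networkx implementations they check.
"""
from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    n = lengths.shape[0]
    d = lengths.astype(float).copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def onnela_clustering(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    what = np.zeros_like(w)
    what[off] = w[off] / w[off].max()
    c = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and what[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == h or j == i or h == i:
                    continue
                total += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def local_efficiency_brute(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if j != i and w[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        lengths = np.full((k, k), np.inf)
        for a, ja in enumerate(nb):
            lengths[a, a] = 0.0
            for b, jb in enumerate(nb):
                if a != b and w[ja, jb] > 0:
                    lengths[a, b] = 1.0 / w[ja, jb]
        d = floyd_warshall(lengths)
        total = 0.0
        for a, ja in enumerate(nb):
            for b, jb in enumerate(nb):
                if a == b or not np.isfinite(d[a, b]) or d[a, b] == 0:
                    continue
                total += (w[i, ja] * w[i, jb] / d[a, b]) ** (1.0 / 3.0)
        e[i] = total / (k * (k - 1))
    return e


def betweenness_enumeration(w: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Count shortest paths by exhaustive simple-path enumeration.

    Paths longer than the known shortest distance (plus tolerance) are
    pruned during the DFS; each unordered source-target pair contributes
    sigma_st(v)/sigma_st to every interior node v.
    """
    n = w.shape[0]
    lengths = np.full((n, n), np.inf)
    off = ~np.eye(n, dtype=bool)
    lengths[off] = 1.0 / w[off]
    np.fill_diagonal(lengths, 0.0)
    dist = floyd_warshall(lengths)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        best = dist[s, t]
        shortest_paths: list[tuple[int, ...]] = []

        def dfs(node: int, visited: tuple[int, ...], acc: float) -> None:
            if acc > best + tol:
                return
            if node == t:
                if abs(acc - best) <= tol:
                    shortest_paths.append(visited)
                return
            for nxt in range(n):
                if nxt in visited or w[node, nxt] <= 0:
                    continue
                dfs(nxt, visited + (nxt,), acc + lengths[node, nxt])

        dfs(s, (s,), 0.0)
        sigma = len(shortest_paths)
        if sigma == 0:
            continue
        for path in shortest_paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def ols_normal_equations(y: np.ndarray, ages: np.ndarray, degree: int) -> np.ndarray:
    """Solve (X'X) beta = X'y explicitly."""
    x = np.vander(np.asarray(ages, float), degree + 1, increasing=True)
    return np.linalg.solve(x.T @ x, x.T @ np.asarray(y, float))
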