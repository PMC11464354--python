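"""Independent brute-force oracles for graph metrics.

Deliberately naive implementations (dict-based BFS, explicit geodesic
enumeration, direct Pearson correlation) used only to check the package's
metric routines on small graphs. They share no code with scnkit.metrics.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def edges_of(A) -> list[tuple[int, int]]:
    A = np.asarray(A)
    n = A.shape[0]
    return [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j]]


def neighbors(A, i) -> list[int]:
    return [j for j in range(A.shape[0]) if A[i][j] and j != i]


def bfs_distances(A, source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in neighbors(A, u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        queue = nxt
    return dist


def clustering_oracle(A) -> float:
    n = np.asarray(A).shape[0]
    cs = []
    for i in range(n):
        nb = neighbors(A, i)
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if A[a][b])
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def path_length_oracle(A) -> float:
    """Mean shortest-path length over reachable ordered pairs (nan if none)."""
    n = np.asarray(A).shape[0]
    lengths = []
    for i in range(n):
        dist = bfs_distances(A, i)
        lengths.extend(d for j, d in dist.items() if j != i)
    return float(np.mean(lengths)) if lengths else math.nan


def global_efficiency_oracle(A) -> float:
    n = np.asarray(A).shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        dist = bfs_distances(A, i)
        total += sum(1.0 / d for j, d in dist.items() if j != i)
    return total / (n * (n - 1))


def local_efficiency_oracle(A) -> tuple[float, list[float]]:
    A = np.asarray(A)
    n = A.shape[0]
    nodal = []
    for i in range(n):
        nb = neighbors(A, i)
        if len(nb) < 2:
            nodal.append(0.0)
            continue
        sub = A[np.ix_(nb, nb)]
        nodal.append(global_efficiency_oracle(sub))
    return float(np.mean(nodal)), nodal


def betweenness_oracle(A) -> list[float]:
    """Unnormalized betweenness by explicit enumeration of all geodesics."""
    A = np.asarray(A)
    n = A.shape[0]

    def all_geodesics(s, t):
        dist_s = bfs_distances(A, s)
        if t not in dist_s:
            return []
        dist_t = bfs_distances(A, t)
        d = dist_s[t]
        paths = [[s]]
        for step in range(1, d + 1):
            paths = [
                p + [v]
                for p in paths
                for v in neighbors(A, p[-1])
                if dist_s.get(v) == step and dist_t.get(v) == d - step
            ]
        return paths

    btw = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        paths = all_geodesics(s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / len(paths)
    return btw


def assortativity_oracle(A) -> float:
    """Pearson correlation of degrees over edge endpoints (both directions)."""
    A = np.asarray(A)
    deg = A.sum(axis=1)
    xs, ys = [], []
    for i, j in edges_of(A):
        xs.extend([deg[i], deg[j]])
        ys.extend([deg[j], deg[i]])
    if np.std(xs) == 0 or np.std(ys) == 0:
        return math.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def trapezoid_oracle(xs, ys) -> float:
    """Reference trapezoid summation, written out longhand."""
    total = 0.0
    for k in range(1, len(xs)):
        total += 0.5 * (ys[k] + ys[k - 1]) * (xs[k] - xs[k - 1])
    return total


def random_adjacency(rng, n: int, p: float) -> np.ndarray:
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T
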