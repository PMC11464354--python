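"""Binary-graph topology metrics and null-model normalization.

Conventions (they matter for thresholded, possibly fragmented graphs):

* characteristic path length ``L`` averages shortest-path lengths over
  *reachable* ordered pairs only;
* unreachable pairs contribute 0 to global efficiency (1/inf = 0);
* nodal local efficiency of a node is the global efficiency of the
  subgraph induced by its neighbors (0 for degree < 2); the global value
  is the mean over nodes;
* betweenness is unnormalized (sums of geodesic fractions over unordered
  pairs);
* gamma, lambda, sigma normalize clustering and path length by the means
  of a degree-preserving (Maslov-Sneppen double-edge-swap) null ensemble.

Shortest paths are computed by simultaneous dense BFS (numpy); rewiring
uses a numba-jitted double-edge-swap kernel; betweenness delegates to
networkx.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit


def as_adjacency(graph) -> np.ndarray:
    """Coerce a networkx graph or square 0/1 matrix to a dense adjacency."""
    if isinstance(graph, nx.Graph):
        return nx.to_numpy_array(graph, dtype=float)
    A = np.asarray(graph, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    A = (A != 0).astype(float)
    np.fill_diagonal(A, 0.0)
    return A


def as_graph(graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    return nx.from_numpy_array(as_adjacency(graph))


def _distances(A: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest paths by simultaneous BFS (matmul).

    O(diameter) dense matrix products; unreachable pairs are inf. Faster
    than sparse-graph routines for the small dense graphs used here.
    """
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier.astype(float) @ A) > 0
        frontier = nxt & ~reached
        D[frontier] = d
        reached |= frontier
    return D


def nodal_clustering(graph) -> np.ndarray:
    """Per-node clustering coefficient: triangles / (k choose 2), 0 for k<2."""
    A = as_adjacency(graph)
    k = A.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def clustering_and_path(graph) -> tuple[float, float]:
    """Mean clustering coefficient C and characteristic path length L.

    L is the mean shortest-path length over reachable ordered pairs;
    a graph with no edges has undefined L (nan).
    """
    A = as_adjacency(graph)
    n = A.shape[0]
    if n < 2:
        raise ValueError(f"graph must have >= 2 nodes, got {n}")
    C = float(nodal_clustering(A).mean())
    D = _distances(A)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    L = float(D[finite].mean()) if finite.any() else float("nan")
    return C, L


def efficiencies(graph) -> tuple[float, float, np.ndarray]:
    """Global efficiency, mean local efficiency, and nodal local efficiency."""
    A = as_adjacency(graph)
    n = A.shape[0]
    if n < 2:
        raise ValueError(f"graph must have >= 2 nodes, got {n}")
    eglob = _global_efficiency(A)
    nodal = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if nb.size < 2:
            continue
        nodal[i] = _global_efficiency(A[np.ix_(nb, nb)])
    return eglob, float(nodal.mean()), nodal


def _global_efficiency(A: np.ndarray) -> float:
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = _distances(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def centralities(graph) -> tuple[np.ndarray, np.ndarray]:
    """Nodal degree (raw edge counts) and unnormalized betweenness."""
    G = as_graph(graph)
    if G.number_of_nodes() < 2:
        raise ValueError("graph must have >= 2 nodes")
    nodes = sorted(G.nodes())
    deg = np.array([G.degree(v) for v in nodes], dtype=float)
    bc = nx.betweenness_centrality(G, normalized=False)
    btw = np.array([bc[v] for v in nodes], dtype=float)
    return deg, btw


def assortativity(graph) -> float:
    """Degree assortativity (Pearson correlation of degrees over edge ends).

    Returns nan for degenerate graphs (regular degree sequence over edge
    endpoints) rather than raising.
    """
    G = as_graph(graph)
    if G.number_of_edges() < 1:
        raise ValueError("assortativity requires at least one edge")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = nx.degree_assortativity_coefficient(G)
    return float(r)


@dataclass
class NullEnsemble:
    """Degree-preserving random reference graphs and their C/L statistics."""

    graphs: list[np.ndarray]
    clustering: np.ndarray  # per-null mean clustering
    path_length: np.ndarray  # per-null characteristic path length
    seed: int
    rewired: bool  # False if the source could not be rewired

    @property
    def n(self) -> int:
        return len(self.graphs)


@njit(cache=True)
def _swap_kernel(A, edges, nswap, max_tries, seed):  # pragma: no cover - jitted
    """In-place Maslov-Sneppen double-edge swaps on a dense adjacency.

    Picks two distinct edges (u,v), (x,y) (random orientation), proposes
    (u,x), (v,y), and accepts when the result stays simple. Returns the
    number of accepted swaps.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    swaps = 0
    tries = 0
    while swaps < nswap and tries < max_tries:
        tries += 1
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        u, v = edges[e1, 0], edges[e1, 1]
        x, y = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if A[u, x] == 1.0 or A[v, y] == 1.0:
            continue
        A[u, v] = A[v, u] = 0.0
        A[x, y] = A[y, x] = 0.0
        A[u, x] = A[x, u] = 1.0
        A[v, y] = A[y, v] = 1.0
        edges[e1, 0], edges[e1, 1] = u, x
        edges[e2, 0], edges[e2, 1] = v, y
        swaps += 1
    return swaps


def random_reference(
    graph, n_nulls: int = 100, swaps_per_edge: int = 10, seed: int = 0
) -> NullEnsemble:
    """Maslov-Sneppen degree-preserving null ensemble.

    Each null graph is produced by ``swaps_per_edge * |E|`` double-edge
    swaps of a copy of the source; every null is simple and has the
    source's exact degree sequence. Graphs too dense or too small to admit
    any legal swap are returned unrewired with ``rewired=False``.
    """
    A0 = as_adjacency(graph)
    n = A0.shape[0]
    iu = np.triu_indices(n, k=1)
    sel = A0[iu] > 0
    edges0 = np.column_stack([iu[0][sel], iu[1][sel]]).astype(np.int64)
    m = edges0.shape[0]
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    max_edges = n * (n - 1) // 2
    rewirable = m >= 2 and m < max_edges
    seeds = np.random.SeedSequence(seed).generate_state(n_nulls)
    graphs, Cs, Ls = [], [], []
    rewired = rewirable
    for s in seeds:
        A = A0.copy()
        if rewirable:
            nswap = swaps_per_edge * m
            done = _swap_kernel(
                A, edges0.copy(), nswap, 100 * nswap, np.int64(s % 2**31)
            )
            if done == 0:
                rewired = False
        graphs.append(A)
        C, L = clustering_and_path(A)
        Cs.append(C)
        Ls.append(L)
    return NullEnsemble(
        graphs=graphs,
        clustering=np.array(Cs),
        path_length=np.array(Ls),
        seed=seed,
        rewired=rewired,
    )


def normalized_smallworld(graph, nulls: NullEnsemble) -> tuple[float, float, float]:
    """Small-world normalization: gamma = C/<C_null>, lambda = L/<L_null>,
    sigma = gamma/lambda. Zero null means yield nan (flagged, not raised)."""
    if nulls.n == 0:
        raise ValueError("null ensemble is empty")
    C, L = clustering_and_path(graph)
    c_null = float(np.nanmean(nulls.clustering))
    l_null = float(np.nanmean(nulls.path_length))
    gamma = C / c_null if c_null > 0 else float("nan")
    lam = L / l_null if l_null > 0 else float("nan")
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam > 0 else float("nan")
    return gamma, lam, sigma


def auc_over_density(
    values, densities, density_range: tuple[float, float]
) -> float:
    """Trapezoidal area under a metric-vs-density curve over a range.

    ``densities`` is the full grid on which ``values`` is defined; the
    integral runs over the grid points within ``[lo, hi]`` inclusive. Every
    grid point implied by the range and grid step must be present.
    """
    densities = np.asarray(densities, dtype=float)
    values = np.asarray(values, dtype=float)
    if densities.shape != values.shape:
        raise ValueError("values and densities must have the same length")
    if np.any(np.diff(densities) <= 0):
        raise ValueError("density grid must be strictly increasing")
    lo, hi = density_range
    if lo > hi:
        raise ValueError(f"invalid density range {density_range}")
    tol = 1e-9
    mask = (densities >= lo - tol) & (densities <= hi + tol)
    sub_d = densities[mask]
    if sub_d.size < 2:
        raise ValueError(f"density range {density_range} covers < 2 grid points")
    if abs(sub_d[0] - lo) > tol or abs(sub_d[-1] - hi) > tol:
        missing = [x for x in (lo, hi) if not np.any(np.abs(sub_d - x) <= tol)]
        raise ValueError(f"range endpoints not on the grid: {missing}")
    return float(np.trapezoid(values[mask], sub_d))
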