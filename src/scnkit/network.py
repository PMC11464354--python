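"""Individual similarity networks, density thresholding, and density admission.

Each subject's 76 z-scored features become the nodes of a fully weighted
graph with edge weight

    w(x, y) = exp(-(z_x - z_y)^2)  in (0, 1],   w = 1 iff z_x = z_y,

i.e. regions with similar (covariate-adjusted, reference-scaled) morphometry
are strongly connected. Weighted graphs are thresholded at each density D of
a grid by keeping the k = round(D * N(N-1)/2) largest-weight edges and
binarizing, which makes every subject's graph directly comparable (equal
edge counts) and the ensembles nested across densities.

A density is *admitted* for analysis when the binarized cohort satisfies
three criteria: >80% of nodes non-isolated, modularity > 0.3, and
small-world index sigma > 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import metrics as gm

DEFAULT_DENSITY_GRID = tuple(np.round(np.arange(0.01, 0.501, 0.01), 2))


@dataclass
class WeightedSimilarityNetwork:
    """Symmetric weighted similarity graph for one subject."""

    subject_id: str
    node_names: tuple[str, ...]
    weights: np.ndarray  # N x N, symmetric, zero diagonal, off-diag in (0, 1]

    def __post_init__(self) -> None:
        W = self.weights
        n = len(self.node_names)
        if W.shape != (n, n):
            raise ValueError(f"weights shape {W.shape} != ({n}, {n})")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        off = W[~np.eye(n, dtype=bool)]
        if np.any(off <= 0) or np.any(off > 1):
            raise ValueError("off-diagonal weights must lie in (0, 1]")


def similarity_network(
    z_row: pd.Series | np.ndarray,
    subject_id: str = "",
    node_names: tuple[str, ...] | None = None,
) -> WeightedSimilarityNetwork:
    """Build the weighted similarity network from one subject's z-scores."""
    if isinstance(z_row, pd.Series):
        if node_names is None:
            node_names = tuple(z_row.index)
        z = z_row.to_numpy(float)
    else:
        z = np.asarray(z_row, dtype=float)
        if node_names is None:
            node_names = tuple(f"node{i}" for i in range(z.size))
    if not np.isfinite(z).all():
        bad = [node_names[i] for i in np.flatnonzero(~np.isfinite(z))]
        raise ValueError(
            f"non-finite z-scores for subject {subject_id!r} at features {bad}"
        )
    diff = z[:, None] - z[None, :]
    W = np.exp(-(diff**2))
    np.fill_diagonal(W, 0.0)
    return WeightedSimilarityNetwork(subject_id=subject_id, node_names=node_names, weights=W)


def edge_count(density: float, n_nodes: int) -> int:
    """Edges retained at a density: round-half-away-from-zero of D*N(N-1)/2."""
    m_max = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density * m_max + 0.5))


@dataclass
class BinaryNetworkEnsemble:
    """Binarized graphs of one subject across a density grid (nested)."""

    subject_id: str
    node_names: tuple[str, ...]
    densities: tuple[float, ...]
    edge_order: np.ndarray  # (M, 2) edges sorted by decreasing weight
    edge_counts: tuple[int, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def _k(self, density: float) -> int:
        for d, k in zip(self.densities, self.edge_counts):
            if abs(d - density) <= 1e-9:
                return k
        raise KeyError(f"density {density} not on the ensemble grid")

    def adjacency(self, density: float) -> np.ndarray:
        k = self._k(density)
        n = self.n_nodes
        A = np.zeros((n, n))
        e = self.edge_order[:k]
        A[e[:, 0], e[:, 1]] = 1.0
        A[e[:, 1], e[:, 0]] = 1.0
        return A

    def graph(self, density: float) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        G.add_edges_from(map(tuple, self.edge_order[: self._k(density)]))
        return G


def threshold_binarize(
    network: WeightedSimilarityNetwork,
    density_grid=DEFAULT_DENSITY_GRID,
) -> BinaryNetworkEnsemble:
    """Threshold a weighted network at each grid density and binarize.

    At density D the k = round(D*M) largest-weight edges are kept (M =
    N(N-1)/2 possible edges). Ties at the k-th weight are broken by
    lexicographic (i, j) node order, so results are deterministic. The
    retained edge sets are nested across densities by construction.
    """
    densities = tuple(float(d) for d in density_grid)
    if not densities:
        raise ValueError("density grid is empty")
    if any(d <= 0 or d > 1 for d in densities):
        raise ValueError(f"densities must lie in (0, 1]: {densities}")
    n = len(network.node_names)
    iu = np.triu_indices(n, k=1)
    w = network.weights[iu]
    order = np.lexsort((iu[1], iu[0], -w))
    edges = np.column_stack([iu[0][order], iu[1][order]])
    counts = []
    for d in densities:
        k = edge_count(d, n)
        if k == 0:
            raise ValueError(f"density {d} retains zero edges for N={n}")
        counts.append(k)
    return BinaryNetworkEnsemble(
        subject_id=network.subject_id,
        node_names=network.node_names,
        densities=densities,
        edge_order=edges,
        edge_counts=tuple(counts),
    )


@dataclass(frozen=True)
class AdmissionCriteria:
    """Thresholds a binarized density must exceed to be admitted."""

    min_connected_fraction: float = 0.8
    min_modularity: float = 0.3
    min_sigma: float = 1.0
    #: "nonisolated": fraction of nodes with degree >= 1 (default reading);
    #: "giant": fraction of nodes in the largest connected component.
    connectivity: str = "nonisolated"


@dataclass
class AdmissionResult:
    connected_fraction: float
    modularity: float
    sigma: float
    passes: bool


def connected_fraction(graph, mode: str = "nonisolated") -> float:
    A = gm.as_adjacency(graph)
    n = A.shape[0]
    if mode == "nonisolated":
        return float((A.sum(axis=1) > 0).mean())
    if mode == "giant":
        G = gm.as_graph(A)
        return max(len(c) for c in nx.connected_components(G)) / n
    raise ValueError(f"unknown connectivity mode {mode!r}")


def best_modularity(graph, seed: int = 0, restarts: int = 10) -> float:
    """Best-of-restarts Louvain modularity of a binary graph."""
    G = gm.as_graph(graph)
    if G.number_of_edges() == 0:
        return 0.0
    best = -np.inf
    for r in range(restarts):
        parts = nx.community.louvain_communities(G, seed=seed + r)
        q = nx.community.modularity(G, parts)
        best = max(best, q)
    return float(best)


def admission_check(
    graph,
    null_ensemble: gm.NullEnsemble | None = None,
    criteria: AdmissionCriteria = AdmissionCriteria(),
    seed: int = 0,
    n_nulls: int = 20,
    swaps_per_edge: int = 10,
    restarts: int = 10,
) -> AdmissionResult:
    """Evaluate the three admission diagnostics on one binarized graph.

    A null ensemble may be supplied (e.g. shared across calls); otherwise a
    degree-preserving ensemble of ``n_nulls`` graphs is generated.
    """
    A = gm.as_adjacency(graph)
    frac = connected_fraction(A, criteria.connectivity)
    q = best_modularity(A, seed=seed, restarts=restarts)
    if null_ensemble is None:
        null_ensemble = gm.random_reference(
            A, n_nulls=n_nulls, swaps_per_edge=swaps_per_edge, seed=seed
        )
    _, _, sigma = gm.normalized_smallworld(A, null_ensemble)
    passes = (
        frac > criteria.min_connected_fraction
        and q > criteria.min_modularity
        and (np.isfinite(sigma) and sigma > criteria.min_sigma)
    )
    return AdmissionResult(
        connected_fraction=frac, modularity=q, sigma=float(sigma), passes=bool(passes)
    )


@dataclass
class DensityRange:
    """Admitted density interval with the per-density cohort diagnostics."""

    min_density: float
    max_density: float
    step: float
    diagnostics: pd.DataFrame = field(repr=False)

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.min_density, self.max_density)


def determine_density_range(
    ensembles: list[BinaryNetworkEnsemble],
    criteria: AdmissionCriteria = AdmissionCriteria(),
    aggregate: str = "mean",
    seed: int = 0,
    n_nulls: int = 20,
    swaps_per_edge: int = 10,
    restarts: int = 10,
) -> DensityRange:
    """Find the longest contiguous run of densities admitted for the cohort.

    Diagnostics are computed per subject at each grid density and, under the
    default ``aggregate="mean"``, the criteria are applied to the cohort
    means; ``aggregate="all"`` requires every individual subject to pass.
    Raises if no density is admitted.
    """
    if not ensembles:
        raise ValueError("no subjects given")
    grid = ensembles[0].densities
    for e in ensembles:
        if e.densities != grid:
            raise ValueError("all subjects must share one density grid")
    if aggregate not in ("mean", "all"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.generate_state(len(ensembles))
    rows = []
    passes = []
    for di, d in enumerate(grid):
        res = [
            admission_check(
                e.adjacency(d),
                criteria=criteria,
                seed=int(subj_seeds[si] % 2**31) + di,
                n_nulls=n_nulls,
                swaps_per_edge=swaps_per_edge,
                restarts=restarts,
            )
            for si, e in enumerate(ensembles)
        ]
        frac = np.array([r.connected_fraction for r in res])
        q = np.array([r.modularity for r in res])
        sig = np.array([r.sigma for r in res])
        if aggregate == "mean":
            ok = (
                frac.mean() > criteria.min_connected_fraction
                and q.mean() > criteria.min_modularity
                and np.isfinite(np.nanmean(sig))
                and np.nanmean(sig) > criteria.min_sigma
            )
        else:
            ok = all(r.passes for r in res)
        rows.append(
            {
                "density": d,
                "connected_fraction": frac.mean(),
                "modularity": q.mean(),
                "sigma": float(np.nanmean(sig)),
                "admitted": bool(ok),
            }
        )
        passes.append(bool(ok))
    diag = pd.DataFrame(rows)
    best_run = _longest_true_run(passes)
    if best_run is None:
        raise ValueError(
            "no density on the grid satisfies the admission criteria; "
            "review the grid or relax the criteria"
        )
    lo, hi = best_run
    step = float(np.median(np.diff(grid))) if len(grid) > 1 else 0.0
    return DensityRange(
        min_density=float(grid[lo]),
        max_density=float(grid[hi]),
        step=step,
        diagnostics=diag,
    )


def _longest_true_run(flags: list[bool]) -> tuple[int, int] | None:
    best = None
    start = None
    for i, f in enumerate(flags + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    return best


def write_edge_list(network: WeightedSimilarityNetwork, path) -> None:
    """Export a weighted network as a tab-separated edge list."""
    n = len(network.node_names)
    iu = np.triu_indices(n, k=1)
    df = pd.DataFrame(
        {
            "node_a": [network.node_names[i] for i in iu[0]],
            "node_b": [network.node_names[j] for j in iu[1]],
            "weight": network.weights[iu],
        }
    )
    df.to_csv(path, sep="\t", index=False)
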