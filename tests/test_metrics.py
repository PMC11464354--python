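import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from scnkit import metrics as gm

from . import oracles as orc


def path3():
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
    return A


class TestClosedForms:
    def test_triangle(self):
        A = np.ones((3, 3)) - np.eye(3)
        C, L = gm.clustering_and_path(A)
        assert (C, L) == (1.0, 1.0)

    def test_three_node_path(self):
        C, L = gm.clustering_and_path(path3())
        assert C == 0.0
        assert L == pytest.approx(4 / 3)  # distances 1,1,2 over pairs

    def test_efficiencies_complete_graph(self):
        A = np.ones((5, 5)) - np.eye(5)
        eglob, eloc, nodal = gm.efficiencies(A)
        assert eglob == pytest.approx(1.0)
        assert eloc == pytest.approx(1.0)
        assert np.allclose(nodal, 1.0)

    def test_efficiencies_three_node_path(self):
        eglob, eloc, _ = gm.efficiencies(path3())
        assert eglob == pytest.approx((1 + 1 + 0.5) / 3)
        assert eloc == 0.0  # no node has two interconnected neighbors

    def test_betweenness_path_center_and_star_hub(self):
        deg, btw = gm.centralities(path3())
        assert deg[1] == 2 and btw[1] == 1.0
        star = nx.star_graph(3)  # hub + 3 leaves
        _, btw = gm.centralities(star)
        assert btw[0] == 3.0  # three leaf pairs route through the hub

    def test_assortativity_star_is_minus_one(self):
        assert gm.assortativity(nx.star_graph(3)) == pytest.approx(-1.0)

    def test_assortativity_regular_graph_is_nan(self):
        ring = nx.cycle_graph(6)  # 2-regular
        assert math.isnan(gm.assortativity(ring))

    def test_too_small_graphs_rejected(self):
        with pytest.raises(ValueError):
            gm.clustering_and_path(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            gm.assortativity(np.zeros((3, 3)))

    def test_disconnected_pairs_excluded_from_L_zero_in_eglob(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1  # two disjoint edges
        C, L = gm.clustering_and_path(A)
        assert L == 1.0  # only reachable pairs counted
        eglob, _, _ = gm.efficiencies(A)
        assert eglob == pytest.approx(4 / 12)  # 4 ordered reachable pairs


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_all_metrics_match_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        A = orc.random_adjacency(rng, n, float(rng.uniform(0.15, 0.75)))
        C, L = gm.clustering_and_path(A)
        assert C == pytest.approx(orc.clustering_oracle(A), abs=1e-12)
        Lo = orc.path_length_oracle(A)
        assert (math.isnan(L) and math.isnan(Lo)) or L == pytest.approx(Lo, abs=1e-12)
        eglob, eloc, nodal = gm.efficiencies(A)
        assert eglob == pytest.approx(orc.global_efficiency_oracle(A), abs=1e-12)
        elo, nodal_o = orc.local_efficiency_oracle(A)
        assert eloc == pytest.approx(elo, abs=1e-12)
        assert np.allclose(nodal, nodal_o, atol=1e-12)
        deg, btw = gm.centralities(A)
        assert np.allclose(deg, A.sum(axis=1))
        assert np.allclose(btw, orc.betweenness_oracle(A), atol=1e-9)
        if A.sum() > 0:
            r = gm.assortativity(A)
            ro = orc.assortativity_oracle(A)
            assert (math.isnan(r) and math.isnan(ro)) or r == pytest.approx(
                ro, abs=1e-9
            )


class TestNullModels:
    def test_degree_sequences_preserved(self, rng):
        A = orc.random_adjacency(rng, 30, 0.2)
        nulls = gm.random_reference(A, n_nulls=10, seed=4)
        src = sorted(A.sum(axis=1))
        for g in nulls.graphs:
            assert sorted(g.sum(axis=1)) == src

    def test_complete_graph_unrewirable(self):
        A = np.ones((6, 6)) - np.eye(6)
        nulls = gm.random_reference(A, n_nulls=3, seed=0)
        assert not nulls.rewired
        for g in nulls.graphs:
            assert np.array_equal(g, A)

    def test_lattice_nulls_lose_clustering(self):
        G = nx.watts_strogatz_graph(76, 8, 0.0, seed=0)
        C_src, _ = gm.clustering_and_path(G)
        nulls = gm.random_reference(G, n_nulls=20, seed=1)
        assert nulls.clustering.mean() < C_src

    def test_self_ensemble_normalizes_to_one(self, rng):
        A = orc.random_adjacency(rng, 20, 0.3)
        C, L = gm.clustering_and_path(A)
        nulls = gm.NullEnsemble(
            graphs=[A], clustering=np.array([C]), path_length=np.array([L]),
            seed=0, rewired=False,
        )
        gamma, lam, sigma = gm.normalized_smallworld(A, nulls)
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_lattice_sigma_exceeds_one(self):
        G = nx.watts_strogatz_graph(76, 8, 0.0, seed=0)
        nulls = gm.random_reference(G, n_nulls=10, seed=2)
        *_, sigma = gm.normalized_smallworld(G, nulls)
        assert sigma > 1.5

    def test_er_graph_close_to_own_null(self):
        sigmas = []
        for seed in range(10):
            G = nx.erdos_renyi_graph(76, 0.2, seed=seed)
            nulls = gm.random_reference(G, n_nulls=10, seed=seed)
            *_, s = gm.normalized_smallworld(G, nulls)
            sigmas.append(s)
        assert 0.8 <= np.mean(sigmas) <= 1.2

    def test_determinism_given_seed(self, rng):
        A = orc.random_adjacency(rng, 25, 0.25)
        n1 = gm.random_reference(A, n_nulls=5, seed=9)
        n2 = gm.random_reference(A, n_nulls=5, seed=9)
        for g1, g2 in zip(n1.graphs, n2.graphs):
            assert np.array_equal(g1, g2)


class TestAUC:
    def test_constant_curve(self):
        grid = np.round(np.arange(0.10, 0.341, 0.01), 2)
        assert gm.auc_over_density(np.ones_like(grid), grid, (0.10, 0.34)) == (
            pytest.approx(0.24)
        )

    def test_linear_ramp_triangle_area(self):
        grid = np.round(np.arange(0.10, 0.341, 0.01), 2)
        vals = (grid - 0.10) / 0.24
        assert gm.auc_over_density(vals, grid, (0.10, 0.34)) == pytest.approx(0.12)

    def test_matches_reference_summation(self, rng):
        grid = np.round(np.arange(0.05, 0.51, 0.01), 2)
        vals = rng.normal(size=grid.size)
        got = gm.auc_over_density(vals, grid, (0.11, 0.42))
        mask = (grid >= 0.11 - 1e-9) & (grid <= 0.42 + 1e-9)
        want = orc.trapezoid_oracle(list(grid[mask]), list(vals[mask]))
        assert got == pytest.approx(want, abs=1e-12)

    def test_missing_grid_points_rejected(self):
        with pytest.raises(ValueError, match="not on the grid"):
            gm.auc_over_density([1.0, 1.0], [0.1, 0.2], (0.1, 0.25))
        with pytest.raises(ValueError, match="strictly increasing"):
            gm.auc_over_density([1.0, 1.0], [0.2, 0.1], (0.1, 0.2))


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=hs.integers(0, 10_000))
    def test_metrics_invariant_under_node_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 14))
        A = orc.random_adjacency(rng, n, 0.4)
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        B = P @ A @ P.T
        assert gm.clustering_and_path(A) == pytest.approx(
            gm.clustering_and_path(B), nan_ok=True
        )
        ea, eb = gm.efficiencies(A), gm.efficiencies(B)
        assert ea[:2] == pytest.approx(eb[:2])
        assert np.allclose(np.sort(ea[2]), np.sort(eb[2]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=hs.integers(0, 10_000))
    def test_adding_edge_monotone_for_eglob_and_degree(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        A = orc.random_adjacency(rng, n, 0.3)
        free = [(i, j) for i in range(n) for j in range(i + 1, n) if not A[i, j]]
        if not free:
            return
        i, j = free[int(rng.integers(len(free)))]
        B = A.copy()
        B[i, j] = B[j, i] = 1
        assert gm.efficiencies(B)[0] >= gm.efficiencies(A)[0] - 1e-12
        assert B.sum(axis=1)[i] == A.sum(axis=1)[i] + 1

    def test_smallworld_sigma_watts_strogatz(self):
        """sigma > 1 for rewired ring lattices in nearly all seeds."""
        wins = 0
        trials = 50
        for seed in range(trials):
            G = nx.watts_strogatz_graph(76, 8, 0.1, seed=seed)
            nulls = gm.random_reference(G, n_nulls=8, seed=seed)
            *_, sigma = gm.normalized_smallworld(G, nulls)
            wins += sigma > 1
        assert wins >= 0.95 * trials
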