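"""MST construction and tree metrics: oracles, closed forms, identities."""

import itertools

import networkx as nx
import numpy as np
import pytest

from phasetree.topology import (
    GlobalMetrics,
    SpanningTree,
    betweenness,
    degree_divergence,
    invert_weights,
    kruskal_mst,
    leaf_fraction,
    subject_average,
    tree_metrics,
)


def _random_weights(n, rng):
    w = rng.uniform(0.5, 10.0, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, np.inf)
    return w


def _star_tree(n):
    return SpanningTree(n, [(0, j) for j in range(1, n)])


def _path_tree(n):
    return SpanningTree(n, [(i, i + 1) for i in range(n - 1)])


class TestInvertWeights:
    def test_reciprocal_and_sentinel(self):
        adj = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 1.0], [0.0, 1.0, 0.0]])
        w = invert_weights(adj)
        assert w[0, 1] == 2.0
        assert w[1, 2] == 1.0
        assert np.isinf(w[0, 2])  # PLI = 0 -> heavier than any finite edge
        assert np.all(np.isinf(np.diag(w)))


class TestKruskal:
    def test_exhaustive_minimum_small_graphs(self):
        """Kruskal total weight equals the minimum over all spanning trees
        (enumerated by brute force) for 40 random graphs with N <= 6."""
        rng = np.random.default_rng(99)
        for trial in range(40):
            n = int(rng.integers(3, 7))
            w = _random_weights(n, rng)
            tree = kruskal_mst(w)
            got = w[tree.edges[:, 0], tree.edges[:, 1]].sum()
            all_edges = list(itertools.combinations(range(n), 2))
            best = np.inf
            for subset in itertools.combinations(all_edges, n - 1):
                g = nx.Graph(subset)
                if g.number_of_nodes() == n and nx.is_connected(g):
                    best = min(best, sum(w[i, j] for i, j in subset))
            assert got == pytest.approx(best)

    def test_matches_networkx_on_larger_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 30
            w = _random_weights(n, rng)
            tree = kruskal_mst(w)
            g = nx.Graph()
            for i in range(n):
                for j in range(i + 1, n):
                    g.add_edge(i, j, weight=w[i, j])
            ref = nx.minimum_spanning_tree(g, algorithm="kruskal")
            got = w[tree.edges[:, 0], tree.edges[:, 1]].sum()
            assert got == pytest.approx(ref.size(weight="weight"))

    def test_ninety_nodes_gives_89_edges_connected_acyclic(self):
        tree = kruskal_mst(_random_weights(90, np.random.default_rng(1)))
        assert tree.edges.shape == (89, 2)
        g = nx.Graph(tree.edges.tolist())
        assert nx.is_tree(g) and g.number_of_nodes() == 90

    def test_planted_path_is_recovered(self):
        # weights chosen so the path edges are the three lightest compatible
        w = np.full((4, 4), 5.0)
        np.fill_diagonal(w, np.inf)
        for k, (i, j) in enumerate([(0, 1), (1, 2), (2, 3)]):
            w[i, j] = w[j, i] = 1.0 + 0.1 * k
        tree = kruskal_mst(w)
        assert sorted(map(tuple, tree.edges.tolist())) == [(0, 1), (1, 2), (2, 3)]

    def test_tie_break_is_deterministic(self):
        w = np.ones((8, 8))
        np.fill_diagonal(w, np.inf)
        t1, t2 = kruskal_mst(w), kruskal_mst(w.copy())
        assert np.array_equal(t1.edges, t2.edges)
        # stable (weight, i, j) order on all-equal weights picks the star at 0
        assert sorted(map(tuple, t1.edges.tolist())) == [(0, j) for j in range(1, 8)]

    def test_wrong_edge_count_rejected(self):
        with pytest.raises(ValueError):
            SpanningTree(4, [(0, 1), (2, 3)])


class TestClosedForms:
    @pytest.mark.parametrize(
        "tree, L, K",
        [
            (_star_tree(4), 0.75, 2.0),
            (_path_tree(4), 0.5, 5 / 3),
            (_star_tree(90), 89 / 90, 45.0),
        ],
    )
    def test_star_and_path(self, tree, L, K):
        assert leaf_fraction(tree) == pytest.approx(L)
        assert degree_divergence(tree) == pytest.approx(K)

    @pytest.mark.parametrize("n", [4, 10, 50, 90])
    def test_general_n_formulas(self, n):
        assert degree_divergence(_star_tree(n)) == pytest.approx(n / 2)
        assert degree_divergence(_path_tree(n)) == pytest.approx((2 * n - 3) / (n - 1))
        assert degree_divergence(_star_tree(n)) > degree_divergence(_path_tree(n))


class TestBetweenness:
    def test_star_center_and_leaves(self):
        bc = betweenness(_star_tree(4))
        assert bc[0] == pytest.approx(0.5)  # 3 leaf pairs / 6 total pairs
        assert np.all(bc[1:] == 0)

    def test_path_of_three(self):
        bc = betweenness(_path_tree(3))
        assert bc[1] == pytest.approx(1 / 3)
        assert bc[0] == bc[2] == 0

    @pytest.mark.parametrize("n", [5, 20, 90])
    def test_star_center_general(self, n):
        assert betweenness(_star_tree(n))[0] == pytest.approx((n - 2) / n)

    def test_matches_networkx_convention_up_to_normalization(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 30))
            tree = kruskal_mst(_random_weights(n, rng))
            g = nx.Graph(tree.edges.tolist())
            ref = nx.betweenness_centrality(g, normalized=False)
            expected = np.array([ref[v] for v in range(n)]) / (n * (n - 1) / 2)
            assert np.allclose(betweenness(tree), expected)

    def test_tree_identities(self):
        """Degree sum = 2(N-1); total through-path count equals the sum over
        pairs of (path length - 1)."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(4, 25))
            tree = kruskal_mst(_random_weights(n, rng))
            assert tree.degrees.sum() == 2 * (n - 1)
            g = nx.Graph(tree.edges.tolist())
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            interior = sum(
                lengths[s][t] - 1 for s in range(n) for t in range(s + 1, n)
            )
            total = betweenness(tree).sum() * (n * (n - 1) / 2)
            assert total == pytest.approx(interior)


class TestSubjectAverage:
    def test_identical_epochs_average_to_themselves(self):
        g = GlobalMetrics(0.6, 2.2)
        bc = np.array([0.1, 0.0, 0.3])
        sm = subject_average([(g, bc)] * 10, "s1", "beta")
        assert sm.n_epochs == 10
        assert sm.leaf_fraction == pytest.approx(0.6)
        assert np.allclose(sm.betweenness, bc)

    def test_arithmetic_mean(self):
        pairs = [
            (GlobalMetrics(0.5, 2.0), np.zeros(3)),
            (GlobalMetrics(0.7, 3.0), np.ones(3)),
        ]
        sm = subject_average(pairs, "s1", "beta")
        assert sm.leaf_fraction == pytest.approx(0.6)
        assert sm.degree_divergence == pytest.approx(2.5)
        assert np.allclose(sm.betweenness, 0.5)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            subject_average([], "s1", "beta")
        with pytest.raises(ValueError):
            subject_average(
                [(GlobalMetrics(0.5, 2.0), np.zeros(3)),
                 (GlobalMetrics(0.5, 2.0), np.zeros(4))],
                "s1", "beta",
            )


def test_ground_truth_star_recovery_noise_free(tiny_spec):
    """Noise-free star coupling: the beta-band MST recovers the true star."""
    import dataclasses

    from phasetree import pli_matrix, subject_phase_epochs
    from phasetree.synthdata import CouplingGraph, generate_subject

    spec = dataclasses.replace(
        tiny_spec,
        noise_sd=0.0,
        coupling_graph_controls=CouplingGraph("star", 1.0),
    )
    rec = generate_subject(spec, "control", np.random.default_rng(4))
    pes = subject_phase_epochs(
        rec.data, rec.fs, pad_seconds=rec.pad_seconds, target_fs=None,
        epoch_length=spec.epoch_length, n_epochs=1,
    )
    beta = next(pe for pe in pes if pe.band.name == "beta")
    tree = kruskal_mst(invert_weights(pli_matrix(beta)))
    got = {tuple(sorted(e)) for e in tree.edges.tolist()}
    assert got == {(0, j) for j in range(1, spec.n_rois)}


def test_star_cohorts_have_higher_k_than_chain(tiny_spec):
    """Monotone contrast: star coupling yields broader degree distributions
    (higher K) than chain coupling at equal noise."""
    star_k = []
    chain_k = []
    for seed in range(6):
        for topo, sink in (("star", star_k), ("chain", chain_k)):
            import dataclasses

            from phasetree import pli_matrix, subject_phase_epochs
            from phasetree.synthdata import CouplingGraph, generate_subject

            spec = dataclasses.replace(
                tiny_spec, coupling_graph_controls=CouplingGraph(topo, 0.8)
            )
            rec = generate_subject(spec, "control", np.random.default_rng(100 + seed))
            pes = subject_phase_epochs(
                rec.data, rec.fs, pad_seconds=rec.pad_seconds, target_fs=None,
                epoch_length=spec.epoch_length, n_epochs=spec.n_epochs,
            )
            ks = [
                tree_metrics(pli_matrix(pe))[0].degree_divergence
                for pe in pes if pe.band.name == "beta"
            ]
            sink.append(np.mean(ks))
    assert np.mean(star_k) > np.mean(chain_k)
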