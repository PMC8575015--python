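import numpy as np
import networkx as nx
import pytest

from markerpanel import (
    ExpressionMatrix,
    mutual_information,
    build_network,
    detect_modules,
    modularity,
    annotate_modules,
    simulate_expression,
    default_spec,
)
from markerpanel.network import CellTypeNetwork


def net_from_graph(G):
    m = len(G)
    return CellTypeNetwork(nodes=tuple(G.nodes), mi=np.zeros((m, m)),
                           cutoff=0.0, graph=G)


class TestMutualInformation:
    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert abs(mutual_information(x, y) - mutual_information(y, x)) <= 1e-9

    def test_independent_vectors_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals.append(mutual_information(rng.normal(size=200),
                                           rng.normal(size=200)))
        assert np.mean(vals) < 0.05

    def test_self_dependence_dominates_shuffles(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        self_mi = mutual_information(x, x)
        for _ in range(5):
            assert self_mi >= mutual_information(x, rng.permutation(x))

    def test_strong_dependence_beats_independent_baseline(self):
        gains = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            dep = mutual_information(x, 2 * x + 0.1 * rng.normal(size=200))
            ind = mutual_information(x, rng.normal(size=200))
            gains.append(dep - ind)
        assert np.mean(gains) > 0.5

    def test_permutation_null_indistinguishable(self):
        # paired comparison over seeds: independent draws vs permuted pairing
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=120), rng.normal(size=120)
            diffs.append(mutual_information(x, y)
                         - mutual_information(x, rng.permutation(y)))
        # mean difference within 2 standard errors of zero
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) <= 2 * se + 1e-9

    def test_constant_vector_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones(10), np.arange(10.0)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.arange(2.0), np.arange(2.0))


class TestBuildNetwork:
    @pytest.fixture
    def em(self):
        em, _ = simulate_expression(default_spec(m=6, n_background=30, seed=5))
        return em

    def test_infinite_cutoff_gives_edgeless(self, em):
        net = build_network(em, list(em.gene_ids), cutoff=np.inf)
        assert net.graph.number_of_edges() == 0
        assert net.graph.number_of_nodes() == em.m

    def test_negative_cutoff_gives_complete_graph(self, em):
        net = build_network(em, list(em.gene_ids), cutoff=-1.0)
        assert net.graph.number_of_edges() == em.m * (em.m - 1) // 2

    def test_cutoff_monotone_in_edge_count(self, em):
        counts = [build_network(em, list(em.gene_ids), cutoff=c).graph.number_of_edges()
                  for c in (0.0, 0.25, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_duplicated_profiles_have_max_offdiagonal_mi(self, em):
        S = em.S.copy()
        S[1] = S[0]
        dup = ExpressionMatrix(em.cell_type_ids, em.gene_ids, S)
        net = build_network(dup, list(em.gene_ids), cutoff=0.25)
        off = net.mi.copy()
        np.fill_diagonal(off, -np.inf)
        i, j = np.unravel_index(np.argmax(off), off.shape)
        assert {i, j} == {0, 1}

    def test_mi_matrix_symmetric_with_dominant_diagonal(self, em):
        net = build_network(em, list(em.gene_ids), cutoff=0.25)
        np.testing.assert_allclose(net.mi, net.mi.T, atol=1e-9)
        assert np.all(np.diag(net.mi) >= net.mi.max(axis=1) - 1e-9)

    def test_missing_panel_gene_rejected(self, em):
        with pytest.raises(ValueError, match="missing"):
            build_network(em, ["nope"], cutoff=0.25)

    def test_small_panel_warns(self, em):
        with pytest.warns(UserWarning, match="small"):
            build_network(em, list(em.gene_ids[:3]), cutoff=0.25)


class TestDetectModules:
    def test_two_disconnected_triangles(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f")])
        modules, Q = detect_modules(net_from_graph(G))
        assert sorted(sorted(m) for m in modules) == [["a", "b", "c"], ["d", "e", "f"]]
        assert Q == pytest.approx(0.5)

    def test_complete_graph_has_no_structure(self):
        G = nx.relabel_nodes(nx.complete_graph(5), str)
        modules, Q = detect_modules(net_from_graph(G))
        assert len(modules) == 1
        assert Q == pytest.approx(0.0)

    def test_triangle_plus_isolate(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        G.add_node("z")
        modules, Q = detect_modules(net_from_graph(G))
        assert sorted(sorted(m) for m in modules) == [["a", "b", "c"], ["z"]]
        assert Q == pytest.approx(0.0)  # e_11=1, a_1=1 -> 1-1=0

    def test_edgeless_graph_convention(self):
        G = nx.Graph()
        G.add_nodes_from("abc")
        modules, Q = detect_modules(net_from_graph(G))
        assert len(modules) == 3 and Q == 0.0

    def test_q_matches_independent_recomputation(self):
        rng = np.random.default_rng(2)
        G = nx.gnp_random_graph(12, 0.3, seed=4)
        G = nx.relabel_nodes(G, str)
        net = net_from_graph(G)
        modules, Q = detect_modules(net)
        # independent recomputation from the adjacency matrix
        A = nx.to_numpy_array(G, nodelist=sorted(G.nodes))
        order = {n: i for i, n in enumerate(sorted(G.nodes))}
        two_E = A.sum()
        q = 0.0
        for mod in modules:
            idx = [order[n] for n in mod]
            e_in = A[np.ix_(idx, idx)].sum() / two_E
            a = A[idx, :].sum() / two_E
            q += e_in - a**2
        assert Q == pytest.approx(q, abs=1e-9)
        assert -0.5 <= Q < 1

    def test_partition_covers_all_nodes(self):
        G = nx.relabel_nodes(nx.karate_club_graph(), str)
        modules, _ = detect_modules(net_from_graph(G))
        nodes = [n for mod in modules for n in mod]
        assert sorted(nodes) == sorted(G.nodes)
        assert len(nodes) == len(set(nodes))


class TestAnnotateModules:
    def test_frequency_ranking(self):
        modules = [{"n1", "n2", "n3", "n4", "n5", "n6"}]
        labels = dict(n1="T", n2="T", n3="T", n4="B", n5="B", n6="NK")
        assert annotate_modules(modules, labels) == [[("T", 3), ("B", 2), ("NK", 1)]]

    def test_truncates_to_top_five(self):
        modules = [set(f"n{i}" for i in range(7))]
        labels = {f"n{i}": f"L{i}" for i in range(7)}
        out = annotate_modules(modules, labels)
        assert len(out[0]) == 5

    def test_tie_break_lexicographic(self):
        modules = [{"a", "b"}]
        assert annotate_modules(modules, {"a": "x", "b": "w"}) == [[("w", 1), ("x", 1)]]

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="n2"):
            annotate_modules([{"n1", "n2"}], {"n1": "T"})
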