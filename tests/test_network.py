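"""Incidence matrix, Dice coefficients, network construction, MST, Louvain."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from termshift.corpus import AnalyzedRecord
from termshift.network import (
    IncidenceMatrix,
    build_incidence,
    build_network,
    detect_communities,
    dice,
    dice_matrix,
    export_graphml,
    load_graphml,
    max_spanning_tree,
    min_frequency_at_threshold,
    seed_cooccurring_terms,
)


def _analyzed(rows, period="post"):
    return [
        AnalyzedRecord(f"r{i}", "2019-01", terms, period) for i, terms in enumerate(rows)
    ]


def _seed_matrix(n, freqs: dict[str, int], seed="seed") -> IncidenceMatrix:
    """Seed in all n records; each term in its first `freq` records."""
    rows = [[seed] + [t for t, f in freqs.items() if i < f] for i in range(n)]
    return build_incidence(_analyzed(rows))


class TestIncidence:
    def test_multiplicity_binarized(self):
        m = build_incidence(_analyzed([["a", "a", "a", "b"]]))
        assert m.X.tolist() == [[1, 1]]

    def test_matches_hand_enumeration(self):
        m = build_incidence(_analyzed([["a", "c"], ["b", "c"]]))
        assert m.terms == ["a", "b", "c"]
        assert m.X.tolist() == [[1, 0, 1], [0, 1, 1]]

    def test_column_sum_is_record_frequency(self):
        rows = [["t"] if i < 4 else ["u"] for i in range(10)]
        m = build_incidence(_analyzed(rows))
        assert m.term_frequency("t") == 4

    def test_empty_vocabulary_errors(self):
        with pytest.raises(ValueError, match="vocabulary"):
            build_incidence(_analyzed([[], []]))


class TestDice:
    def test_self_dice_is_one(self):
        m = build_incidence(_analyzed([["a", "b"], ["a"]]))
        assert dice(m, "a", "a") == 1.0

    def test_disjoint_is_zero(self):
        m = build_incidence(_analyzed([["a"], ["b"]]))
        assert dice(m, "a", "b") == 0.0

    def test_seed_reduction_closed_form(self):
        # seed present everywhere: dice(seed, t) = 2f / (n + f)
        n = 57
        m = _seed_matrix(n, {"t": 13, "u": 40})
        for t, f in (("t", 13), ("u", 40)):
            assert dice(m, "seed", t) == pytest.approx(2 * f / (n + f))

    def test_symmetry_range_monotonicity_random(self):
        rng = np.random.default_rng(3)
        X = (rng.random((30, 6)) < 0.4).astype(np.uint8)
        X[:, 0] = 1  # avoid empty columns warning path
        m = IncidenceMatrix(
            [f"r{i}" for i in range(30)],
            list("abcdef"),
            X,
            ["post"] * 30,
        )
        D = dice_matrix(m)
        assert np.allclose(D.values, D.values.T)
        assert ((D.values >= 0) & (D.values <= 1.0 + 1e-12)).all()
        for a, b in itertools.combinations(m.terms, 2):
            assert dice(m, a, b) == pytest.approx(D.loc[a, b])


class TestSeedTable:
    def test_rows_match_closed_form(self):
        n = 200
        freqs = {"alpha": 150, "beta": 60, "gamma": 20}
        m = _seed_matrix(n, freqs)
        table = seed_cooccurring_terms(m, "seed", theta=0.3)
        # gamma: dice = 40/220 = 0.182 < 0.3 -> excluded
        assert list(table["term"]) == ["alpha", "beta"]
        row = table.set_index("term").loc["alpha"]
        assert row["dice"] == pytest.approx(round(2 * 150 / (n + 150), 3))
        assert row["share_pct"] == 75.0

    def test_threshold_algebra(self):
        n = 100
        f_min = min_frequency_at_threshold(n, 0.3)  # ceil(0.3n/1.7)
        assert f_min == 18
        m = _seed_matrix(n, {"just": f_min, "below": f_min - 1})
        table = seed_cooccurring_terms(m, "seed", theta=0.3)
        assert list(table["term"]) == ["just"]

    def test_paper_scale_minimum_frequency(self):
        assert min_frequency_at_threshold(1353, 0.3) == 239


class TestBuildNetwork:
    def test_chain_component(self):
        # seed-A 0.4, A-B 0.35, B-C 0.1: C falls outside the component
        rows = (
            [["seed", "a"]] * 4
            + [["seed"]] * 2
            + [["a", "b"]] * 2
            + [["b"]]
            + [["c"]] * 10
            + [["b", "c"]]
        )
        m = build_incidence(_analyzed(rows))
        G = build_network(m, "seed", theta=0.3)
        assert set(G.nodes) == {"seed", "a", "b"}
        assert G.number_of_edges() == 2

    def test_theta_one_isolates_seed(self):
        m = _seed_matrix(10, {"t": 5})
        G = build_network(m, "seed", theta=1.0)
        assert set(G.nodes) == {"seed"}

    def test_node_frequency_attribute(self):
        m = _seed_matrix(10, {"t": 6})
        G = build_network(m, "seed", theta=0.3)
        assert G.nodes["t"]["frequency"] == 6

    def test_component_matches_bfs_oracle(self):
        rng = np.random.default_rng(11)
        X = (rng.random((40, 8)) < 0.35).astype(np.uint8)
        X[:, 0] = 1
        terms = [f"t{i}" for i in range(8)]
        m = IncidenceMatrix([f"r{i}" for i in range(40)], terms, X, ["post"] * 40)
        theta = 0.45
        G = build_network(m, "t0", theta)
        # oracle: explicit pairwise dice + BFS from the seed
        adj = {t: set() for t in terms}
        for a, b in itertools.combinations(terms, 2):
            if dice(m, a, b) >= theta:
                adj[a].add(b)
                adj[b].add(a)
        seen, stack = {"t0"}, ["t0"]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        assert set(G.nodes) == seen


def _random_weighted_graph(rng, n):
    G = nx.Graph()
    nodes = [f"n{i}" for i in range(n)]
    G.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < 0.7:
            G.add_edge(a, b, dice=float(rng.random()))
    if not nx.is_connected(G):
        comps = list(nx.connected_components(G))
        for c1, c2 in zip(comps, comps[1:]):
            G.add_edge(min(c1), min(c2), dice=float(rng.random()))
    return G


class TestMaxSpanningTree:
    def test_triangle_drops_weakest(self):
        G = nx.Graph()
        G.add_edge("a", "b", dice=0.9)
        G.add_edge("b", "c", dice=0.8)
        G.add_edge("a", "c", dice=0.7)
        T = max_spanning_tree(G)
        assert set(map(frozenset, T.edges)) == {
            frozenset({"a", "b"}),
            frozenset({"b", "c"}),
        }

    def test_tree_input_identity(self):
        G = nx.Graph()
        G.add_edge("a", "b", dice=0.5)
        G.add_edge("b", "c", dice=0.4)
        T = max_spanning_tree(G)
        assert set(T.edges) == set(G.edges)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 6):
            for _ in range(5):
                G = _random_weighted_graph(rng, n)
                T = max_spanning_tree(G)
                assert T.number_of_edges() == n - 1
                got = sum(d["dice"] for _, _, d in T.edges(data=True))
                best = -1.0
                edges = list(G.edges(data="dice"))
                for subset in itertools.combinations(edges, n - 1):
                    H = nx.Graph()
                    H.add_nodes_from(G.nodes)
                    H.add_edges_from((u, v) for u, v, _ in subset)
                    if nx.is_connected(H):
                        best = max(best, sum(w for _, _, w in subset))
                assert got == pytest.approx(best)

    def test_disconnected_input_errors(self):
        G = nx.Graph()
        G.add_edge("a", "b", dice=0.5)
        G.add_node("c")
        with pytest.raises(ValueError, match="connected"):
            max_spanning_tree(G)


def _two_cliques(weak=0.1, strong=0.9):
    G = nx.Graph()
    for block in ("abcd", "efgh"):
        for u, v in itertools.combinations(block, 2):
            G.add_edge(u, v, dice=strong)
    G.add_edge("d", "e", dice=weak)
    return G


def _exhaustive_best_partition(G):
    """Maximize modularity over all partitions (Bell-number enumeration)."""
    nodes = list(G.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {first}] + part[i + 1 :]
            yield part + [{first}]

    best, best_q = None, -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(G, part, weight="dice")
        if q > best_q:
            best, best_q = part, q
    return best, best_q


class TestCommunities:
    def test_two_cliques_recovered_vs_exhaustive(self):
        G = _two_cliques()
        expected, expected_q = _exhaustive_best_partition(G)
        part = detect_communities(G, random_seed=0)
        got = {frozenset(c) for c in part.communities()}
        assert got == {frozenset(c) for c in expected}
        assert got == {frozenset("abcd"), frozenset("efgh")}
        assert part.modularity == pytest.approx(expected_q)

    def test_disconnected_components_never_share(self):
        G = nx.Graph()
        G.add_edge("a", "b", dice=0.5)
        G.add_edge("c", "d", dice=0.5)
        part = detect_communities(G, random_seed=0)
        assert part.mapping["a"] == part.mapping["b"]
        assert part.mapping["c"] == part.mapping["d"]
        assert part.mapping["a"] != part.mapping["c"]

    def test_edgeless_singletons(self):
        G = nx.Graph()
        G.add_nodes_from("abc")
        part = detect_communities(G, random_seed=0)
        assert len(set(part.mapping.values())) == 3
        assert part.modularity == 0.0

    def test_deterministic_under_seed(self):
        G = _two_cliques(weak=0.4, strong=0.6)
        p1 = detect_communities(G, random_seed=7)
        p2 = detect_communities(G, random_seed=7)
        assert p1.mapping == p2.mapping

    def test_relabeling_invariance(self):
        G = _two_cliques()
        H = nx.relabel_nodes(G, {n: f"x_{n}" for n in G.nodes})
        pg = detect_communities(G, random_seed=0)
        ph = detect_communities(H, random_seed=0)
        got_g = {frozenset(c) for c in pg.communities()}
        got_h = {frozenset(x[2:] for x in c) for c in ph.communities()}
        assert got_g == got_h

    def test_beats_singleton_partition(self):
        G = _two_cliques()
        part = detect_communities(G, random_seed=0)
        singletons = [{n} for n in G.nodes]
        assert part.modularity >= nx.community.modularity(G, singletons, weight="dice")


class TestGraphml:
    def test_round_trip_preserves_structure(self, tmp_path):
        m = _seed_matrix(20, {"t": 12, "u": 15})
        G = build_network(m, "seed", theta=0.3)
        part = detect_communities(G, random_seed=0)
        path = tmp_path / "net.graphml"
        export_graphml(G, path, part)
        H = load_graphml(path)
        assert set(H.nodes) == set(G.nodes)
        assert H.number_of_edges() == G.number_of_edges()
        for u, v, d in G.edges(data=True):
            assert H.edges[u, v]["dice"] == pytest.approx(d["dice"])
        for n in G.nodes:
            assert H.nodes[n]["community"] == part.mapping[n]
            assert H.nodes[n]["frequency"] == G.nodes[n]["frequency"]

    def test_partitionless_export_omits_community(self, tmp_path):
        m = _seed_matrix(10, {"t": 8})
        G = build_network(m, "seed", theta=0.3)
        path = tmp_path / "net.graphml"
        export_graphml(G, path)
        H = load_graphml(path)
        assert all("community" not in H.nodes[n] for n in H.nodes)

    def test_schema_wellformed_xml(self, tmp_path):
        from lxml import etree

        m = _seed_matrix(10, {"t": 8, "u": 9})
        G = build_network(m, "seed", theta=0.3)
        path = tmp_path / "net.graphml"
        export_graphml(G, path)
        doc = etree.parse(str(path))
        ns = doc.getroot().nsmap[None]
        assert ns == "http://graphml.graphdrawing.org/xmlns"
        assert len(doc.findall(f".//{{{ns}}}node")) == G.number_of_nodes()
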