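"""Communication-network analysis against hand calculations and
exhaustive path enumeration."""

import itertools

import networkx as nx
import numpy as np
import pytest

from allokit.network import (RegionSet, CommunicationPath, PocketDefinition,
                             build_graph, total_edge_weight, betweenness,
                             cross_region_strength, region_center_residue,
                             shortest_path, detect_relays,
                             prioritize_pockets, parse_fpocket_info,
                             export_edge_tsv)
from allokit.nri import LatentInteractionGraph, ordered_pairs


def latent_from_matrix(m: np.ndarray) -> LatentInteractionGraph:
    """Interaction-probability matrix → latent graph (2 edge types)."""
    n = m.shape[0]
    probs = np.array([[1 - m[i, j], m[i, j]] for i, j in ordered_pairs(n)])
    return LatentInteractionGraph(n, probs)


def brute_force_shortest(graph: nx.DiGraph, s: int, t: int):
    """Exhaustive enumeration of all simple paths by −ln(w) length."""
    best, best_d = None, np.inf
    for path in nx.all_simple_paths(graph, s, t):
        d = sum(-np.log(graph.edges[a, b]["weight"])
                for a, b in zip(path[:-1], path[1:]))
        if d < best_d - 1e-12:
            best, best_d = path, d
    return best, best_d


def brute_force_betweenness(graph: nx.DiGraph) -> dict[int, float]:
    """Directed betweenness by explicit enumeration of all shortest
    paths, fractional credit on ties."""
    n = graph.number_of_nodes()
    score = {v: 0.0 for v in graph.nodes}
    for s, t in itertools.permutations(graph.nodes, 2):
        paths, dists = [], []
        for path in nx.all_simple_paths(graph, s, t):
            d = sum(-np.log(graph.edges[a, b]["weight"])
                    for a, b in zip(path[:-1], path[1:]))
            paths.append(path)
            dists.append(d)
        if not paths:
            continue
        dmin = min(dists)
        shortest = [p for p, d in zip(paths, dists) if d < dmin + 1e-12]
        for p in shortest:
            for v in p[1:-1]:
                score[v] += 1.0 / len(shortest)
    norm = (n - 1) * (n - 2)
    return {v: s / norm for v, s in score.items()}


def random_weighted_digraph(rng, n_nodes, p_edge=0.4) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    for i, j in itertools.permutations(range(n_nodes), 2):
        if rng.random() < p_edge:
            g.add_edge(i, j, weight=float(rng.uniform(0.05, 1.0)))
    for a, b, d in g.edges(data=True):
        d["distance"] = -np.log(d["weight"])
    return g


class TestBuildGraph:
    def test_zero_threshold_keeps_all_ordered_pairs(self, rng):
        m = rng.uniform(0.01, 0.99, size=(5, 5))
        np.fill_diagonal(m, 0)
        g = build_graph(latent_from_matrix(m), min_probability=0.0)
        assert g.number_of_edges() == 5 * 4

    def test_high_threshold_empties_graph(self, rng):
        m = rng.uniform(0.01, 0.5, size=(4, 4))
        np.fill_diagonal(m, 0)
        g = build_graph(latent_from_matrix(m), min_probability=0.95)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 4   # nodes always retained

    def test_weights_equal_latent_probabilities(self, rng):
        m = rng.uniform(0.0, 1.0, size=(6, 6))
        np.fill_diagonal(m, 0)
        g = build_graph(latent_from_matrix(m), min_probability=0.5)
        for i, j, d in g.edges(data=True):
            assert d["weight"] == pytest.approx(m[i, j])
            assert m[i, j] >= 0.5

    def test_total_weight_equals_matrix_sum(self, rng):
        m = rng.uniform(0, 1, size=(7, 7))
        np.fill_diagonal(m, 0)
        thr = 0.3
        g = build_graph(latent_from_matrix(m), min_probability=thr)
        expected = m[m >= thr].sum()
        assert total_edge_weight(g) == pytest.approx(expected, rel=1e-9)

    def test_empty_graph_weight_zero(self):
        g = nx.DiGraph()
        assert total_edge_weight(g) == 0.0


class TestBetweenness:
    def test_directed_chain_middle_node(self):
        g = nx.DiGraph()
        for a, b in [(0, 1), (1, 2)]:
            g.add_edge(a, b, weight=0.5, distance=-np.log(0.5))
        g.add_nodes_from([0, 1, 2])
        bt = betweenness(g)
        assert bt[1] == pytest.approx(0.5)   # 1/((3−1)(3−2))
        assert bt[0] == bt[2] == 0.0

    def test_star_center_matches_enumeration(self, rng):
        g = nx.DiGraph()
        for k in range(1, 6):
            for a, b in [(0, k), (k, 0)]:
                w = float(rng.uniform(0.3, 0.9))
                g.add_edge(a, b, weight=w, distance=-np.log(w))
        bt = betweenness(g)
        ref = brute_force_betweenness(g)
        for v in g.nodes:
            assert bt[v] == pytest.approx(ref[v], abs=1e-9)

    def test_random_graphs_match_enumeration(self, rng):
        for _ in range(10):
            g = random_weighted_digraph(rng, int(rng.integers(4, 8)))
            bt = betweenness(g)
            ref = brute_force_betweenness(g)
            for v in g.nodes:
                assert bt[v] == pytest.approx(ref[v], abs=1e-9)

    def test_nonpositive_weight_rejected(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=0.0, distance=np.inf)
        with pytest.raises(ValueError):
            betweenness(g)


class TestCrossRegionStrength:
    def test_uniform_weights_give_uniform_matrix(self):
        m = np.full((6, 6), 0.7)
        np.fill_diagonal(m, 0)
        g = build_graph(latent_from_matrix(m), min_probability=0.0)
        regions = RegionSet({"A": {0, 1, 2}, "B": {3, 4, 5}})
        mat, names = cross_region_strength(g, regions)
        np.testing.assert_allclose(mat, 0.7, rtol=1e-9)

    def test_single_cross_pair_diluted_by_pair_count(self):
        m = np.zeros((6, 6))
        m[0, 3] = 0.7
        g = build_graph(latent_from_matrix(m), min_probability=0.0)
        regions = RegionSet({"A": {0, 1, 2}, "B": {3, 4, 5}})
        mat, names = cross_region_strength(g, regions)
        a, b = names.index("A"), names.index("B")
        assert mat[a, b] == pytest.approx(0.7 / 9)
        assert mat[b, a] == 0.0   # directed: asymmetry preserved

    def test_region_missing_from_graph_rejected(self):
        g = build_graph(latent_from_matrix(np.zeros((4, 4))), 0.0)
        with pytest.raises(ValueError, match="Z"):
            cross_region_strength(g, RegionSet({"Z": {99}}))


class TestRegionCenter:
    def test_collinear_middle(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        assert region_center_residue(coords, {0, 1, 2}) == 1

    def test_single_residue(self):
        coords = np.zeros((5, 3))
        assert region_center_residue(coords, {3}) == 3

    def test_matches_exhaustive_scan(self, rng):
        coords = rng.normal(size=(20, 3))
        region = set(rng.choice(20, size=8, replace=False).tolist())
        centroid = coords[sorted(region)].mean(axis=0)
        best = min(sorted(region),
                   key=lambda r: (np.linalg.norm(coords[r] - centroid), r))
        assert region_center_residue(coords, region) == best


class TestShortestPath:
    def test_probability_one_edge_is_free(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=1.0, distance=0.0)
        p = shortest_path(g, 0, 1)
        assert p.residues == [0, 1]
        assert p.distance == 0.0

    def test_two_hops_beat_weak_direct_edge(self):
        g = nx.DiGraph()
        for a, b, w in [(0, 2, 0.1), (0, 1, 0.9), (1, 2, 0.9)]:
            g.add_edge(a, b, weight=w, distance=-np.log(w))
        p = shortest_path(g, 0, 2)
        assert p.residues == [0, 1, 2]
        assert p.distance == pytest.approx(-2 * np.log(0.9))

    def test_unreachable_is_flagged_not_raised(self):
        g = nx.DiGraph()
        g.add_nodes_from([0, 1])
        p = shortest_path(g, 0, 1)
        assert not p.reachable
        assert p.residues == []

    def test_duality_distance_vs_probability_product(self, rng):
        for _ in range(20):
            g = random_weighted_digraph(rng, 6)
            nodes = list(g.nodes)
            s, t = rng.choice(nodes, 2, replace=False)
            p = shortest_path(g, int(s), int(t))
            if p.reachable:
                assert np.exp(-p.distance) == pytest.approx(
                    np.prod(p.edge_probabilities), rel=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        checked = 0
        for _ in range(30):
            g = random_weighted_digraph(rng, int(rng.integers(4, 7)))
            nodes = list(g.nodes)
            s, t = rng.choice(nodes, 2, replace=False)
            ours = shortest_path(g, int(s), int(t))
            ref_path, ref_d = brute_force_shortest(g, int(s), int(t))
            if ref_path is None:
                assert not ours.reachable
            else:
                assert ours.distance == pytest.approx(ref_d, abs=1e-9)
                checked += 1
        assert checked >= 10

    def test_tie_break_prefers_fewer_hops_then_lexicographic(self):
        w = 0.5
        g = nx.DiGraph()
        # two equal-distance routes 0→3: direct w² edge vs 2-hop w·w
        for a, b, wt in [(0, 3, w * w), (0, 1, w), (1, 3, w),
                         (0, 2, w), (2, 3, w)]:
            g.add_edge(a, b, weight=wt, distance=-np.log(wt))
        p = shortest_path(g, 0, 3)
        assert p.residues == [0, 3]          # fewer hops wins
        g.remove_edge(0, 3)
        p = shortest_path(g, 0, 3)
        assert p.residues == [0, 1, 3]       # lexicographic among 2-hop

    def test_same_source_target_rejected(self):
        g = nx.DiGraph()
        g.add_node(0)
        with pytest.raises(ValueError):
            shortest_path(g, 0, 0)


class TestRelays:
    @staticmethod
    def _path(src, dst, residues):
        probs = [0.9] * (len(residues) - 1)
        return CommunicationPath(src, dst, residues,
                                 float(np.sum(-np.log(probs))), probs)

    def test_identical_paths_no_relays(self):
        a = {"S2": self._path(44, 146, [44, 146])}
        rep = detect_relays(a, a)
        assert rep["S2"]["relays"] == []
        assert rep["S2"]["unchanged"]

    def test_new_intermediate_detected_as_relay(self):
        # apo 44→146 direct; bound routes through 214
        a = {"S2": self._path(44, 146, [44, 146])}
        b = {"S2": self._path(44, 146, [44, 214, 146])}
        rep = detect_relays(a, b)
        assert rep["S2"]["relays"] == [214]
        assert rep["S2"]["lost"] == []

    def test_lost_intermediate_reported(self):
        a = {"S3": self._path(44, 178, [44, 52, 178])}
        b = {"S3": self._path(44, 178, [44, 214, 178])}
        rep = detect_relays(a, b)
        assert rep["S3"]["relays"] == [214]
        assert rep["S3"]["lost"] == [52]

    def test_mismatched_keys_rejected(self):
        a = {"S1": self._path(0, 1, [0, 1])}
        with pytest.raises(ValueError, match="S1"):
            detect_relays(a, {})


class TestPockets:
    def test_pocket_with_all_overlaps_ranks_first(self):
        pockets = [PocketDefinition(1, {10, 11}),
                   PocketDefinition(2, {20, 30, 40})]
        centrality = {20: 0.9, 30: 0.8, 10: 0.01, 11: 0.01, 40: 0.0}
        ranked = prioritize_pockets(pockets, centrality, relays={40})
        assert ranked[0]["pocket_id"] == 2
        assert ranked[1]["score"] == 0

    def test_relay_plus_hub_beats_relay_only(self):
        pockets = [PocketDefinition(1, {5}),
                   PocketDefinition(2, {6, 7})]
        centrality = {5: 0.0, 6: 0.0, 7: 1.0}
        ranked = prioritize_pockets(pockets, centrality, relays={5, 6})
        assert ranked[0]["pocket_id"] == 2
        assert ranked[0]["score"] == 2

    def test_tie_broken_by_external_score(self):
        pockets = [PocketDefinition(1, {5}, score=0.2),
                   PocketDefinition(2, {6}, score=0.8)]
        ranked = prioritize_pockets(pockets, centrality={5: 0.0, 6: 0.0},
                                    relays={5, 6})
        assert ranked[0]["pocket_id"] == 2

    def test_parse_fpocket_block_format(self, tmp_path):
        text = ("Pocket 1\n  Score : 0.45\n  Volume : 220.0\n"
                "  Residues: 224, 247, 248, 252\n"
                "Pocket 2\n  Score : 0.30\n  Residues: 10, 11\n")
        f = tmp_path / "info.txt"
        f.write_text(text)
        pockets = parse_fpocket_info(f)
        assert len(pockets) == 2
        assert pockets[0].residues == {223, 246, 247, 251}  # 0-based
        assert pockets[0].score == 0.45
        assert pockets[0].volume == 220.0

    def test_parse_plain_tsv(self, tmp_path):
        f = tmp_path / "pockets.tsv"
        f.write_text("# id\tresidues\n1\t5 6 7\n2\t9,10\n")
        pockets = parse_fpocket_info(f)
        assert pockets[1].residues == {8, 9}


class TestRegionSet:
    def test_default_ranges_include_declared_s2_s3_overlap(self):
        rs = RegionSet.from_ranges_1based()
        assert 159 in rs["S2"] and 159 in rs["S3"]  # residue 160, 0-based
        assert rs["beta1_alpha2"] == set(range(34, 63))

    def test_undeclared_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSet({"A": {1, 2}, "B": {2, 3}})

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            RegionSet({"A": set()})


def test_edge_tsv_is_one_based(tmp_path, rng):
    m = np.zeros((3, 3))
    m[0, 2] = 0.8
    g = build_graph(latent_from_matrix(m), min_probability=0.5)
    out = tmp_path / "edges.tsv"
    export_edge_tsv(g, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "source\ttarget\tweight"
    assert lines[1].startswith("1\t3\t")
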