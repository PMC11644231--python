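"""Unit and property tests for the interaction-network stage.

Graph-theoretic quantities (diameter, betweenness, clustering) are
checked against brute-force oracles written from first principles:
all-pairs distances by Floyd-Warshall over the adjacency matrix,
betweenness by explicit enumeration of all shortest paths, clustering by
triangle counting over neighbor pairs.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txnet.network import (
    ALLOWED_CHANNELS,
    CHANNELS,
    ChannelEdge,
    build_network,
    centrality,
    component_diameters,
    network_summary,
    read_string_edges,
    recombine_score,
    remove_group_nodes,
    select_hubs,
    select_max_diameter_component,
    write_string_edges,
)

# ---------------------------------------------------------------- oracles


def floyd_warshall_distances(nodes, edge_set):
    inf = float("inf")
    dist = {(u, v): (0 if u == v else inf) for u in nodes for v in nodes}
    for u, v in edge_set:
        dist[(u, v)] = dist[(v, u)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                via = dist[(i, k)] + dist[(k, j)]
                if via < dist[(i, j)]:
                    dist[(i, j)] = via
    return dist


def bruteforce_component_diameters(nodes, edge_set):
    dist = floyd_warshall_distances(nodes, edge_set)
    comps = []
    remaining = set(nodes)
    while remaining:
        seed = next(iter(remaining))
        comp = {v for v in nodes if dist[(seed, v)] < float("inf")}
        remaining -= comp
        diam = max(dist[(u, v)] for u in comp for v in comp)
        comps.append((frozenset(comp), int(diam)))
    return comps


def enumerate_shortest_paths(nodes, adj, s, t, dist):
    """All shortest s-t paths by depth-first extension along the metric."""
    if dist[(s, t)] == float("inf"):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist[(s, u)] + 1 == dist[(s, v)] and dist[(v, t)] == dist[(s, t)] - dist[(s, v)]:
                extend(path + [v])

    extend([s])
    return paths


def bruteforce_betweenness(nodes, edge_set):
    """Normalized betweenness by explicit shortest-path enumeration."""
    adj = {u: set() for u in nodes}
    for u, v in edge_set:
        adj[u].add(v)
        adj[v].add(u)
    dist = floyd_warshall_distances(nodes, edge_set)
    bt = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(nodes, adj, s, t, dist)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            bt[v] += frac
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return {v: b / norm for v, b in bt.items()}


def bruteforce_clustering(nodes, edge_set):
    adj = {u: set() for u in nodes}
    for u, v in edge_set:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def random_graph(seed, max_n=7):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_n + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = rng.uniform(0.15, 0.7)
    edge_set = {
        (a, b) for a, b in itertools.combinations(nodes, 2) if rng.uniform() < p
    }
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edge_set)
    return g, nodes, edge_set


def make_edge(a, b, **scores):
    return ChannelEdge(a, b, scores, recombine_score(scores, CHANNELS))


# ------------------------------------------------------------ ChannelEdge


class TestChannelEdge:
    def test_pair_stored_in_canonical_order(self):
        e = ChannelEdge("ZZZ", "AAA", {"experimental": 0.9}, 0.9)
        assert e.pair == ("AAA", "ZZZ")

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            ChannelEdge("A", "A", {}, 0.0)

    def test_score_validation(self):
        with pytest.raises(ValueError):
            ChannelEdge("A", "B", {"experimental": 1.2}, 0.5)
        with pytest.raises(ValueError):
            ChannelEdge("A", "B", {"bogus_channel": 0.5}, 0.5)


class TestStringIO:
    def test_roundtrip_preserves_scores_to_file_precision(self, tmp_path):
        edges = [
            make_edge("A", "B", experimental=0.95, textmining=0.4),
            make_edge("B", "C", coexpression=0.61),
        ]
        path = tmp_path / "edges.tsv"
        write_string_edges(edges, path)
        back = read_string_edges(path)
        assert len(back) == 2
        by_pair = {e.pair: e for e in back}
        assert by_pair[("A", "B")].channel_scores["experimental"] == pytest.approx(
            0.95, abs=5e-4
        )
        assert by_pair[("B", "C")].channel_scores["coexpression"] == pytest.approx(
            0.61, abs=5e-4
        )

    def test_symmetric_duplicates_collapse_and_self_loops_drop(self, tmp_path):
        header = "protein1\tprotein2\t" + "\t".join(
            ["neighborhood", "fusion", "cooccurence", "coexpression",
             "experimental", "database", "textmining", "combined_score"]
        )
        rows = [
            "A\tB\t0\t0\t0\t0\t950\t0\t0\t950",
            "B\tA\t0\t0\t0\t0\t950\t0\t0\t950",
            "C\tC\t0\t0\t0\t0\t900\t0\t0\t900",
        ]
        path = tmp_path / "edges.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        edges = read_string_edges(path)
        assert [e.pair for e in edges] == [("A", "B")]

    def test_missing_columns_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein1\tscore\nA\t1\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_string_edges(path)


# -------------------------------------------------------- recombine_score


class TestRecombineScore:
    def test_no_evidence_returns_prior(self):
        assert recombine_score({}, ALLOWED_CHANNELS) == pytest.approx(0.041)

    @pytest.mark.parametrize("s", [0.45, 0.70, 0.90, 0.99])
    def test_single_channel_idempotence(self, s):
        got = recombine_score({"experimental": s}, ["experimental"])
        assert got == pytest.approx(s, abs=1e-3)

    def test_two_half_channels_zero_prior(self):
        got = recombine_score(
            {"experimental": 0.5, "coexpression": 0.5},
            ["experimental", "coexpression"],
            prior=0.0,
        )
        assert got == pytest.approx(0.75, abs=1e-12)

    def test_excluded_channels_are_ignored(self):
        base = recombine_score({"experimental": 0.8}, ALLOWED_CHANNELS)
        with_tm = recombine_score(
            {"experimental": 0.8, "textmining": 0.99}, ALLOWED_CHANNELS
        )
        assert base == pytest.approx(with_tm, abs=1e-15)

    @settings(derandomize=True, max_examples=100)
    @given(
        s1=st.floats(min_value=0, max_value=1),
        s2=st.floats(min_value=0, max_value=1),
        delta=st.floats(min_value=0, max_value=0.5),
    )
    def test_monotone_in_every_allowed_channel(self, s1, s2, delta):
        chans = ["experimental", "coexpression"]
        lo = recombine_score({"experimental": s1, "coexpression": s2}, chans)
        hi = recombine_score(
            {"experimental": min(1.0, s1 + delta), "coexpression": s2}, chans
        )
        assert hi >= lo - 1e-12

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            recombine_score({}, ALLOWED_CHANNELS, prior=1.0)


# ---------------------------------------------------------- build_network


class TestBuildNetwork:
    def test_textmining_only_edge_excluded(self):
        e = make_edge("A", "B", textmining=0.99)
        g = build_network([e], ["A", "B"])
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B"}  # isolated DEGs retained

    def test_strong_experimental_edge_included(self):
        e = make_edge("A", "B", experimental=0.95)
        g = build_network([e], ["A", "B"])
        assert g.has_edge("A", "B")
        assert g.edges["A", "B"]["score"] >= 0.900

    def test_edge_to_non_deg_excluded(self):
        e = make_edge("A", "B", experimental=0.99)
        g = build_network([e], ["A", "C"])
        assert g.number_of_edges() == 0

    def test_empty_deg_list_rejected(self):
        with pytest.raises(ValueError, match="empty DEG list"):
            build_network([], [])


# ------------------------------------------------- components & diameters


class TestComponentsAndDiameter:
    def test_path_graph_diameter(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        [(comp, diam)] = component_diameters(g)
        assert diam == 3

    def test_triangle_diameter(self):
        g = nx.complete_graph(3)
        [(comp, diam)] = component_diameters(g)
        assert diam == 1

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        g, nodes, edge_set = random_graph(seed)
        got = {c: d for c, d in component_diameters(g)}
        want = {c: d for c, d in bruteforce_component_diameters(nodes, edge_set)}
        assert got == want

    def test_max_diameter_beats_size(self):
        g = nx.Graph()
        nx.add_path(g, ["p1", "p2", "p3", "p4", "p5"])  # diameter 4
        g = nx.compose(g, nx.complete_graph([f"k{i}" for i in range(40)]))
        sel = select_max_diameter_component(g)
        assert set(sel.nodes) == {"p1", "p2", "p3", "p4", "p5"}

    def test_tie_break_lexicographic(self):
        g = nx.Graph()
        nx.add_path(g, ["B1", "B2", "B3"])
        nx.add_path(g, ["A1", "A2", "A3"])
        sel = select_max_diameter_component(g)
        assert set(sel.nodes) == {"A1", "A2", "A3"}

    def test_single_component_is_identity(self):
        g = nx.path_graph(["x", "y", "z"])
        sel = select_max_diameter_component(g)
        assert set(sel.nodes) == set(g.nodes)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_max_diameter_component(nx.Graph())


class TestRemoveGroupNodes:
    def test_disjoint_group_is_noop(self):
        g = nx.path_graph(["a", "b", "c"])
        out = remove_group_nodes(g, ["zzz"])
        assert set(out.nodes) == set(g.nodes)
        assert out.number_of_edges() == g.number_of_edges()

    def test_cut_vertex_removal_keeps_both_components(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        out = remove_group_nodes(g, ["c"])
        assert set(out.nodes) == {"a", "b", "d", "e"}
        assert nx.number_connected_components(out) == 2


# -------------------------------------------------------------- centrality


class TestCentrality:
    def test_middle_of_three_path_has_full_betweenness(self):
        g = nx.path_graph(["a", "b", "c"])
        cent = centrality(g).set_index("gene")
        assert cent.loc["b", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["a", "betweenness"] == pytest.approx(0.0)

    def test_star_center_has_full_betweenness(self):
        g = nx.star_graph(["hub", "l1", "l2", "l3", "l4"])
        cent = centrality(g).set_index("gene")
        assert cent.loc["hub", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["hub", "degree"] == 4

    def test_four_path_interior_betweenness(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        cent = centrality(g).set_index("gene")
        assert cent.loc["b", "betweenness"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(60, 120))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        g, nodes, edge_set = random_graph(seed)
        got = centrality(g).set_index("gene")["betweenness"].to_dict()
        want = bruteforce_betweenness(nodes, edge_set)
        for v in nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-9)

    def test_tiny_components_have_zero_betweenness(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        cent = centrality(g)
        assert (cent["betweenness"] == 0).all()


class TestSelectHubs:
    def test_boundary_values_are_strict(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "gene": ["at_bt", "at_deg", "passes"],
                "degree": [5, 2, 3],
                "betweenness": [0.5, 0.9, 0.51],
            }
        )
        assert select_hubs(records) == ["passes"]

    def test_sorted_by_betweenness_then_degree(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "gene": ["b", "a", "c"],
                "degree": [3, 4, 9],
                "betweenness": [0.9, 0.9, 0.6],
            }
        )
        assert select_hubs(records) == ["a", "b", "c"]


class TestNetworkSummary:
    def test_triangle(self):
        s = network_summary(nx.complete_graph(3))
        assert s["avg_degree"] == pytest.approx(2.0)
        assert s["avg_clustering"] == pytest.approx(1.0)

    def test_star_has_zero_clustering(self):
        s = network_summary(nx.star_graph(3))
        assert s["avg_clustering"] == pytest.approx(0.0)

    def test_empty_graph_is_zeros(self):
        s = network_summary(nx.Graph())
        assert s == {"n_nodes": 0, "n_edges": 0, "avg_degree": 0.0, "avg_clustering": 0.0}

    @pytest.mark.parametrize("seed", range(120, 150))
    def test_clustering_matches_triangle_counting(self, seed):
        g, nodes, edge_set = random_graph(seed)
        want = bruteforce_clustering(nodes, edge_set)
        got = network_summary(g)["avg_clustering"]
        assert got == pytest.approx(sum(want.values()) / len(nodes), abs=1e-12)
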