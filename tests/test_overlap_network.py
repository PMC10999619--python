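"""Overlap networks, modularity, module detection and stable groups."""

import networkx as nx
import numpy as np
import pytest

from nichecomm import (
    build_network,
    detect_modules,
    export_network,
    modularity,
    read_network,
    stable_groups,
)
from nichecomm.niche_metrics import OverlapMatrix


def om_from(values, species=None, method="pianka", stage="S1"):
    values = np.asarray(values, dtype=float)
    np.fill_diagonal(values, np.nan)
    species = species or [f"s{i}" for i in range(values.shape[0])]
    return OverlapMatrix(stage=stage, species=species, method=method, values=values)


def two_triangles():
    g = nx.Graph()
    g.add_weighted_edges_from(
        [("a", "b", 1), ("b", "c", 1), ("a", "c", 1), ("d", "e", 1), ("e", "f", 1), ("d", "f", 1)]
    )
    return g


def random_weighted_graph(rng, n):
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for k in range(i + 1, n):
            if rng.random() < 0.55:
                g.add_edge(f"n{i}", f"n{k}", weight=float(rng.uniform(0.05, 1.0)))
    if g.number_of_edges() == 0:
        g.add_edge("n0", "n1", weight=1.0)
    return g


class TestBuildNetwork:
    def test_triangle_at_zero_threshold(self):
        om = om_from(np.full((3, 3), 0.5))
        g = build_network(om, threshold=0.0)
        assert g.number_of_edges() == 3

    def test_high_threshold_leaves_isolated_nodes(self):
        om = om_from(np.full((3, 3), 0.5))
        g = build_network(om, threshold=0.6)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_levins_mean_symmetrization(self):
        vals = np.array([[np.nan, 0.5], [1.0, np.nan]])
        om = om_from(vals, method="levins")
        g = build_network(om, symmetrize="mean")
        assert g["s0"]["s1"]["weight"] == pytest.approx(0.75)
        gmax = build_network(om, symmetrize="max")
        assert gmax["s0"]["s1"]["weight"] == pytest.approx(1.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_network(om_from(np.full((2, 2), 0.5)), threshold=-0.1)

    def test_species_numbers_attached(self):
        om = om_from(np.full((2, 2), 0.5), species=["Poa annua", "Carex foo"])
        g = build_network(om, species_numbers={"Poa annua": 43, "Carex foo": 12})
        assert g.nodes["Poa annua"]["species_no"] == 43


class TestModularity:
    def test_single_module_is_zero(self):
        g = two_triangles()
        g.add_edge("c", "d", weight=0.5)
        assert modularity(g, {n: 0 for n in g}) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_split_is_half(self):
        g = two_triangles()
        part = {n: 0 if n in "abc" else 1 for n in g}
        assert modularity(g, part) == pytest.approx(0.5)

    def test_two_node_split_is_minus_half(self):
        g = nx.Graph()
        g.add_edge("x", "y", weight=2.0)
        assert modularity(g, {"x": 0, "y": 1}) == pytest.approx(-0.5)

    def test_edgeless_errors(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="edgeless"):
            modularity(g, {"a": 0, "b": 0})

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_weighted_graph(rng, int(rng.integers(4, 9)))
            labels = {n: int(rng.integers(0, 3)) for n in g}
            groups = {}
            for n, c in labels.items():
                groups.setdefault(c, set()).add(n)
            expected = nx.community.modularity(g, groups.values(), weight="weight")
            assert modularity(g, labels) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(3)
        g = random_weighted_graph(rng, 7)
        labels = {n: int(rng.integers(0, 2)) for n in g}
        scaled = g.copy()
        for u, v in scaled.edges:
            scaled[u][v]["weight"] *= 13.7
        assert modularity(g, labels) == pytest.approx(modularity(scaled, labels))


class TestDetectModules:
    @pytest.mark.parametrize("method", ["greedy", "multilevel", "exhaustive"])
    def test_two_triangles_any_method(self, method):
        part = detect_modules(two_triangles(), method=method, seed=0)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(4)
        for method in ("greedy", "exhaustive"):
            part = detect_modules(g, method=method)
            assert part.n_modules == 1
            assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_weak_bridge_barbell_splits_at_bridge(self):
        g = two_triangles()
        g.add_edge("c", "d", weight=0.01)
        for method in ("greedy", "exhaustive"):
            part = detect_modules(g, method=method)
            mods = sorted(sorted(m) for m in part.modules())
            assert mods == [["a", "b", "c"], ["d", "e", "f"]]

    def test_isolated_nodes_are_singletons_not_counted(self):
        g = two_triangles()
        g.add_node("lonely")
        part = detect_modules(g, method="greedy")
        assert part.n_modules == 2
        assert [part.membership["lonely"]] not in [
            [part.membership[n]] for n in "abcdef"
        ]

    def test_exhaustive_refuses_large_graphs(self):
        g = nx.complete_graph(13)
        with pytest.raises(ValueError, match="12"):
            detect_modules(g, method="exhaustive")

    def test_greedy_is_deterministic(self):
        rng = np.random.default_rng(4)
        g = random_weighted_graph(rng, 8)
        p1 = detect_modules(g, method="greedy")
        p2 = detect_modules(g, method="greedy")
        assert p1.membership == p2.membership and p1.q == p2.q

    def test_heuristic_never_beats_exhaustive(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            g = random_weighted_graph(rng, int(rng.integers(4, 9)))
            q_h = detect_modules(g, method="greedy").q
            q_x = detect_modules(g, method="exhaustive").q
            assert q_h <= q_x + 1e-12

    def test_module_count_matches_partition(self):
        rng = np.random.default_rng(7)
        g = random_weighted_graph(rng, 8)
        part = detect_modules(g, method="greedy")
        connected = [n for n in g if g.degree(n) > 0]
        assert part.n_modules == len({part.membership[n] for n in connected})


class TestStableGroups:
    def test_recovers_published_groups(self, species_table):
        parts = {s: species_table.stage_partition(s) for s in ("S1", "S2", "S3")}
        pres = {s: species_table.species_present(s) for s in ("S1", "S2", "S3")}
        result = stable_groups(parts, pres)
        numbered = sorted(
            sorted(species_table.species_number(sp) for sp in g) for g in result.groups
        )
        assert numbered == [
            [2, 9, 18, 26, 32, 45],  # group b
            [6, 8, 17, 22, 25, 27, 42],  # group a
            [12, 37],  # group c
            [15, 41],  # group e
            [35, 38],  # group d
        ]

    def test_all_one_module_gives_single_group(self):
        parts = {
            "S1": {"a": 0, "b": 0, "c": 0},
            "S2": {"a": 1, "b": 1, "c": 1},
        }
        result = stable_groups(parts)
        assert result.groups == [frozenset({"a", "b", "c"})]

    def test_single_stage_species_excluded(self):
        parts = {
            "S1": {"a": 0, "b": 0},
            "S2": {"a": 0, "b": 0, "only_s2": 0},
        }
        result = stable_groups(parts)
        assert result.groups == [frozenset({"a", "b"})]

    def test_invariant_to_stage_ordering(self, species_table):
        stages = ("S1", "S2", "S3")
        parts = {s: species_table.stage_partition(s) for s in stages}
        pres = {s: species_table.species_present(s) for s in stages}
        fwd = stable_groups(parts, pres)
        rev = stable_groups(
            {s: parts[s] for s in reversed(stages)}, {s: pres[s] for s in reversed(stages)}
        )
        assert sorted(map(sorted, fwd.groups)) == sorted(map(sorted, rev.groups))

    def test_requires_two_stages(self):
        with pytest.raises(ValueError):
            stable_groups({"S1": {"a": 0}})


class TestExportImport:
    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_round_trip_weights_and_modules(self, tmp_path, fmt):
        g = two_triangles()
        g.nodes["a"]["species_no"] = 12
        part = detect_modules(g, method="greedy")
        path = tmp_path / f"net.{fmt}"
        export_network(g, part, path, format=fmt)
        back = read_network(path, format=fmt)
        assert set(back.nodes) == set(g.nodes)
        for u, v, w in g.edges(data="weight"):
            assert back[u][v]["weight"] == pytest.approx(w)
        assert back.nodes["a"]["species_no"] == 12
        # module labels group the same nodes
        assert {back.nodes[n]["module"] for n in "abc"} != {
            back.nodes[n]["module"] for n in "def"
        }

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_edgeless_network_round_trips(self, tmp_path, fmt):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        path = tmp_path / f"empty.{fmt}"
        export_network(g, None, path, format=fmt)
        back = read_network(path, format=fmt)
        assert set(back.nodes) == {"x", "y"} and back.number_of_edges() == 0

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(nx.Graph(), None, tmp_path / "x", format="gexf")
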