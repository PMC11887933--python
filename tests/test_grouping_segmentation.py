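"""Boundary graph, selection placement, and spreading dynamics."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from uncrowding import cortical_dynamics as cd
from uncrowding import grouping_segmentation as gseg
from uncrowding import stimuli as stim

from conftest import make_bar_image


def graph_from_bars(bars, config, clock, params=gseg.BipoleParams()):
    img = make_bar_image(bars, config)
    field = cd.evolve(cd.oriented_response(img), clock)
    return gseg.build_graph(cd.accumulate(field, clock.offset_ms), config, params)


def oracle_components(graph: gseg.BoundaryGraph, params: gseg.BipoleParams, ppd: float):
    """Independent re-derivation of the link rules + BFS connectivity.

    Plain pair loops over nodes; no reuse of the adjacency matrix.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for i in range(graph.n_nodes):
        for j in range(i + 1, graph.n_nodes):
            dx = abs(graph.x_deg[i] - graph.x_deg[j])
            dy = abs(graph.y_deg[i] - graph.y_deg[j])
            oi, oj = graph.orientation[i], graph.orientation[j]
            if oi == oj:
                along, across = (dy, dx) if oi == gseg.VERTICAL else (dx, dy)
                if across <= params.lateral_tolerance_deg + 1e-9 and along <= params.max_bridge_deg + 1e-9:
                    g.add_edge(i, j)
            else:
                if dx * ppd <= 0.5 and dy * ppd <= 2.5:
                    g.add_edge(i, j)
    comps = list(nx.connected_components(g))
    labels = np.empty(graph.n_nodes, dtype=int)
    for k, comp in enumerate(comps):
        for i in comp:
            labels[i] = k
    return len(comps), labels


def partitions_equal(labels_a, labels_b) -> bool:
    pairs = set(zip(labels_a.tolist(), labels_b.tolist()))
    return len(pairs) == len(set(labels_a)) == len(set(labels_b))


class TestBuildGraph:
    def test_empty_map_empty_graph(self, config):
        g = gseg.build_graph(np.zeros((4, 50, 50)), config)
        assert g.n_nodes == 0
        assert g.connected_components()[0] == 0

    def test_small_gap_bridged(self, config, clock):
        g = graph_from_bars([(0.0, -0.55, 0.9), (0.0, 0.55, 0.9)], config, clock)
        assert g.n_nodes > 0
        assert g.connected_components()[0] == 1

    def test_large_gap_not_bridged(self, config, clock):
        # gap of 1.25 deg between bar ends
        g = graph_from_bars([(0.0, -1.525, 1.8), (0.0, 1.525, 1.8)], config, clock)
        assert g.connected_components()[0] == 2

    def test_equal_flankers_one_group(self, pipeline_products):
        g = pipeline_products["EQUAL_FLANKERS"]["graph"]
        n, labels = g.connected_components()
        vernier = (np.abs(g.x_deg) <= 0.25) & (np.abs(g.y_deg) <= 1.0)
        flanker = (np.abs(g.x_deg) >= 0.35) & (np.abs(g.x_deg) <= 1.3)
        assert set(labels[vernier]) & set(labels[flanker])

    def test_long_flankers_separate_from_vernier(self, pipeline_products):
        g = pipeline_products["LONG"]["graph"]
        _, labels = g.connected_components()
        vernier = (np.abs(g.x_deg) <= 0.25) & (np.abs(g.y_deg) <= 1.0)
        flanker = (np.abs(g.x_deg) >= 0.35) & (np.abs(g.x_deg) <= 1.3)
        assert not (set(labels[vernier]) & set(labels[flanker]))

    def test_gapped_middle_segments_join_vernier(self, pipeline_products):
        g = pipeline_products["GAPPED"]["graph"]
        _, labels = g.connected_components()
        vernier = (np.abs(g.x_deg) <= 0.25) & (np.abs(g.y_deg) <= 1.0)
        middle = (np.abs(g.x_deg) >= 0.35) & (np.abs(g.x_deg) <= 1.3) & (np.abs(g.y_deg) <= 1.1)
        top = (np.abs(g.x_deg) >= 0.35) & (np.abs(g.x_deg) <= 1.3) & (g.y_deg < -2.0)
        assert set(labels[vernier]) & set(labels[middle])
        assert not (set(labels[vernier]) & set(labels[top]))

    def test_component_structure_matches_oracle(self, config, clock):
        rng = np.random.default_rng(7)
        params = gseg.BipoleParams()
        for _ in range(10):
            n_bars = rng.integers(2, 5)
            bars = [
                (
                    float(rng.integers(-5, 6)) * 0.5,
                    float(rng.integers(-3, 4)) * 0.7,
                    float(rng.choice([0.9, 1.8, 2.7])),
                )
                for _ in range(n_bars)
            ]
            g = graph_from_bars(bars, config, clock, params)
            n_impl, labels_impl = g.connected_components()
            n_orc, labels_orc = oracle_components(g, params, config.pixels_per_degree)
            assert n_impl == n_orc
            assert partitions_equal(labels_impl, labels_orc)

    def test_bipole_params_validation(self):
        with pytest.raises(ValueError):
            gseg.BipoleParams(max_bridge_deg=0.05, lateral_tolerance_deg=0.1)


class TestPlaceSelection:
    def test_long_two_disks_at_top(self):
        spec = stim.make_condition_spec("LONG")
        sig = gseg.place_selection(spec)
        assert len(sig.centers_deg) == 2
        for cx, cy in sig.centers_deg:
            assert cy == pytest.approx(-4.25)
            assert abs(cx) == pytest.approx(0.8)

    def test_vernier_only_empty(self):
        sig = gseg.place_selection(stim.make_condition_spec("VERNIER_ONLY"))
        assert sig.empty

    def test_long_disks_cover_every_flanker_top(self, pipeline_products):
        prod = pipeline_products["LONG"]
        g, sig = prod["graph"], prod["signal"]
        covered = sig.covers(g.x_deg, g.y_deg)
        for x in (-1.2, -0.8, -0.4, 0.4, 0.8, 1.2):
            near_top = (np.abs(g.x_deg - x) < 0.1) & (g.y_deg < -3.5)
            assert covered[near_top].any(), f"flanker column {x} top not covered"

    def test_long_disks_avoid_vernier(self, pipeline_products):
        prod = pipeline_products["LONG"]
        g, sig = prod["graph"], prod["signal"]
        covered = sig.covers(g.x_deg, g.y_deg)
        vernier = (np.abs(g.x_deg) <= 0.25) & (np.abs(g.y_deg) <= 1.0)
        assert not covered[vernier].any()

    def test_gapped_disks_cover_only_top_segments(self, pipeline_products):
        prod = pipeline_products["GAPPED"]
        g, sig = prod["graph"], prod["signal"]
        covered = sig.covers(g.x_deg, g.y_deg)
        assert covered.any()
        assert np.all(g.y_deg[covered] < -2.0)


class TestSpread:
    def test_empty_seeds_all_layer0(self, pipeline_products, clock):
        state = pipeline_products["VERNIER_ONLY"]["state"]
        assert not state.layer1(clock.end_ms).any()

    def test_monotone_growth(self, pipeline_products, clock):
        state = pipeline_products["LONG"]["state"]
        prev = np.zeros(state.graph.n_nodes, dtype=bool)
        for t in np.arange(0, clock.end_ms + 1, 20.0):
            cur = state.layer1(float(t))
            assert np.all(prev <= cur)
            prev = cur

    def test_every_node_in_exactly_one_layer(self, pipeline_products, clock):
        state = pipeline_products["GAPPED"]["state"]
        for t in (150.0, 200.0, 300.0):
            layer = state.layer(t)
            assert np.isin(layer, (0, 1)).all()

    def test_geodesic_ball_equals_networkx_oracle(self, pipeline_products, clock):
        state = pipeline_products["GAPPED"]["state"]
        g = state.graph
        G = nx.from_scipy_sparse_array(g.adjacency)
        seeds = np.nonzero(state.seeds)[0]
        lengths = nx.multi_source_dijkstra_path_length(G, set(seeds.tolist()))
        t = 220.0
        radius = state.speed_deg_per_ms * (t - state.start_ms)
        oracle = np.zeros(g.n_nodes, dtype=bool)
        for i, d in lengths.items():
            if d <= radius + 1e-12:
                oracle[i] = True
        assert np.array_equal(state.layer1(t), oracle)

    def test_long_fractions_at_end(self, pipeline_products, clock):
        state = pipeline_products["LONG"]["state"]
        g = state.graph
        in1 = state.layer1(clock.end_ms)
        flanker = (np.abs(g.x_deg) >= 0.35) & (np.abs(g.x_deg) <= 1.3)
        vernier = (np.abs(g.x_deg) <= 0.25) & (np.abs(g.y_deg) <= 1.0)
        assert in1[flanker].mean() >= 0.9
        assert (~in1[vernier]).mean() >= 0.9

    def test_gapped_middle_segments_never_selected(self, pipeline_products, clock):
        state = pipeline_products["GAPPED"]["state"]
        g = state.graph
        middle = (np.abs(g.x_deg) >= 0.35) & (np.abs(g.x_deg) <= 1.3) & (np.abs(g.y_deg) <= 1.1)
        assert middle.any()
        for t in np.arange(0, clock.end_ms + 1, 20.0):
            assert not state.layer1(float(t))[middle].any()

    def test_completion_time_near_100ms(self, pipeline_products, clock):
        state = pipeline_products["LONG"]["state"]
        g = state.graph
        flanker = (np.abs(g.x_deg) >= 0.35) & (np.abs(g.x_deg) <= 1.3)
        d = state.distance_deg[flanker]
        completion = d[np.isfinite(d)].max() / state.speed_deg_per_ms
        assert 70.0 <= completion <= 110.0

    def test_unreachable_nodes_stay_layer0(self, pipeline_products, clock):
        state = pipeline_products["GAPPED_INWARD"]["state"]
        g = state.graph
        pacman = np.abs(g.x_deg) > 2.0
        assert pacman.any()
        assert not state.layer1(clock.end_ms)[pacman].any()
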