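import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hospiflow import published
from hospiflow.network import (
    build_network,
    compute_metrics,
    flow_matrix,
    flow_matrix_from_counts,
)

from .conftest import make_registry


def newman_assortativity(g: nx.Graph) -> float:
    """Brute-force degree assortativity: Pearson correlation of end degrees
    over the edge list with both orientations included."""
    xs, ys = [], []
    deg = dict(g.degree())
    for u, v in g.edges():
        xs.extend([deg[u], deg[v]])
        ys.extend([deg[v], deg[u]])
    xs, ys = np.array(xs, float), np.array(ys, float)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def events_from_pairs(pairs):
    """pairs: list of (from, to, n_events)."""
    rows = []
    for u, v, n in pairs:
        for i in range(n):
            rows.append({"from_hospital": u, "to_hospital": v, "same_rhg": False})
    return pd.DataFrame(rows)


def labels_for(hospitals):
    return pd.Series(0, index=pd.Index(hospitals, name="hospital_id"), name="cluster")


REGISTRY = make_registry({f"H{i}": "R1" for i in range(8)})


class TestBuildNetwork:
    def test_no_events_edgeless(self):
        g = build_network(events_from_pairs([]), labels_for(["H1", "H2", "H3"]), REGISTRY)
        assert g.number_of_edges() == 0
        assert compute_metrics(g).edge_density == 0.0

    def test_strong_rule_either_direction(self):
        ev = events_from_pairs([("H1", "H2", 120), ("H2", "H1", 5)])
        g = build_network(ev, labels_for(["H1", "H2"]), REGISTRY, strong_threshold=100, mode="strong")
        assert g.has_edge("H1", "H2") and g.has_edge("H2", "H1")
        assert g["H2"]["H1"]["weight"] == 5  # weak back-edge kept with its pair

    def test_strong_rule_boundary(self):
        ev = events_from_pairs([("H1", "H2", 99), ("H2", "H1", 99)])
        strong = build_network(ev, labels_for(["H1", "H2"]), REGISTRY, 100, mode="strong")
        all_mode = build_network(ev, labels_for(["H1", "H2"]), REGISTRY, 100, mode="all")
        assert strong.number_of_edges() == 0
        assert all_mode.number_of_edges() == 2

    def test_total_weight_equals_event_count(self):
        ev = events_from_pairs([("H1", "H2", 7), ("H2", "H3", 3), ("H3", "H1", 2)])
        g = build_network(ev, labels_for(["H1", "H2", "H3"]), REGISTRY)
        assert compute_metrics(g).total_weight == len(ev)

    def test_unknown_hospital_rejected(self):
        ev = events_from_pairs([("H1", "HX", 1)])
        with pytest.raises(ValueError, match="without labels"):
            build_network(ev, labels_for(["H1", "H2"]), REGISTRY)

    def test_strong_mode_equals_manual_pair_deletion(self):
        # two code paths, one answer: strong mode vs deleting weak pairs by hand
        ev = events_from_pairs(
            [("H1", "H2", 120), ("H2", "H1", 5), ("H2", "H3", 40), ("H3", "H4", 200),
             ("H4", "H3", 150), ("H1", "H4", 99)]
        )
        hospitals = ["H1", "H2", "H3", "H4"]
        strong = build_network(ev, labels_for(hospitals), REGISTRY, 100, mode="strong")
        manual = build_network(ev, labels_for(hospitals), REGISTRY, 100, mode="all")
        for u, v in [("H2", "H3"), ("H1", "H4")]:  # pairs below threshold
            if manual.has_edge(u, v):
                manual.remove_edge(u, v)
            if manual.has_edge(v, u):
                manual.remove_edge(v, u)
        ms, mm = compute_metrics(strong), compute_metrics(manual)
        assert ms.edge_density == mm.edge_density
        assert ms.transitivity_global == mm.transitivity_global
        assert (math.isnan(ms.assortativity_degree) and math.isnan(mm.assortativity_degree)) or (
            ms.assortativity_degree == pytest.approx(mm.assortativity_degree)
        )


def graph_to_network(g: nx.Graph) -> nx.DiGraph:
    d = nx.DiGraph()
    d.add_nodes_from(g.nodes())
    for u, v in g.edges():
        d.add_edge(u, v, weight=1)
    return d


class TestMetrics:
    def test_star_graph_closed_forms(self):
        g = graph_to_network(nx.star_graph(5))
        m = compute_metrics(g)
        assert m.assortativity_degree == pytest.approx(-1.0)
        assert m.transitivity_global == 0.0

    def test_triangle_plus_pendant_transitivity(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])
        m = compute_metrics(graph_to_network(g))
        # 3 triangles-closures / 5 connected triples
        assert m.transitivity_global == pytest.approx(0.6)

    def test_directed_density(self):
        d = nx.DiGraph()
        d.add_nodes_from([0, 1, 2])
        d.add_edge(0, 1, weight=1)
        d.add_edge(1, 2, weight=1)
        assert compute_metrics(d).edge_density == pytest.approx(2 / 6)

    def test_undefined_assortativity_flagged(self):
        cycle = graph_to_network(nx.cycle_graph(5))  # all degrees equal
        m = compute_metrics(cycle)
        assert not m.assortativity_defined
        assert math.isnan(m.assortativity_degree)

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_newman_on_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 21))
        p = float(rng.uniform(0.15, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if g.number_of_edges() == 0:
            return
        expected = newman_assortativity(g)
        m = compute_metrics(graph_to_network(g))
        if math.isnan(expected):
            assert not m.assortativity_defined
        else:
            assert m.assortativity_degree == pytest.approx(expected, abs=1e-8)

    def test_two_tier_hub_spoke_flow_is_disassortative(self):
        # many spokes each sending to one of two hubs: hubs have high degree,
        # spokes degree one -> negative degree correlation
        d = nx.DiGraph()
        for i in range(12):
            d.add_edge(f"S{i}", f"HUB{i % 2}", weight=50)
        d.add_edge("HUB0", "HUB1", weight=10)
        m = compute_metrics(d)
        assert m.assortativity_degree < 0


class TestFlowMatrix:
    def test_hand_arithmetic(self):
        ev = events_from_pairs([("A", "B", 3), ("B", "A", 1)])
        labels = pd.Series(["cA", "cB"], index=["A", "B"])
        fm = flow_matrix(ev, labels)
        assert fm.grand_total == 4
        assert fm.row_pct.loc["cA", "cB"] == pytest.approx(100.0)
        assert fm.overall_pct.loc["cA", "cB"] == pytest.approx(75.0)

    def test_all_events_within_one_cluster_is_diagonal(self):
        ev = events_from_pairs([("A", "B", 5), ("B", "A", 2)])
        labels = pd.Series(["c1", "c1"], index=["A", "B"])
        fm = flow_matrix(ev, labels)
        assert fm.counts.loc["c1", "c1"] == 7
        assert fm.row_pct.loc["c1", "c1"] == pytest.approx(100.0)

    def test_percentage_invariants(self):
        fm = flow_matrix_from_counts(published.FLOW_COUNTS)
        assert np.allclose(fm.row_pct.sum(axis=1), 100.0, atol=0.1)
        assert fm.overall_pct.to_numpy().sum() == pytest.approx(100.0, abs=0.1)
        assert fm.grand_total == published.FLOW_COUNTS.to_numpy().sum()

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            flow_matrix_from_counts(pd.DataFrame([[0, 0], [0, 0]]))
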