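"""Patient-flow network construction and structural statistics.

Hospitals are vertices; a directed edge u -> v carries the number of
mobility events sending patients from u to v.  Two views are analyzed:
``all`` (every relation) and ``strong`` (only hospital pairs exchanging at
least ``strong_threshold`` patients *in either direction* — both directed
edges of a qualifying pair are retained).

Degree assortativity (Newman's degree-degree Pearson correlation) and
global transitivity (3 x triangles / connected triples) are computed on the
undirected simple graph underlying the flow network; edge density on the
directed simple graph, m / (n (n - 1)).  A disassortative coefficient
(r < 0) means hubs connect preferentially to low-degree spokes — the
signature of a referral system where small hospitals send patients to a few
reference centers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["build_network", "compute_metrics", "flow_matrix", "flow_matrix_from_counts", "FlowMatrix", "NetworkMetrics"]


def build_network(
    events: pd.DataFrame,
    cluster_labels: pd.Series,
    registry: pd.DataFrame,
    strong_threshold: int = 100,
    mode: str = "all",
) -> nx.DiGraph:
    """Aggregate mobility events into a directed weighted graph.

    Nodes are all hospitals carrying a cluster label (isolated hospitals are
    retained); node attributes ``cluster`` and ``rhg_id``; edge attribute
    ``weight``.  ``mode="strong"`` keeps a hospital pair iff the larger of
    its two directed weights reaches ``strong_threshold``.
    """
    if mode not in ("all", "strong"):
        raise ValueError(f"unknown mode {mode!r}")
    known = set(cluster_labels.index)
    if len(events):
        used = set(events["from_hospital"]) | set(events["to_hospital"])
        unknown = used - known
        if unknown:
            raise ValueError(f"events reference hospitals without labels: {sorted(unknown)[:5]}")

    rhg = dict(zip(registry["hospital_id"], registry["rhg_id"]))
    g = nx.DiGraph(mode=mode, threshold_applied=strong_threshold if mode == "strong" else 0)
    for h in cluster_labels.index:
        g.add_node(h, cluster=int(cluster_labels[h]) if pd.api.types.is_integer_dtype(cluster_labels) else cluster_labels[h], rhg_id=rhg.get(h, ""))

    if len(events) == 0:
        return g
    w = events.groupby(["from_hospital", "to_hospital"], observed=True).size()
    if mode == "strong":
        keep = set()
        for (u, v), weight in w.items():
            pair_max = max(weight, w.get((v, u), 0))
            if pair_max >= strong_threshold:
                keep.add((u, v))
        w = w[w.index.isin(keep)]
    for (u, v), weight in w.items():
        if u == v:
            continue
        g.add_edge(u, v, weight=int(weight))
    return g


@dataclass
class NetworkMetrics:
    assortativity_degree: float  # undirected Newman correlation; NaN if undefined
    assortativity_defined: bool
    assortativity_directed_out_in: float  # directed (out, in) variant, extra
    transitivity_global: float
    edge_density: float
    n_nodes: int
    n_edges: int
    total_weight: int
    nodes: pd.DataFrame  # per-node degree / in_strength / out_strength

    def to_dict(self) -> dict:
        d = {
            "assortativity_degree": None if not self.assortativity_defined else self.assortativity_degree,
            "assortativity_defined": self.assortativity_defined,
            "assortativity_directed_out_in": None
            if math.isnan(self.assortativity_directed_out_in)
            else self.assortativity_directed_out_in,
            "transitivity_global": self.transitivity_global,
            "edge_density": self.edge_density,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "total_weight": self.total_weight,
        }
        return d


def compute_metrics(network: nx.DiGraph) -> NetworkMetrics:
    """Structural statistics of a flow network.

    Assortativity can be undefined (zero variance of degrees at edge ends,
    e.g. cycles or complete graphs); it is then reported as NaN with
    ``assortativity_defined = False`` rather than as a number.
    """
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("compute_metrics needs at least 2 nodes")
    und = nx.Graph(network)  # collapse direction, drop parallel directions

    if und.number_of_edges() == 0:
        assort, defined = math.nan, False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assort = float(nx.degree_assortativity_coefficient(und))
        defined = not math.isnan(assort)

    if network.number_of_edges() == 0:
        directed_assort = math.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                directed_assort = float(
                    nx.degree_assortativity_coefficient(network, x="out", y="in")
                )
            except (ZeroDivisionError, ValueError):
                directed_assort = math.nan

    transitivity = float(nx.transitivity(und))
    m = network.number_of_edges()
    density = m / (n * (n - 1))

    deg = dict(und.degree())
    in_strength = dict(network.in_degree(weight="weight"))
    out_strength = dict(network.out_degree(weight="weight"))
    nodes = pd.DataFrame(
        {
            "degree": pd.Series(deg),
            "in_strength": pd.Series(in_strength),
            "out_strength": pd.Series(out_strength),
        }
    ).fillna(0)
    nodes.index.name = "hospital_id"

    return NetworkMetrics(
        assortativity_degree=assort,
        assortativity_defined=defined,
        assortativity_directed_out_in=directed_assort,
        transitivity_global=transitivity,
        edge_density=float(density),
        n_nodes=n,
        n_edges=m,
        total_weight=int(sum(d["weight"] for _, _, d in network.edges(data=True))),
        nodes=nodes.sort_index(),
    )


@dataclass
class FlowMatrix:
    """Inter-cluster mobility: counts with row and overall percentages."""

    counts: pd.DataFrame  # (sending cluster x receiving cluster) event counts
    row_pct: pd.DataFrame  # counts / row totals, in percent
    overall_pct: pd.DataFrame  # counts / grand total, in percent

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def flow_matrix_from_counts(counts: pd.DataFrame) -> FlowMatrix:
    """Build a :class:`FlowMatrix` from a square table of event counts."""
    counts = counts.astype(int)
    total = counts.to_numpy().sum()
    if total <= 0:
        raise ValueError("flow matrix has no events")
    row_totals = counts.sum(axis=1)
    row_pct = 100.0 * counts.div(row_totals.replace(0, pd.NA), axis=0).fillna(0.0)
    overall_pct = 100.0 * counts / total
    return FlowMatrix(counts=counts, row_pct=row_pct, overall_pct=overall_pct)


def flow_matrix(events: pd.DataFrame, cluster_labels: pd.Series) -> FlowMatrix:
    """Aggregate mobility events by (sending cluster, receiving cluster)."""
    missing = (
        set(events["from_hospital"]) | set(events["to_hospital"])
    ) - set(cluster_labels.index)
    if missing:
        raise ValueError(f"events reference unlabeled hospitals: {sorted(missing)[:5]}")
    labels = sorted(cluster_labels.unique())
    frm = events["from_hospital"].map(cluster_labels)
    to = events["to_hospital"].map(cluster_labels)
    counts = (
        pd.crosstab(frm, to)
        .reindex(index=labels, columns=labels, fill_value=0)
        .rename_axis(index="from_cluster", columns="to_cluster")
    )
    return flow_matrix_from_counts(counts)
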