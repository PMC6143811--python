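"""Open tripartite gene–metabolite–pathway networks.

Significant genes, metabolites and pathways become the three disjoint node
sets of an *open* tripartite graph: edges are allowed only between genes
and metabolites and between metabolites and pathways (never gene–pathway
and never within a set).  The module builds these graphs from reporter
scores, projects them onto bipartite layers, computes the standard
topology panel (density, clustering, diameter, path length) and overlays
time-resolved networks to expose exclusive and shared structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional

import networkx as nx
import pandas as pd

from .exceptions import ValidationError
from .model import MetabolicModel

NODE_SETS = ("gene", "metabolite", "pathway")


@dataclass
class TripartiteNetwork:
    """Open tripartite graph over significant entities.

    ``genes``, ``metabolites`` and ``pathways`` map node id to its p-value;
    the id sets must be pairwise disjoint.  ``gm_edges`` joins genes to
    metabolites and ``mp_edges`` joins metabolites to pathways; any other
    edge shape is rejected at construction.
    """

    genes: dict[str, float] = field(default_factory=dict)
    metabolites: dict[str, float] = field(default_factory=dict)
    pathways: dict[str, float] = field(default_factory=dict)
    gm_edges: set[tuple[str, str]] = field(default_factory=set)
    mp_edges: set[tuple[str, str]] = field(default_factory=set)
    time_label: Optional[str] = None

    def __post_init__(self) -> None:
        g, m, p = set(self.genes), set(self.metabolites), set(self.pathways)
        if g & m or m & p or g & p:
            raise ValidationError("tripartite node sets must be pairwise disjoint")
        for a, b in self.gm_edges:
            if a not in g or b not in m:
                raise ValidationError(
                    f"illegal edge ({a!r}, {b!r}): gene–metabolite edges must join a declared "
                    "gene to a declared metabolite (same-set and gene–pathway edges are forbidden)"
                )
        for a, b in self.mp_edges:
            if a not in m or b not in p:
                raise ValidationError(
                    f"illegal edge ({a!r}, {b!r}): metabolite–pathway edges must join a declared "
                    "metabolite to a declared pathway (same-set and gene–pathway edges are forbidden)"
                )

    # ------------------------------------------------------------------

    @property
    def total_nodes(self) -> int:
        return len(self.genes) + len(self.metabolites) + len(self.pathways)

    @property
    def total_edges(self) -> int:
        return len(self.gm_edges) + len(self.mp_edges)

    def node_set(self, node: str) -> str:
        if node in self.genes:
            return "gene"
        if node in self.metabolites:
            return "metabolite"
        if node in self.pathways:
            return "pathway"
        raise KeyError(node)

    def node_ids(self) -> set[str]:
        return set(self.genes) | set(self.metabolites) | set(self.pathways)

    def edge_ids(self) -> set[tuple[str, str, str]]:
        """Edges tagged with their kind, for overlay identity."""
        return {("gm", a, b) for a, b in self.gm_edges} | {("mp", a, b) for a, b in self.mp_edges}

    def to_graph(self) -> nx.Graph:
        """Simple undirected graph with set/p node attributes and kind edge attribute."""
        g = nx.Graph()
        for ids, kind in ((self.genes, "gene"), (self.metabolites, "metabolite"), (self.pathways, "pathway")):
            for node, p in ids.items():
                g.add_node(node, set=kind, p=float(p))
        for a, b in self.gm_edges:
            g.add_edge(a, b, kind="gm")
        for a, b in self.mp_edges:
            g.add_edge(a, b, kind="mp")
        return g


def build_tripartite(
    sig_genes: Mapping[str, float] | pd.Series,
    met_scores: pd.DataFrame,
    path_scores: pd.DataFrame,
    model: MetabolicModel,
    alpha: float = 0.05,
    time_label: Optional[str] = None,
) -> TripartiteNetwork:
    """Assemble the open tripartite network of significant entities.

    Nodes are genes with p <= alpha and metabolites/pathways with corrected
    p <= alpha.  An edge appears iff both endpoints are significant and
    associated in the model.  Isolated significant nodes are retained.
    """
    gp = pd.Series(sig_genes, dtype=float)
    genes = {g: float(p) for g, p in gp.items() if p <= alpha and g in model.genes}
    mets = {m: float(p) for m, p in met_scores["p"].items() if p <= alpha}
    paths = {pw: float(p) for pw, p in path_scores["p"].items() if p <= alpha}
    gm = {(g, m) for g, m in model.gene_metabolite if g in genes and m in mets}
    mp = {(m, pw) for m, pw in model.metabolite_pathway if m in mets and pw in paths}
    return TripartiteNetwork(genes, mets, paths, gm, mp, time_label)


def drop_isolated(net: TripartiteNetwork) -> TripartiteNetwork:
    """Variant without isolated significant nodes (affects density/averages)."""
    connected = {a for e in net.gm_edges | net.mp_edges for a in e}
    return TripartiteNetwork(
        {k: v for k, v in net.genes.items() if k in connected},
        {k: v for k, v in net.metabolites.items() if k in connected},
        {k: v for k, v in net.pathways.items() if k in connected},
        set(net.gm_edges),
        set(net.mp_edges),
        net.time_label,
    )


def project(network: TripartiteNetwork, drop: Literal["G", "P"]) -> nx.Graph:
    """Bipartite projection: drop='P' keeps gene–metabolite, drop='G' keeps metabolite–pathway."""
    if drop == "P":
        sub = TripartiteNetwork(
            dict(network.genes), dict(network.metabolites), {}, set(network.gm_edges), set(), network.time_label
        )
    elif drop == "G":
        sub = TripartiteNetwork(
            {}, dict(network.metabolites), dict(network.pathways), set(), set(network.mp_edges), network.time_label
        )
    else:
        raise ValidationError(f"drop must be 'G' or 'P', got {drop!r}")
    return sub.to_graph()


@dataclass(frozen=True)
class NetworkMetrics:
    """Topology panel of a (possibly disconnected) simple undirected graph.

    Diameter and average path length refer to the largest connected
    component; they are NaN for edgeless graphs.
    """

    density: float
    avg_clustering: float
    diameter: float
    avg_path_length: float
    total_nodes: int
    total_edges: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "density": self.density,
                "avg_clustering": self.avg_clustering,
                "diameter": self.diameter,
                "avg_path_length": self.avg_path_length,
                "total_nodes": self.total_nodes,
                "total_edges": self.total_edges,
            }
        )


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Largest connected component; ties by edge count, then smallest node id."""
    comps = list(nx.connected_components(graph))
    if not comps:
        raise ValidationError("graph has no nodes")
    comps.sort(key=lambda c: (-len(c), -graph.subgraph(c).number_of_edges(), min(map(str, c))))
    return graph.subgraph(comps[0]).copy()


def network_metrics(graph: nx.Graph) -> NetworkMetrics:
    """Density, mean local clustering, LCC diameter and mean shortest path.

    Density pools all node types: 2E / (N(N-1)).  Local clustering of
    degree-<2 vertices counts as 0 in the average.
    """
    n = graph.number_of_nodes()
    if n < 1:
        raise ValidationError("network_metrics requires at least one node")
    density = nx.density(graph) if n > 1 else 0.0
    clustering = nx.average_clustering(graph) if n > 0 else 0.0
    if graph.number_of_edges() == 0:
        diameter = math.nan
        apl = math.nan
    else:
        lcc = largest_component(graph)
        diameter = float(nx.diameter(lcc))
        apl = float(nx.average_shortest_path_length(lcc))
    return NetworkMetrics(
        density=density,
        avg_clustering=clustering,
        diameter=diameter,
        avg_path_length=apl,
        total_nodes=n,
        total_edges=graph.number_of_edges(),
    )


@dataclass
class OverlayResult:
    """Set algebra over time-resolved networks.

    ``exclusive_nodes``/``exclusive_edges`` count elements present in
    exactly one network, per time label; ``shared_all_*`` hold the
    intersection across every network.  ``union`` is a graph whose nodes
    and edges carry a ``presence`` attribute (sorted tuple of time labels).
    """

    labels: list[str]
    exclusive_nodes: dict[str, set[str]]
    exclusive_edges: dict[str, set[tuple]]
    shared_all_nodes: set[str]
    shared_all_edges: set[tuple]
    union: nx.Graph

    def exclusive_node_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.exclusive_nodes.items()}

    def exclusive_edge_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.exclusive_edges.items()}


def overlay(networks: Iterable[TripartiteNetwork]) -> OverlayResult:
    """Overlay >= 2 networks by string-id node identity."""
    nets = list(networks)
    if len(nets) < 2:
        raise ValidationError("overlay requires at least 2 networks")
    labels = [str(n.time_label) for n in nets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicated time labels: {labels}")

    node_presence: dict[str, list[str]] = {}
    edge_presence: dict[tuple, list[str]] = {}
    for net, lab in zip(nets, labels):
        for node in net.node_ids():
            node_presence.setdefault(node, []).append(lab)
        for edge in net.edge_ids():
            edge_presence.setdefault(edge, []).append(lab)

    excl_nodes = {lab: set() for lab in labels}
    excl_edges = {lab: set() for lab in labels}
    for node, present in node_presence.items():
        if len(present) == 1:
            excl_nodes[present[0]].add(node)
    for edge, present in edge_presence.items():
        if len(present) == 1:
            excl_edges[present[0]].add(edge)
    shared_nodes = {n for n, present in node_presence.items() if len(present) == len(nets)}
    shared_edges = {e for e, present in edge_presence.items() if len(present) == len(nets)}

    union = nx.Graph()
    for net in nets:
        for node in net.node_ids():
            union.add_node(node, set=net.node_set(node))
    for node, present in node_presence.items():
        union.nodes[node]["presence"] = tuple(sorted(present))
    for (kind, a, b), present in edge_presence.items():
        union.add_edge(a, b, kind=kind, presence=tuple(sorted(present)))

    return OverlayResult(labels, excl_nodes, excl_edges, shared_nodes, shared_edges, union)


def metrics_table(
    networks: Iterable[TripartiteNetwork],
    overlay_result: Optional[OverlayResult] = None,
) -> pd.DataFrame:
    """Topology panel per time point, one column per network.

    Rows: density, average clustering coefficient, diameter, total nodes,
    exclusive nodes, total edges, exclusive edges, average path length.
    """
    nets = list(networks)
    if overlay_result is None and len(nets) >= 2:
        overlay_result = overlay(nets)
    cols = {}
    for net in nets:
        m = network_metrics(net.to_graph())
        lab = str(net.time_label)
        cols[lab] = {
            "density": m.density,
            "avg_clustering": m.avg_clustering,
            "diameter": m.diameter,
            "total_nodes": m.total_nodes,
            "exclusive_nodes": len(overlay_result.exclusive_nodes[lab]) if overlay_result else math.nan,
            "total_edges": m.total_edges,
            "exclusive_edges": len(overlay_result.exclusive_edges[lab]) if overlay_result else math.nan,
            "avg_path_length": m.avg_path_length,
        }
    order = [
        "density", "avg_clustering", "diameter", "total_nodes",
        "exclusive_nodes", "total_edges", "exclusive_edges", "avg_path_length",
    ]
    return pd.DataFrame(cols).reindex(order)


# ---------------------------------------------------------------------- I/O


def export_graph(network: TripartiteNetwork, fmt: Literal["graphml", "sif", "edgelist"], path) -> None:
    """Write the network as GraphML (lossless), SIF ('gm'/'mp' interactions) or TSV edge list."""
    g = network.to_graph()
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(network.gm_edges):
                fh.write(f"{a}\tgm\t{b}\n")
            for a, b in sorted(network.mp_edges):
                fh.write(f"{a}\tmp\t{b}\n")
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\tkind\ttarget\n")
            for a, b in sorted(network.gm_edges):
                fh.write(f"{a}\tgm\t{b}\n")
            for a, b in sorted(network.mp_edges):
                fh.write(f"{a}\tmp\t{b}\n")
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def import_graphml(path, time_label: Optional[str] = None) -> TripartiteNetwork:
    """Rebuild a TripartiteNetwork from a GraphML file written by export_graph."""
    g = nx.read_graphml(path)
    genes, mets, paths = {}, {}, {}
    for node, data in g.nodes(data=True):
        kind = data.get("set")
        p = float(data.get("p", math.nan))
        {"gene": genes, "metabolite": mets, "pathway": paths}[kind][node] = p
    gm, mp = set(), set()
    for a, b, data in g.edges(data=True):
        if data.get("kind") == "gm":
            gm.add((a, b) if a in genes else (b, a))
        else:
            mp.add((a, b) if a in mets else (b, a))
    return TripartiteNetwork(genes, mets, paths, gm, mp, time_label)
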