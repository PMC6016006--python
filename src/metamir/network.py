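"""Mixed gene-gene / miRNA-gene interaction network and hub analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .dataio import PPIEdge

__all__ = ["InteractionNetwork", "HubReport", "build_network", "hubs", "export"]

DEFAULT_SCORE_MIN = 0.4  # conventional medium-confidence interaction score
DEFAULT_HUB_COUNT = 6


@dataclass
class InteractionNetwork:
    """Undirected graph with typed nodes (gene | mirna) and typed edges
    (ppi | mirna_target)."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n,
                "node_type": data["node_type"],
                "degree": self.graph.degree[n],
                "is_hub": data.get("is_hub", False),
            }
            for n, data in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_id", "node_type", "degree", "is_hub"])


@dataclass
class HubReport:
    hub_ids: list[str]
    n_components_before: int
    n_components_after: int
    largest_component_before: int
    largest_component_after: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hub_id": self.hub_ids,
                "n_components_before": self.n_components_before,
                "n_components_after": self.n_components_after,
                "largest_component_before": self.largest_component_before,
                "largest_component_after": self.largest_component_after,
            }
        )


def build_network(
    ppi: Sequence[PPIEdge],
    pairs: Iterable[tuple[str, str]],
    genes_of_interest: Optional[Iterable[str]] = None,
    score_min: float = DEFAULT_SCORE_MIN,
) -> InteractionNetwork:
    """Assemble the mixed network.

    Gene-gene edges are kept when ``combined_score >= score_min`` and both
    endpoints belong to ``genes_of_interest`` (no restriction when None);
    every (miRNA, gene) pair is added as a ``mirna_target`` edge.  Isolated
    requested genes are retained as nodes.
    """
    if not 0.0 <= score_min <= 1.0:
        raise ValueError("score_min must be in [0, 1]")
    goi = set(genes_of_interest) if genes_of_interest is not None else None
    g = nx.Graph()

    if goi is not None:
        for gene in sorted(goi):
            g.add_node(gene, node_type="gene")

    for edge in ppi:
        if edge.combined_score < score_min:
            continue
        if goi is not None and not (edge.gene_a in goi and edge.gene_b in goi):
            continue
        g.add_node(edge.gene_a, node_type="gene")
        g.add_node(edge.gene_b, node_type="gene")
        g.add_edge(edge.gene_a, edge.gene_b, edge_type="ppi", score=edge.combined_score)

    for mirna, gene in pairs:
        if mirna == gene:
            raise ValueError(f"self-loop not allowed: {mirna}")
        g.add_node(mirna, node_type="mirna")
        if g.nodes.get(gene, {}).get("node_type") == "mirna":
            raise ValueError(f"{gene!r} already registered as a miRNA node")
        g.add_node(gene, node_type="gene")
        g.add_edge(mirna, gene, edge_type="mirna_target")

    if g.number_of_edges() == 0:
        warnings.warn("network has no edges", stacklevel=2)

    nx.set_node_attributes(g, {n: int(d) for n, d in g.degree()}, "degree")
    nx.set_node_attributes(g, False, "is_hub")
    return InteractionNetwork(graph=g)


def hubs(network: InteractionNetwork, h: int = DEFAULT_HUB_COUNT) -> HubReport:
    """Top-``h`` nodes by degree (ties broken lexicographically) and the
    connectivity change when they are removed.

    Also marks ``is_hub`` on the network's nodes in place.
    """
    g = network.graph
    if h < 1:
        raise ValueError("h must be >= 1")
    if h >= g.number_of_nodes():
        raise ValueError(f"h={h} must be smaller than the node count {g.number_of_nodes()}")

    ranked = sorted(g.degree(), key=lambda item: (-item[1], item[0]))
    hub_ids = [node for node, _ in ranked[:h]]

    comps_before = list(nx.connected_components(g))
    largest_before = max((len(c) for c in comps_before), default=0)

    reduced = g.copy()
    reduced.remove_nodes_from(hub_ids)
    comps_after = list(nx.connected_components(reduced))
    largest_after = max((len(c) for c in comps_after), default=0)

    nx.set_node_attributes(g, False, "is_hub")
    nx.set_node_attributes(g, {n: True for n in hub_ids}, "is_hub")

    return HubReport(
        hub_ids=hub_ids,
        n_components_before=len(comps_before),
        n_components_after=len(comps_after),
        largest_component_before=largest_before,
        largest_component_after=largest_after,
    )


def export(network: InteractionNetwork, outdir) -> dict[str, str]:
    """Write GraphML and SIF renditions; returns their paths.

    SIF uses one line per edge: ``source<TAB>edge_type<TAB>target``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graphml_path = outdir / "network.graphml"
    sif_path = outdir / "network.sif"

    nx.write_graphml(network.graph, graphml_path)

    with open(sif_path, "w", encoding="utf-8") as fh:
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{data['edge_type']}\t{b}\n")
        for node in sorted(nx.isolates(network.graph)):
            fh.write(f"{node}\n")

    return {"network_graphml": str(graphml_path), "network_sif": str(sif_path)}
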