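"""Per-TF induced PPI subnetworks and their connected components.

For each active TF, the protein products of its target genes induce a
local subnetwork in the global PPI graph.  That subnetwork decomposes into
connected components -- called WCCs here, the field's term for them even
though the PPI graph is undirected -- and each WCC is searched separately
for candidate complexes.  Isolated target proteins carry no edges and are
dropped at decomposition (a candidate needs at least two edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .data import PPINetwork, RegulatoryNetwork

__all__ = [
    "TFSubnetwork",
    "WCC",
    "build_tf_subnetwork",
    "decompose_wcc",
    "write_wcc_graphml",
]


@dataclass
class TFSubnetwork:
    """PPI subgraph induced by one TF's target-gene protein products."""

    tf: str
    graph: nx.Graph


@dataclass
class WCC:
    """One connected component of a TF subnetwork."""

    tf: str
    graph: nx.Graph

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_tf_subnetwork(
    tf: str, tr: RegulatoryNetwork, ppi: PPINetwork
) -> TFSubnetwork:
    """Induce the PPI subgraph over proteins coding for the TF's targets."""
    if tf not in tr.tfs:
        raise KeyError(f"unknown TF {tf!r}")
    targets = tr.targets_of(tf)
    nodes = {p for p in ppi.proteins if ppi.gene_of(p) in targets}
    return TFSubnetwork(tf=tf, graph=ppi.induced(nodes))


def decompose_wcc(sub: TFSubnetwork) -> list[WCC]:
    """Split a TF subnetwork into its connected components.

    Isolated nodes are discarded; output is sorted by (-edges, node list)
    so the decomposition is deterministic up to graph identity.
    """
    comps = []
    for nodes in nx.connected_components(sub.graph):
        if len(nodes) < 2:
            continue
        comps.append(WCC(tf=sub.tf, graph=sub.graph.subgraph(nodes).copy()))
    comps.sort(key=lambda w: (-w.graph.number_of_edges(), sorted(w.graph.nodes)))
    return comps


def write_wcc_graphml(wcc: WCC, path) -> None:
    """Export one WCC as GraphML for external inspection."""
    g = wcc.graph.copy()
    g.graph["tf"] = wcc.tf
    nx.write_graphml(g, path)
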