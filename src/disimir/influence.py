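"""Influence scoring on the consensus network.

A miRNA's influence is the sum, over every node reachable from it
(itself included), of that node's child count raised to 1/d, where d is
one plus the directed hop distance from the miRNA to the node.  The
miRNA's own out-degree therefore enters at full strength (d = 1), its
children's out-degrees enter under a square root (d = 2), and so on:
regulatory reach decays with distance.  Only the topology is used; edge
weights matter only as zero versus nonzero.

Disease-specific influence is the same score computed on the subnetwork
induced by the disease-associated miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import DiseaseAnnotation
from .network_inference import WeightedDirectedNetwork

__all__ = [
    "InfluenceTable", "reachable_with_distances", "influence_score",
    "disease_specific_network", "influence_table", "to_digraph",
]


@dataclass
class InfluenceTable:
    """Whole-network and disease-specific influence per miRNA."""

    whole_network: dict[str, float]
    disease_specific: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.whole_network)
        return pd.DataFrame({
            "mirna": ids,
            "whole_network_influence": [self.whole_network[m] for m in ids],
            "disease_specific_influence": [
                self.disease_specific[m] for m in ids],
        }).set_index("mirna")


def to_digraph(net: WeightedDirectedNetwork) -> nx.DiGraph:
    """Unweighted directed topology: any nonzero edge counts as one hop."""
    g = nx.DiGraph()
    g.add_nodes_from(net.mirna_ids)
    src, tgt = np.nonzero(net.weights)
    g.add_edges_from((net.mirna_ids[i], net.mirna_ids[j])
                     for i, j in zip(src, tgt))
    return g


def reachable_with_distances(net: WeightedDirectedNetwork | nx.DiGraph,
                             m: str) -> dict[str, int]:
    """Shortest directed hop distance from ``m`` to every reachable node.

    ``m`` itself is included at distance 0; each node is visited once at
    its minimal distance, so cycles are handled.
    """
    g = net if isinstance(net, nx.DiGraph) else to_digraph(net)
    if m not in g:
        raise KeyError(f"miRNA {m!r} not in network")
    return dict(nx.single_source_shortest_path_length(g, m))


def influence_score(net: WeightedDirectedNetwork | nx.DiGraph, m: str) -> float:
    """Distance-damped child-count influence of one miRNA.

    C_m = sum over reachable nodes m' of out_degree(m') ** (1 / d) with
    d = hop distance + 1; a node with no children contributes 0, so a
    leaf's influence is exactly 0.
    """
    g = net if isinstance(net, nx.DiGraph) else to_digraph(net)
    dist = reachable_with_distances(g, m)
    score = 0.0
    for node, d in dist.items():
        n_children = g.out_degree(node)
        if n_children > 0:
            score += n_children ** (1.0 / (d + 1))
    return score


def disease_specific_network(net: WeightedDirectedNetwork,
                             ann: DiseaseAnnotation
                             ) -> WeightedDirectedNetwork:
    """Induced subgraph on the disease-associated miRNAs.

    All miRNAs not associated with the disease, and their incident
    edges, are pruned away.
    """
    keep = [i for i, name in enumerate(net.mirna_ids)
            if name in ann.associated]
    if not keep:
        raise ValueError(
            f"no network miRNA is associated with {ann.disease_name!r}; "
            "check identifier matching between expression data and "
            "annotations")
    idx = np.asarray(keep)
    ids = [net.mirna_ids[i] for i in keep]
    return WeightedDirectedNetwork(ids, net.weights[np.ix_(idx, idx)])


def influence_table(net: WeightedDirectedNetwork,
                    ann: DiseaseAnnotation) -> InfluenceTable:
    """Both influence scores for every node of the consensus network.

    Disease-specific influence is 0 for miRNAs that are not
    disease-associated (they do not appear in the pruned network).
    """
    g = to_digraph(net)
    whole = {m: influence_score(g, m) for m in net.mirna_ids}
    disease = {m: 0.0 for m in net.mirna_ids}
    dnet = disease_specific_network(net, ann)
    dg = to_digraph(dnet)
    for m in dnet.mirna_ids:
        disease[m] = influence_score(dg, m)
    return InfluenceTable(whole, disease)
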