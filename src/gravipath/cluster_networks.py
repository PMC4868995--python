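"""Pathway over-representation and PPI subnetwork summaries per gene cluster.

For each cluster of genes the over-representation of every pathway is scored
with the upper-tail hypergeometric test (the standard statistic behind
STRING-style functional enrichment): drawing n cluster genes from a universe
of U measured genes containing K pathway genes, p = P(X >= x) for the
observed overlap x.  The induced protein-protein association subnetwork is
summarized from a user-supplied edge list (nodes, edges above a confidence
cutoff, density, connected components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .dataio import GeneSetCollection, PPIEdgeList

logger = logging.getLogger(__name__)

__all__ = [
    "SubnetworkSummary",
    "hypergeometric_enrichment",
    "induced_subnetwork",
]

ENRICHMENT_COLUMNS = [
    "cluster_id",
    "pathway",
    "overlap",
    "cluster_size",
    "pathway_size",
    "universe_size",
    "p_value",
    "significant",
]


@dataclass
class SubnetworkSummary:
    """Induced PPI subgraph of one cluster: V nodes, E edges above the score
    cutoff, density 2E/(V(V-1)) and component sizes sorted descending."""

    cluster_id: str
    n_nodes: int
    n_edges: int
    density: float
    component_sizes: list[int]


def hypergeometric_enrichment(
    cluster_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    p_max: float = 1e-5,
    cluster_id: str = "cluster",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each pathway.

    Pathways are intersected with the universe before testing; rows are
    flagged significant when p < p_max (default 1e-5).  The p value is not
    multiplicity-corrected; apply Benjamini-Hochberg downstream if desired.
    """
    universe = set(universe)
    cluster = set(cluster_genes)
    if not universe:
        raise ValueError("universe is empty")
    if not cluster:
        raise ValueError("cluster is empty")
    stray = cluster - universe
    if stray:
        raise ValueError(
            f"cluster genes outside the universe: {sorted(stray)[:5]}"
        )
    U, n = len(universe), len(cluster)
    rows = []
    for gs in collection:
        members = set(gs.genes) & universe
        K = len(members)
        if K == 0:
            continue
        x = len(cluster & members)
        p = float(hypergeom.sf(x - 1, U, K, n))
        rows.append(
            {
                "cluster_id": cluster_id,
                "pathway": gs.name,
                "overlap": x,
                "cluster_size": n,
                "pathway_size": K,
                "universe_size": U,
                "p_value": p,
                "significant": p < p_max,
            }
        )
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if len(out):
        out = out.sort_values(["p_value", "pathway"]).reset_index(drop=True)
    return out


def induced_subnetwork(
    cluster_genes: Sequence[str],
    edges: PPIEdgeList,
    score_min: float = 0.4,
    cluster_id: str = "cluster",
) -> SubnetworkSummary:
    """Summarize the PPI subgraph induced on a cluster's genes.

    All cluster genes become nodes (genes absent from the edge list stay
    isolated and are logged); edges require both endpoints in the cluster
    and a confidence score >= score_min.
    """
    cluster = list(dict.fromkeys(cluster_genes))
    if not cluster:
        raise ValueError("cluster is empty")
    g = nx.Graph()
    g.add_nodes_from(cluster)
    members = set(cluster)
    for a, b, score in edges:
        if a in members and b in members and score >= score_min:
            g.add_edge(a, b, weight=score)
    absent = members - edges.nodes
    if absent:
        logger.info(
            "cluster %s: %d genes absent from the edge list kept as isolated "
            "nodes", cluster_id, len(absent),
        )
    v, e = g.number_of_nodes(), g.number_of_edges()
    density = 2 * e / (v * (v - 1)) if v > 1 else 0.0
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return SubnetworkSummary(
        cluster_id=cluster_id,
        n_nodes=v,
        n_edges=e,
        density=density,
        component_sizes=sizes,
    )
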