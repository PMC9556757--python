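"""Key-driver analysis: network hubs whose neighborhoods concentrate a module.

Candidates are network nodes with at least ``min_neighborhood`` genes in
their depth-d directed out-neighborhood (regulator -> target semantics; an
undirected mode is available).  Each candidate is scored by the
hypergeometric tail of the overlap between its neighborhood and the module
over the network-node universe (candidate excluded), BH-adjusted across
candidates.  Key drivers are candidates at FDR < alpha.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import DirectedGeneNetwork
from .diffexpr import bh_fdr
from .rrho import hypergeom_tail


def neighborhood(
    network: DirectedGeneNetwork,
    gene: str,
    depth: int = 1,
    undirected: bool = False,
) -> set[str]:
    """Genes reachable within ``depth`` steps from ``gene``, seed excluded."""
    g = network.graph.to_undirected(as_view=True) if undirected else network.graph
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    reached = nx.single_source_shortest_path_length(g, gene, cutoff=depth)
    return set(reached) - {gene}


def kda(
    network: DirectedGeneNetwork,
    module_genes,
    depth: int = 1,
    min_neighborhood: int = 5,
    alpha: float = 0.05,
    undirected: bool = False,
) -> pd.DataFrame:
    """Neighborhood enrichment of the module across all candidate nodes."""
    nodes = network.nodes
    module = set(module_genes) & nodes
    if not module:
        raise ValueError("module has no genes on the network")
    rows = []
    for cand in sorted(nodes):
        hood = neighborhood(network, cand, depth=depth, undirected=undirected)
        if len(hood) < min_neighborhood:
            continue
        universe = nodes - {cand}
        K = len(module - {cand})
        n = len(hood)
        k = len(hood & module)
        p = hypergeom_tail(k, K, n, len(universe))
        rows.append(
            {
                "gene_id": cand,
                "depth": depth,
                "neighborhood_size": n,
                "overlap": k,
                "p": p,
            }
        )
    if not rows:
        raise ValueError(
            f"no candidate has a neighborhood of >= {min_neighborhood} genes"
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["is_key_driver"] = out["fdr"] < alpha
    return out.sort_values(["p", "gene_id"]).reset_index(drop=True)


def shared_key_drivers(
    kd_a: pd.DataFrame, kd_b: pd.DataFrame
) -> pd.DataFrame:
    """Key drivers called in both analyses, with both p-values reported."""
    a = kd_a.loc[kd_a["is_key_driver"].astype(bool)].set_index("gene_id")
    b = kd_b.loc[kd_b["is_key_driver"].astype(bool)].set_index("gene_id")
    shared = sorted(set(a.index) & set(b.index))
    return pd.DataFrame(
        {
            "gene_id": shared,
            "p_a": [a.at[g, "p"] for g in shared],
            "p_b": [b.at[g, "p"] for g in shared],
        }
    )


def extract_subnetwork(
    network: DirectedGeneNetwork,
    key_drivers,
    module_genes,
    depth: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KD-centered subnetwork: union of KD neighborhoods, role-annotated.

    Roles: ``key_driver`` > ``module`` > ``connector`` (nodes pulled in by a
    neighborhood but outside the module).  Edges are restricted to the node
    union.  Returns (node table, edge table).
    """
    kds = list(dict.fromkeys(key_drivers))
    if not kds:
        raise ValueError("need at least one key driver")
    module = set(module_genes)
    nodes: set[str] = set(kds)
    for kd_gene in kds:
        nodes |= neighborhood(network, kd_gene, depth=depth)
    roles = {}
    for node in nodes:
        if node in kds:
            roles[node] = "key_driver"
        elif node in module:
            roles[node] = "module"
        else:
            roles[node] = "connector"
    node_table = pd.DataFrame(
        sorted(roles.items()), columns=["gene_id", "role"]
    )
    edge_table = pd.DataFrame(
        [
            (u, v)
            for u, v in network.edges
            if u in nodes and v in nodes
        ],
        columns=["source", "target"],
    )
    return node_table, edge_table
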