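"""Filtered differential regulatory subnetworks and Laplacian centrality.

The subnetwork keeps TFs with significant differential involvement,
target genes that are both differentially expressed and annotated to a
process matching one of the cell-fate keywords (aging/senescence,
apoptosis, arrest, autophagy, cycle, death, differentiation, division,
exhaustion, phagocytosis, proliferation, quiescence), and directed
TF -> gene edges whose predicted interaction is strictly stronger in
the case state; the edge weight is the case-minus-control difference.

Node importance is the Laplacian centrality: the relative drop in the
graph's Laplacian energy E = sum_v s_v^2 + 2 sum_{u<v} w_uv^2 when the
node is removed, computed on the symmetrized weight matrix (the graph
is strictly bipartite, so TF strengths are out-strengths and gene
strengths in-strengths).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_KEYWORDS",
    "build_subnetwork",
    "laplacian_centrality",
    "rank_regulators",
]

# cell-fate keyword list; "aging/senescence" is split into alternatives
# and "apoptot" covers GO's adjectival phrasing ("apoptotic process"),
# which the noun "apoptosis" would never substring-match
DEFAULT_KEYWORDS = (
    "aging", "senescence", "apoptosis", "apoptot", "arrest", "autophagy",
    "cycle", "death", "differentiation", "division", "exhaustion",
    "phagocytosis", "proliferation", "quiescence",
)


def _keyword_match(processes, keywords) -> bool:
    kws = [k.lower() for k in keywords]
    return any(k in str(p).lower() for p in processes for k in kws)


def build_subnetwork(
    dtfi_table: pd.DataFrame,
    de_table: pd.DataFrame,
    net_case: pd.DataFrame,
    net_control: pd.DataFrame,
    annotations: dict[str, list[str]],
    keywords=DEFAULT_KEYWORDS,
    dtfi_fdr: float = 0.1,
    de_fdr: float = 0.1,
) -> nx.DiGraph:
    """Rule-filtered directed TF -> gene subnetwork.

    Parameters
    ----------
    dtfi_table : per-TF table with a ``q`` column (see transition.DTFIResult).
    de_table : per-gene table with a ``q`` column (see stats.DEResult).
    net_case, net_control : gene x TF weight matrices, identical axes.
    annotations : gene -> list of process names; keyword matching is
        case-insensitive substring match.
    """
    if not net_case.index.equals(net_control.index) or not net_case.columns.equals(
        net_control.columns
    ):
        raise ValueError("case/control networks must share identifier universes")

    sig_tfs = [t for t in net_case.columns if t in dtfi_table.index
               and dtfi_table.loc[t, "q"] < dtfi_fdr]
    sig_genes = [
        g
        for g in net_case.index
        if g in de_table.index
        and de_table.loc[g, "q"] < de_fdr
        and _keyword_match(annotations.get(g, []), keywords)
    ]

    graph = nx.DiGraph()
    for tf in sig_tfs:
        for gene in sig_genes:
            delta = float(net_case.loc[gene, tf] - net_control.loc[gene, tf])
            if delta > 0:
                graph.add_edge(tf, gene, weight=delta)
    for tf in graph.nodes:
        if tf in sig_tfs:
            graph.nodes[tf]["role"] = "tf"
            graph.nodes[tf]["dtfi_z"] = float(dtfi_table.loc[tf, "z"]) if "z" in dtfi_table else 0.0
    for gene in sig_genes:
        if gene in graph.nodes:
            graph.nodes[gene]["role"] = "gene"
    if graph.number_of_edges() == 0:
        warnings.warn("subnetwork filter produced an empty graph")
    return graph


def laplacian_centrality(graph: nx.DiGraph) -> pd.DataFrame:
    """Laplacian centrality of every node, on the symmetrized weights.

    Uses the closed form for the energy drop after removing node v,
    dE(v) = s_v^2 + 2 sum_u s_u w_uv + sum_u w_uv^2 (s_u the full
    strengths), equivalent to recomputing the energy of G - v.
    Centralities lie in [0, 1]; the graph energy is attached as
    ``result.attrs["energy"]``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(graph.nodes)
    w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    w = w + w.T                                  # symmetrize the bipartite digraph
    s = w.sum(axis=1)
    energy = float((s**2).sum() + (w**2).sum())  # 2*sum_{u<v} w^2 = sum_{u,v} w^2
    if energy == 0:
        raise ValueError("zero-energy graph")
    drop = s**2 + 2 * (w * s[None, :]).sum(axis=1) + (w**2).sum(axis=1)
    cent = drop / energy
    table = pd.DataFrame({"centrality": cent}, index=nodes)
    table["rank"] = table["centrality"].rank(ascending=False, method="min").astype(int)
    table.attrs["energy"] = energy
    table.index.name = "node"
    return table


def rank_regulators(
    centrality: pd.DataFrame,
    graph: nx.DiGraph,
    top_k: int | None = None,
    dtfi_z: pd.Series | None = None,
) -> list[str]:
    """TF nodes sorted by centrality (descending); ties broken by dTFI
    z-score (descending) then lexicographically."""
    tfs = [n for n in centrality.index if graph.nodes[n].get("role") == "tf"]
    if not tfs:
        raise ValueError("no TF nodes in graph")

    def key(tf):
        z = float(dtfi_z.get(tf, graph.nodes[tf].get("dtfi_z", 0.0))) if dtfi_z is not None \
            else float(graph.nodes[tf].get("dtfi_z", 0.0))
        return (-centrality.loc[tf, "centrality"], -z, tf)

    ordered = sorted(tfs, key=key)
    return ordered[:top_k] if top_k else ordered
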