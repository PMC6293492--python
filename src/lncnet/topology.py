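"""Significant-edge network extraction and export.

The visualisation network keeps the top fraction (default 5%) of unique gene
pairs of the powered-Pearson adjacency as edges. Module subnetworks restrict
edges to one module and classify them by the gene types of their endpoints
(ASD-ASD, ASD-lncRNA, lncRNA-lncRNA, other) to expose the contrast in
lncRNA/ASD interactivity between modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ConfigurationError, DataError
from .network import AdjacencyMatrix

__all__ = ["EdgeList", "top_fraction_edges", "classify_and_subset", "export_network"]

EDGE_CLASSES = ("asd_asd", "asd_lnc", "lnc_lnc", "other")


@dataclass
class EdgeList:
    """Undirected weighted edges (gene_i, gene_j, weight[, edge_class]) with
    pairs canonicalised by gene-index order; no self-edges or duplicates."""

    edges: pd.DataFrame
    threshold_weight: float

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if (e["gene_i"] == e["gene_j"]).any():
                raise DataError("edge list contains self-edges")
            if e.duplicated(subset=["gene_i", "gene_j"]).any():
                raise DataError("edge list contains duplicate pairs")
            if (e["weight"] < self.threshold_weight).any():
                raise DataError("edge below the recorded threshold weight")

    def __len__(self) -> int:
        return len(self.edges)

    def class_counts(self) -> pd.Series:
        if "edge_class" not in self.edges.columns:
            return pd.Series(dtype=int)
        counts = self.edges["edge_class"].value_counts()
        return counts.reindex(EDGE_CLASSES, fill_value=0)


def top_fraction_edges(adj: AdjacencyMatrix, fraction: float = 0.05) -> EdgeList:
    """Keep the top ``fraction`` of unique gene pairs by adjacency weight.

    Over the n(n-1)/2 off-diagonal pairs, the top ``ceil(fraction * count)``
    weights are kept; ties at the cut value are all included (so the edge
    count can exceed the nominal number). The threshold weight is recorded.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("edge fraction must lie in (0, 1]")
    arr = adj.values.to_numpy(dtype=float)
    ids = list(adj.gene_ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    weights = arr[iu, ju]
    n_keep = math.ceil(fraction * weights.size)
    # threshold = n-th largest weight; ties at the threshold all survive
    threshold = np.partition(weights, weights.size - n_keep)[weights.size - n_keep]
    mask = weights >= threshold
    edges = pd.DataFrame(
        {
            "gene_i": [ids[i] for i in iu[mask]],
            "gene_j": [ids[j] for j in ju[mask]],
            "weight": weights[mask],
        }
    )
    order = np.argsort(-edges["weight"].to_numpy(), kind="mergesort")
    return EdgeList(edges.iloc[order].reset_index(drop=True), float(threshold))


def _edge_class(asd_i: bool, lnc_i: bool, asd_j: bool, lnc_j: bool) -> str:
    if asd_i and asd_j:
        return "asd_asd"
    if (asd_i and lnc_j) or (asd_j and lnc_i):
        return "asd_lnc"
    if lnc_i and lnc_j:
        return "lnc_lnc"
    return "other"


def classify_and_subset(edges: EdgeList, annot: pd.DataFrame, part,
                        module: int) -> EdgeList:
    """Restrict an edge list to one module and classify edges by gene type.

    Keeps edges whose endpoints both belong to ``module`` and where at least
    one endpoint is a lncRNA or an ASD risk gene; assigns ``edge_class``
    from the endpoint flags.
    """
    if module not in part.module_ids():
        raise KeyError(f"unknown module {module}")
    flags = annot.set_index("gene_id")[["is_asd_risk", "is_lncRNA"]].astype(bool)
    member = set(part.genes_in(module))
    rows = []
    for rec in edges.edges.itertuples(index=False):
        if rec.gene_i not in member or rec.gene_j not in member:
            continue
        asd_i, lnc_i = flags.loc[rec.gene_i]
        asd_j, lnc_j = flags.loc[rec.gene_j]
        if not (asd_i or lnc_i or asd_j or lnc_j):
            continue
        rows.append(
            {"gene_i": rec.gene_i, "gene_j": rec.gene_j, "weight": rec.weight,
             "edge_class": _edge_class(asd_i, lnc_i, asd_j, lnc_j)}
        )
    df = pd.DataFrame(rows, columns=["gene_i", "gene_j", "weight", "edge_class"])
    return EdgeList(df, edges.threshold_weight)


def export_network(edges: EdgeList, annot: pd.DataFrame, path_prefix,
                   part=None) -> dict:
    """Write the network as a TSV edge table and a GraphML document.

    The TSV has columns (source, target, weight, class); the GraphML carries
    node attributes ``gene_type`` and (when a partition is given)
    ``module``, and round-trips through standard graph readers.
    """
    prefix = str(path_prefix)
    tsv_path, graphml_path = prefix + ".edges.tsv", prefix + ".graphml"

    table = edges.edges.rename(columns={"gene_i": "source", "gene_j": "target"})
    if "edge_class" not in table.columns:
        table["edge_class"] = "other"
    table.to_csv(tsv_path, sep="\t", index=False)

    flags = annot.set_index("gene_id")[["is_asd_risk", "is_lncRNA"]].astype(bool)
    g = nx.Graph(threshold_weight=edges.threshold_weight)
    for rec in table.itertuples(index=False):
        g.add_edge(rec.source, rec.target, weight=float(rec.weight),
                   edge_class=rec.edge_class)
    for node in g.nodes:
        asd, lnc = flags.loc[node] if node in flags.index else (False, False)
        g.nodes[node]["gene_type"] = (
            "asd" if asd else "lncRNA" if lnc else "other"
        )
        if part is not None:
            g.nodes[node]["module"] = int(part.labels.get(node, 0))
    nx.write_graphml(g, graphml_path)
    return {"edges_tsv": tsv_path, "graphml": graphml_path}
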