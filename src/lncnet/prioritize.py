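"""Guilt-by-association lncRNA prioritisation.

Each lncRNA's raw score is its summed adjacency to every known ASD risk
gene in the dataset; scores are min-max normalised over the lncRNAs
analysed, so the top candidate always maps to 1. Adjusted intramodular
connectivity — a gene's summed adjacency inside its module minus its summed
adjacency outside — is reported alongside, normalised over the range of all
genes in the dataset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datasets import ConfigurationError
from .network import AdjacencyMatrix

__all__ = [
    "asd_connectivity",
    "minmax_normalize",
    "adjusted_intramodular_connectivity",
    "priority_table",
]


def asd_connectivity(adj: AdjacencyMatrix, lnc_ids, asd_ids) -> pd.Series:
    """Summed adjacency from each lncRNA to the ASD risk gene set.

    ``score(g) = sum over a in asd_ids, a != g of adj[g, a]``; a gene that
    appears in both sets is excluded from its own sum (the diagonal would
    otherwise add a guaranteed +1).
    """
    asd_ids = pd.Index(asd_ids)
    lnc_ids = pd.Index(lnc_ids)
    if len(asd_ids) == 0:
        raise ConfigurationError("ASD gene set is empty")
    for name, ids in (("lncRNA", lnc_ids), ("ASD", asd_ids)):
        extra = ids.difference(adj.gene_ids)
        if len(extra):
            raise ConfigurationError(
                f"{name} ids missing from adjacency: {list(extra)[:5]}"
            )
    block = adj.values.loc[lnc_ids, asd_ids]
    scores = block.sum(axis=1)
    both = lnc_ids.intersection(asd_ids)
    if len(both):
        scores[both] -= 1.0  # remove the unit self-adjacency
    scores.name = "raw_asd_connectivity"
    return scores


def minmax_normalize(values: pd.Series) -> pd.Series:
    """Map values by (x - min) / (max - min) over the collection's range.

    If all values are identical the range is undefined; everything maps to 0
    with a warning.
    """
    if len(values) == 0:
        raise ConfigurationError("cannot normalise an empty collection")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("all values identical; min-max range undefined, mapped to 0",
                      stacklevel=2)
        return pd.Series(0.0, index=values.index, name=values.name)
    return (values - lo) / (hi - lo)


def adjusted_intramodular_connectivity(adj: AdjacencyMatrix, part) -> pd.DataFrame:
    """Within-module minus out-of-module summed adjacency per gene.

    ``value(g) = sum_{j in module(g), j != g} adj[g, j]
               - sum_{j not in module(g)} adj[g, j]``.

    Unassigned genes (label 0) are scored against the unassigned set as
    their "module" and flagged. The normalised column spans the range of
    all genes in the dataset.
    """
    labels = part.labels.reindex(adj.gene_ids)
    if labels.isna().any():
        raise ConfigurationError("partition does not cover the adjacency index")
    arr = adj.values.to_numpy(dtype=float)
    lab = labels.to_numpy()
    total = arr.sum(axis=1) - 1.0  # all off-diagonal adjacency
    raw = np.empty(len(lab))
    for m in np.unique(lab):
        idx = np.flatnonzero(lab == m)
        within = arr[np.ix_(idx, idx)].sum(axis=1) - 1.0
        raw[idx] = within - (total[idx] - within)
    out = pd.DataFrame(
        {
            "raw_intramodular": raw,
            "norm_intramodular": minmax_normalize(
                pd.Series(raw, index=adj.gene_ids)
            ).to_numpy(),
            "unassigned": lab == 0,
        },
        index=adj.gene_ids,
    )
    return out


def priority_table(adj: AdjacencyMatrix, annot: pd.DataFrame, part,
                   asd_ids=None) -> pd.DataFrame:
    """Ranked lncRNA priority report.

    Rows are sorted by normalised ASD connectivity descending (ties broken
    by gene id); columns carry biotype, module assignment, raw and
    normalised ASD connectivity, and raw and normalised adjusted
    intramodular connectivity. The rank is dense (1 = highest score).
    """
    annot = annot.set_index("gene_id")
    lnc_ids = annot.index[annot["is_lncRNA"].astype(bool)].intersection(adj.gene_ids)
    if asd_ids is None:
        asd_ids = annot.index[annot["is_asd_risk"].astype(bool)]
    asd_ids = pd.Index(asd_ids).intersection(adj.gene_ids)
    raw = asd_connectivity(adj, lnc_ids, asd_ids)
    norm = minmax_normalize(raw)
    intra = adjusted_intramodular_connectivity(adj, part)
    table = pd.DataFrame(
        {
            "gene_id": lnc_ids,
            "biotype": annot.loc[lnc_ids, "biotype"].to_numpy(),
            "raw_asd_connectivity": raw.to_numpy(),
            "norm_asd_connectivity": norm.to_numpy(),
            "module": part.labels.reindex(lnc_ids).fillna(0).astype(int).to_numpy(),
            "raw_intramodular": intra.loc[lnc_ids, "raw_intramodular"].to_numpy(),
            "norm_intramodular": intra.loc[lnc_ids, "norm_intramodular"].to_numpy(),
        }
    )
    table = table.sort_values(
        ["norm_asd_connectivity", "gene_id"], ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = table["norm_asd_connectivity"].rank(
        method="dense", ascending=False
    ).astype(int)
    return table
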