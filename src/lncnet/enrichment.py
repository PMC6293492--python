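"""Fisher's-exact enrichment: gene types within modules, and expressed genes
by brain structure x developmental period.

Both analyses share the same machinery: a 2x2 contingency table per unit, a
one-sided (enrichment direction) Fisher's exact test, Benjamini-Hochberg FDR
within the test family, and a ``-log10(FDR)`` transform for display (1.3010
marks FDR = 0.05).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import DataError, ExpressionMatrix, PERIODS

__all__ = [
    "fisher_enrichment_p",
    "add_fdr",
    "module_type_enrichment",
    "structure_period_enrichment",
]

#: FDR values are floored here before the -log10 transform.
FDR_FLOOR = 1e-300


def fisher_enrichment_p(a: int, b: int, c: int, d: int,
                        alternative: str = "greater") -> float:
    """One-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    With ``alternative='greater'`` this is the hypergeometric upper tail —
    the probability of observing at least ``a`` type members in the unit.
    """
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def add_fdr(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg FDR across the rows of one test family, plus the
    ``-log10(fdr)`` display column."""
    out = table.copy()
    if len(out):
        _, fdr, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
        out["fdr"] = fdr
        out["neg_log10_fdr"] = -np.log10(np.maximum(fdr, FDR_FLOOR))
        out["significant"] = out["fdr"] <= alpha
    return out


def module_type_enrichment(part, annot: pd.DataFrame, gene_type: str,
                           alternative: str = "greater",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-module enrichment of a gene type against the whole curated set.

    ``gene_type`` is ``'lncRNA'`` or ``'asd_risk'`` (a boolean annotation
    column ``is_<type>`` is looked up). For each module the 2x2 table is
    (in-module & type, in-module & not type; out-module & type, out-module &
    not type) over every partitioned gene, including the unassigned
    background. FDR is computed across modules within this gene type.
    """
    col = {"lncRNA": "is_lncRNA", "asd_risk": "is_asd_risk"}.get(gene_type)
    if col is None:
        raise DataError(f"unknown gene type {gene_type!r}")
    flags = annot.set_index("gene_id")[col].astype(bool)
    missing = part.labels.index.difference(flags.index)
    if len(missing):
        raise DataError(f"unannotated genes in partition: {list(missing)[:5]}")
    flags = flags.reindex(part.labels.index)
    total_type = int(flags.sum())
    total = len(flags)
    rows = []
    for m in part.module_ids():
        in_mod = part.labels == m
        n_mod = int(in_mod.sum())
        if n_mod == 0:
            warnings.warn(f"module {m} is empty; skipped", stacklevel=2)
            continue
        a = int((flags & in_mod).sum())
        b = n_mod - a
        c = total_type - a
        d = (total - n_mod) - c
        rows.append(
            {"module": m, "gene_type": gene_type, "a": a, "b": b, "c": c, "d": d,
             "p_value": fisher_enrichment_p(a, b, c, d, alternative)}
        )
    return add_fdr(pd.DataFrame(rows), alpha=alpha)


def structure_period_enrichment(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    module_group,
    gene_type_sets: dict,
    threshold: float = 1.0,
    alternative: str = "greater",
    alpha: float = 0.05,
    pair_counting: bool = True,
) -> pd.DataFrame:
    """Expressed-gene enrichment per (structure, period, gene type).

    For each structure/period cell, the expressed count is the number of
    gene-sample pairs with RPKM >= ``threshold`` among the type set's genes
    and the cell's samples; the total is set size x sample count. The
    background is the same pair of counts over all ``module_group`` genes.
    Cells whose structure lacks samples in a period are omitted (some
    structures have no postnatal samples). With ``pair_counting=False``
    a gene counts as expressed if it reaches the threshold in at least one
    of the cell's samples. FDR runs across the whole
    structure x period x type grid.
    """
    if expr.scale != "rpkm":
        raise DataError("structure/period enrichment counts RPKM-scale expression")
    module_group = pd.Index(module_group)
    group_expr = expr.values.loc[module_group]
    for name, ids in gene_type_sets.items():
        extra = pd.Index(ids).difference(module_group)
        if len(extra):
            raise DataError(
                f"gene type set {name!r} not contained in the module group: "
                f"{list(extra)[:5]}"
            )
    rows = []
    for structure in meta["structure"].unique():
        for period in PERIODS:
            samples = meta.loc[
                (meta["structure"] == structure) & (meta["period"] == period),
                "sample_id",
            ]
            samples = [s for s in samples if s in group_expr.columns]
            if not samples:
                continue  # structure absent in this period
            block = group_expr[samples].to_numpy() >= threshold
            if pair_counting:
                bg_expressed = int(block.sum())
                bg_total = block.size
            else:
                bg_expressed = int(block.any(axis=1).sum())
                bg_total = block.shape[0]
            for name, ids in gene_type_sets.items():
                sub = group_expr.index.isin(set(ids))
                tblock = block[sub]
                if pair_counting:
                    a = int(tblock.sum())
                    total = tblock.size
                else:
                    a = int(tblock.any(axis=1).sum())
                    total = tblock.shape[0]
                b = total - a
                c = bg_expressed
                d = bg_total - bg_expressed
                rows.append(
                    {"structure": structure, "period": period, "gene_type": name,
                     "a": a, "b": b, "c": c, "d": d,
                     "p_value": fisher_enrichment_p(a, b, c, d, alternative)}
                )
    return add_fdr(pd.DataFrame(rows), alpha=alpha)
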