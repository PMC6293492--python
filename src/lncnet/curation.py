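"""Dataset curation: expression filtering, log transform, covariance-sum
screening, and ASD risk gene-set compilation.

Curation removes two kinds of uninformative genes before network
construction: genes that never reach a minimum expression level (default
1 RPKM in at least one sample), and "low-information" genes whose summed
pairwise covariance with the rest of the dataset is small. The latter is a
1-dimensional 2-means split on the per-gene covariance sums, keeping the
cluster with the larger mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datasets import ConfigurationError, DataError, ExpressionMatrix

__all__ = [
    "filter_min_expression",
    "log_transform",
    "covariance_sum",
    "kmeans_low_information_filter",
    "compile_asd_gene_set",
    "curate",
]


def filter_min_expression(expr: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose maximum over samples is >= ``threshold`` RPKM.

    The boundary is inclusive: a gene reaching exactly the threshold in a
    single sample is retained. Gene order is preserved.
    """
    if expr.scale != "rpkm":
        raise DataError("minimum-expression filter requires RPKM-scale values")
    keep = expr.values.max(axis=1) >= threshold
    if not keep.any():
        warnings.warn("minimum-expression filter removed every gene", stacklevel=2)
    return ExpressionMatrix(expr.values.loc[keep], scale="rpkm")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply x -> log2(x + 1) and retag the matrix as log2 scale."""
    if expr.scale != "rpkm":
        raise DataError("log transform expects RPKM-scale values")
    return ExpressionMatrix(np.log2(expr.values + 1.0), scale="log2")


def covariance_sum(
    expr: ExpressionMatrix,
    include_diagonal: bool = True,
    absolute: bool = False,
) -> pd.DataFrame:
    """Per-gene sum of pairwise covariances over all genes (log2 scale).

    For gene i the default is the covariance-matrix row sum
    ``cov_sum_i = sum_j cov(x_i, x_j)`` including the diagonal (the gene's
    own variance). Because covariance is bilinear this equals
    ``cov(x_i, sum_j x_j)``, so the full gene x gene matrix is never
    materialised. Covariances use the unbiased (n - 1) denominator; any
    consistent choice only rescales the sums and cannot move the 2-means
    split. With ``absolute=True`` the sum runs over |cov| instead, which
    requires the dense covariance matrix.

    Returns a DataFrame indexed by gene id with a ``cov_sum`` column.
    """
    if expr.scale != "log2":
        raise DataError("covariance sums are defined on the log2 scale")
    if expr.n_samples < 2:
        raise DataError("covariance requires at least 2 samples")
    x = expr.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    n = x.shape[1]
    if absolute:
        cov = (xc @ xc.T) / (n - 1)
        sums = np.abs(cov).sum(axis=1)
        if not include_diagonal:
            sums -= np.abs(np.diag(cov))
    else:
        total = xc.sum(axis=0)
        sums = (xc @ total) / (n - 1)
        if not include_diagonal:
            sums -= (xc * xc).sum(axis=1) / (n - 1)
    return pd.DataFrame({"cov_sum": sums}, index=expr.gene_ids)


def kmeans_low_information_filter(cov: pd.DataFrame, seed: int = 0,
                                  n_init: int = 10) -> pd.DataFrame:
    """Set a ``keep`` flag by 2-means clustering of the covariance sums.

    Genes in the cluster with the larger mean (high information, high summed
    covariance) are kept. If every value is identical the split is undefined
    and all genes are kept with a warning.
    """
    values = cov["cov_sum"].to_numpy(dtype=float)
    out = cov.copy()
    if np.unique(values).size < 2:
        warnings.warn(
            "all covariance sums identical; degenerate clustering keeps all genes",
            stacklevel=2,
        )
        out["keep"] = True
        return out
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    high = int(np.argmax(km.cluster_centers_.ravel()))
    out["keep"] = labels == high
    return out


def compile_asd_gene_set(*lists) -> tuple:
    """Union one or more ASD risk gene-id collections, dropping redundancy.

    Returns ``(gene_set, report)`` where the report records per-list sizes
    and the final union size.
    """
    union: set = set()
    per_list = []
    for i, ids in enumerate(lists):
        ids = set(ids)
        per_list.append({"list": i + 1, "n": len(ids)})
        union |= ids
    if not union:
        warnings.warn("ASD gene-set union is empty", stacklevel=2)
    report = {"per_list": per_list, "n_union": len(union)}
    return union, report


@dataclass
class CurationResult:
    """Outputs of the full curation stage."""

    expression: ExpressionMatrix  # log2 scale, curated genes only
    covariance: pd.DataFrame  # cov_sum + keep for every min-expressed gene
    n_input: int
    n_min_expressed: int
    n_kept: int


def curate(expr: ExpressionMatrix, min_rpkm: float = 1.0, seed: int = 0,
           include_diagonal: bool = True, absolute: bool = False) -> CurationResult:
    """Run the curation chain: expression filter -> log2 transform ->
    covariance sums -> 2-means low-information filter."""
    filtered = filter_min_expression(expr, threshold=min_rpkm)
    logged = log_transform(filtered)
    cov = covariance_sum(logged, include_diagonal=include_diagonal, absolute=absolute)
    cov = kmeans_low_information_filter(cov, seed=seed)
    kept = cov.index[cov["keep"]]
    return CurationResult(
        expression=logged.subset_genes(kept),
        covariance=cov,
        n_input=expr.n_genes,
        n_min_expressed=filtered.n_genes,
        n_kept=len(kept),
    )
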