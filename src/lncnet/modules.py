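"""Module detection: TOM-dissimilarity clustering, tree cutting, eigengenes.

Genes are clustered by average-linkage agglomeration on ``1 - TOM``. Modules
are the dendrogram branches obtained by cutting at a static height (default
0.99 x the maximum merge height) that also satisfy a minimum size, followed
by an optional PAM-like stage that assigns leftover genes to the nearest
module when they sit within its internal dissimilarity spread. This is a
deliberate, documented approximation of the hybrid dynamic tree-cut scheme.

Each module is summarised by its eigengene — the first principal component
of the standardised member x sample submatrix — and modules whose eigengenes
are closer than a merge cut height (default ``1 - cor < 0.2``) are merged
iteratively, closest pair first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datasets import DataError, chronological_order

__all__ = [
    "ModulePartition",
    "EigengeneSet",
    "cluster_dendrogram",
    "dynamic_tree_cut",
    "module_eigengenes",
    "merge_close_modules",
    "eigengene_heatmap_table",
    "dendrogram_to_newick",
]


@dataclass
class ModulePartition:
    """Gene -> integer module label; 0 marks unassigned ("grey") genes."""

    labels: pd.Series
    min_module_size: int = 30
    merge_cut_height: float | None = None

    def module_ids(self) -> list:
        return sorted(set(self.labels) - {0})

    def module_sizes(self) -> pd.Series:
        counts = self.labels[self.labels != 0].value_counts().sort_index()
        counts.name = "size"
        return counts

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    @property
    def n_modules(self) -> int:
        return len(self.module_ids())

    def to_tsv(self, path) -> None:
        self.labels.rename("module").to_frame().to_csv(
            path, sep="\t", index_label="gene_id"
        )


@dataclass
class EigengeneSet:
    """Module eigengenes: unit-norm module x sample profiles plus the
    fraction of module variance each first component explains."""

    profiles: pd.DataFrame
    variance_explained: pd.Series


def cluster_dendrogram(tom: pd.DataFrame) -> np.ndarray:
    """Average-linkage merge tree over genes from TOM dissimilarity.

    Returns a scipy linkage matrix; merge heights are non-decreasing.
    """
    if tom.shape[0] < 2:
        raise DataError("clustering requires at least 2 genes")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(np.clip(diss, 0.0, None), checks=False)
    return hierarchy.linkage(condensed, method="average")


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K by decreasing size (ties: first-gene order)."""
    out = np.zeros_like(labels)
    info = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        idx = np.flatnonzero(labels == lab)
        info.append((-len(idx), idx[0], lab))
    for new, (_, _, old) in enumerate(sorted(info), start=1):
        out[labels == old] = new
    return out


def dynamic_tree_cut(
    dendrogram: np.ndarray,
    diss: pd.DataFrame,
    min_size: int = 30,
    cut_height: float | None = None,
    pam_stage: bool = True,
    pam_quantile: float = 0.9,
) -> ModulePartition:
    """Cut a dendrogram into modules respecting a minimum size.

    Branches are identified by cutting at ``cut_height`` (default 0.99 x the
    maximum merge height); branches smaller than ``min_size`` are left
    unassigned (label 0). The PAM-like stage then assigns each unassigned
    gene to the module with the smallest mean dissimilarity, provided that
    mean falls below the ``pam_quantile`` quantile of the module's internal
    pairwise dissimilarities. Labels are 1..K by decreasing size.
    """
    n = diss.shape[0]
    gene_ids = diss.index
    if min_size > n:
        warnings.warn("min_size exceeds gene count; all genes unassigned",
                      stacklevel=2)
        return ModulePartition(pd.Series(0, index=gene_ids), min_size)
    heights = dendrogram[:, 2]
    if cut_height is None:
        cut_height = 0.99 * float(heights.max())
    raw = hierarchy.fcluster(dendrogram, t=cut_height, criterion="distance")
    labels = raw.copy()
    for lab, count in zip(*np.unique(raw, return_counts=True)):
        if count < min_size:
            labels[raw == lab] = 0
    labels = _relabel_by_size(labels)

    if pam_stage and (labels == 0).any() and labels.max() > 0:
        d = diss.to_numpy(dtype=float)
        module_ids = [m for m in np.unique(labels) if m != 0]
        members = {m: np.flatnonzero(labels == m) for m in module_ids}
        radius = {}
        for m, idx in members.items():
            within = d[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
            radius[m] = np.quantile(within, pam_quantile) if within.size else 0.0
        assigned = labels.copy()
        for g in np.flatnonzero(labels == 0):
            means = {m: d[g, idx].mean() for m, idx in members.items()}
            best = min(means, key=lambda m: (means[m], m))
            if means[best] < radius[best]:
                assigned[g] = best
        labels = assigned

    return ModulePartition(pd.Series(labels, index=gene_ids), min_size)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _orient(profile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip the eigengene so it correlates non-negatively with the module's
    mean expression profile; exact ties resolve to a positive first nonzero
    coordinate."""
    c = float(profile @ reference)
    if c < 0:
        return -profile
    if c == 0:
        nz = np.flatnonzero(profile)
        if nz.size and profile[nz[0]] < 0:
            return -profile
    return profile


def module_eigengenes(expr, part: ModulePartition) -> EigengeneSet:
    """First-principal-component eigengene per module.

    Member genes are standardised over samples; the module profile is the
    first right singular vector of the member x sample matrix (unit
    Euclidean norm), and ``variance_explained`` is the first squared
    singular value over the total.
    """
    missing = part.labels.index.difference(expr.gene_ids)
    if len(missing):
        raise DataError(f"partition genes absent from expression: {list(missing)[:5]}")
    profiles, varexp = {}, {}
    for m in part.module_ids():
        sub = expr.values.loc[part.genes_in(m)].to_numpy(dtype=float)
        xs = _standardize_rows(sub)
        if xs.shape[0] == 1:
            v = xs[0]
            norm = np.linalg.norm(v)
            profile = v / norm if norm else v
            var = 1.0
        else:
            _, s, vt = np.linalg.svd(xs, full_matrices=False)
            profile = vt[0]
            total = float(np.sum(s**2))
            var = float(s[0] ** 2 / total) if total else 0.0
        profiles[m] = _orient(profile, xs.mean(axis=0))
        varexp[m] = var
    prof = pd.DataFrame.from_dict(profiles, orient="index", dtype=float)
    prof.columns = expr.sample_ids
    prof.index.name = "module"
    return EigengeneSet(prof, pd.Series(varexp, name="variance_explained", dtype=float))


def _eigengene_dissimilarity(profiles: pd.DataFrame) -> pd.DataFrame:
    corr = np.corrcoef(profiles.to_numpy(dtype=float))
    corr = np.atleast_2d(corr)
    return pd.DataFrame(1.0 - corr, index=profiles.index, columns=profiles.index)


def merge_close_modules(expr, part: ModulePartition, eig: EigengeneSet,
                        cut_height: float = 0.2):
    """Iteratively merge module pairs with eigengene dissimilarity
    ``1 - cor(E_a, E_b) < cut_height``, closest pair first, recomputing
    eigengenes after each merge until no pair qualifies."""
    if not 0.0 < cut_height < 1.0:
        raise DataError("merge cut height must lie in (0, 1)")
    labels = part.labels.copy()
    profiles = eig.profiles
    while profiles.shape[0] > 1:
        d = _eigengene_dissimilarity(profiles).to_numpy()
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= cut_height:
            break
        a, b = sorted((profiles.index[i], profiles.index[j]))
        labels[labels == b] = a
        interim = ModulePartition(labels, part.min_module_size, cut_height)
        profiles = module_eigengenes(expr, interim).profiles
    arr = _relabel_by_size(labels.to_numpy())
    merged = ModulePartition(
        pd.Series(arr, index=labels.index), part.min_module_size, cut_height
    )
    return merged, module_eigengenes(expr, merged)


@dataclass
class HeatmapTable:
    """Eigengene heatmap payload: chronologically ordered module x sample
    matrix, hierarchical row order, and optional enrichment sidebar."""

    table: pd.DataFrame
    row_order: list
    row_linkage: np.ndarray | None
    sidebar: pd.DataFrame | None = None


def eigengene_heatmap_table(eig: EigengeneSet, meta: pd.DataFrame,
                            sidebar: pd.DataFrame | None = None) -> HeatmapTable:
    """Module x sample eigengene table with samples in chronological order
    and rows ordered by average-linkage clustering on ``1 - cor``."""
    order = [s for s in chronological_order(meta) if s in eig.profiles.columns]
    table = eig.profiles[order]
    if table.shape[0] > 1:
        d = _eigengene_dissimilarity(table).to_numpy()
        np.fill_diagonal(d, 0.0)
        link = hierarchy.linkage(
            squareform(np.clip(d, 0.0, None), checks=False), method="average"
        )
        leaf_order = [table.index[i] for i in hierarchy.leaves_list(link)]
    else:
        link = None
        leaf_order = list(table.index)
    table = table.loc[leaf_order]
    if sidebar is not None:
        sidebar = sidebar.reindex(leaf_order)
    return HeatmapTable(table, leaf_order, link, sidebar)


def dendrogram_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialise a scipy linkage matrix as a Newick string for inspection."""
    tree = hierarchy.to_tree(linkage)
    labels = list(labels)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
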