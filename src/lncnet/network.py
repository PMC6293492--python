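"""Weighted co-expression network construction.

Builds an unsigned weighted network ``a_ij = |corr(x_i, x_j)|**P`` from a
gene x sample log2 expression matrix, assesses the scale-free fit of the
resulting connectivity distribution, and computes the topological overlap
matrix (TOM) whose complement ``1 - TOM`` is the clustering dissimilarity.

Two correlation kinds coexist, matching their uses downstream: the biweight
midcorrelation (robust to single-sample outliers) feeds module detection,
while the plain Pearson correlation feeds the visualisation / prioritisation
adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ConfigurationError, DataError

__all__ = [
    "AdjacencyMatrix",
    "ScaleFreeFit",
    "correlation_matrix",
    "soft_threshold_adjacency",
    "scale_free_fit",
    "soft_threshold_scan",
    "topological_overlap",
]

#: Observations beyond this many MADs from the gene median get zero weight
#: in the biweight midcorrelation.
BICOR_MAD_CAP = 9.0

#: At most this fraction of observations on each side of the median may be
#: truncated to zero weight; when a gene's distribution would exceed it (e.g.
#: a bimodal developmental trajectory whose minority state looks like a block
#: of "outliers"), the weight function is rescaled on that side so genuinely
#: informative samples keep nonzero weight.
BICOR_MAX_P_OUTLIERS = 0.1


@dataclass
class AdjacencyMatrix:
    """Symmetric gene x gene connectivity in [0, 1] with unit diagonal."""

    values: pd.DataFrame
    power: int = 7
    corr_kind: str = "pearson"
    signed: bool = False  # always unsigned here; kept for provenance

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise DataError("adjacency matrix must be square")
        if arr.size:
            if not np.allclose(arr, arr.T, atol=1e-12):
                raise DataError("adjacency matrix must be symmetric")
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                raise DataError("adjacency entries must lie in [0, 1]")
            if not np.allclose(np.diag(arr), 1.0):
                raise DataError("adjacency diagonal must be 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit for one candidate soft-threshold power."""

    power: int
    r_squared: float  # signed negative when the log-log slope is positive
    mean_connectivity: float


def _bicor_transform(x: np.ndarray,
                     max_p_outliers: float = BICOR_MAX_P_OUTLIERS) -> np.ndarray:
    """Row-wise biweight transform; rows are scaled to unit Euclidean norm.

    Observations beyond ``BICOR_MAD_CAP`` MADs get zero weight, but no more
    than ``max_p_outliers`` of each side may be truncated: when a side's
    ``max_p_outliers`` quantile of the scaled deviation u exceeds 1 in
    magnitude, u is rescaled on that side so the quantile lands at the
    truncation boundary. Rows whose MAD is zero fall back to ordinary
    mean-centring, so their correlations reduce to Pearson. Zero-variance
    rows come back as zeros.
    """
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    out = np.empty_like(x, dtype=float)
    good = mad.ravel() > 0
    if good.any():
        u = (x[good] - med[good]) / (BICOR_MAD_CAP * mad[good])
        low_q = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
        high_q = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
        low_scale = np.maximum(-low_q, 1.0)
        high_scale = np.maximum(high_q, 1.0)
        u = np.where(u < 0, u / low_scale, u / high_scale)
        w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
        out[good] = (x[good] - med[good]) * w
    if (~good).any():
        rows = x[~good]
        out[~good] = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    nz = norms.ravel() > 0
    out[nz] /= norms[nz]
    out[~nz] = 0.0
    return out


def correlation_matrix(expr, kind: str = "pearson") -> pd.DataFrame:
    """Gene x gene correlation matrix (Pearson or biweight midcorrelation).

    Zero-variance genes get correlation 0 with every other gene (with a
    warning); the diagonal is always 1.
    """
    if expr.scale != "log2":
        raise DataError("correlations are computed on the log2 scale")
    if expr.n_samples < 3:
        raise DataError("correlation requires at least 3 samples")
    x = expr.values.to_numpy(dtype=float)
    var = x.var(axis=1)
    if (var == 0).any():
        warnings.warn(
            f"{int((var == 0).sum())} zero-variance gene(s); correlations set to 0",
            stacklevel=2,
        )
    if kind == "pearson":
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(xc, axis=1, keepdims=True)
        nz = norms.ravel() > 0
        xc[nz] /= norms[nz]
        xc[~nz] = 0.0
        corr = xc @ xc.T
    elif kind == "bicor":
        xt = _bicor_transform(x)
        corr = xt @ xt.T
    else:
        raise ConfigurationError(f"unknown correlation kind {kind!r}")
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return pd.DataFrame(corr, index=expr.gene_ids, columns=expr.gene_ids)


def soft_threshold_adjacency(corr: pd.DataFrame, power: int = 7,
                             corr_kind: str = "pearson") -> AdjacencyMatrix:
    """Unsigned soft-threshold adjacency ``a_ij = |corr_ij|**power``."""
    if power < 1:
        raise ConfigurationError("soft-threshold power must be >= 1")
    adj = np.abs(corr.to_numpy(dtype=float)) ** power
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(
        pd.DataFrame(adj, index=corr.index, columns=corr.columns),
        power=int(power),
        corr_kind=corr_kind,
    )


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the log-log connectivity-frequency regression.

    Connectivities are split into ``n_bins`` equal-width bins; within each
    non-empty bin the empirical frequency and the mean connectivity are
    regressed on log10 scale. The R^2 is returned negative when the slope is
    positive (the scale-free criterion rewards a falling degree
    distribution).
    """
    if np.ptp(k) == 0:
        warnings.warn("all connectivities identical; scale-free fit undefined",
                      stacklevel=3)
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_freq.append(np.log10(mask.mean()))
        log_k.append(np.log10(mean_k))
    if len(log_k) < 2 or np.ptp(log_k) == 0:
        warnings.warn("too few usable connectivity bins; scale-free fit undefined",
                      stacklevel=3)
        return 0.0
    fit = stats.linregress(log_k, log_freq)
    r2 = fit.rvalue ** 2
    return -r2 if fit.slope > 0 else r2


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit of an adjacency's connectivity distribution."""
    arr = adj.values.to_numpy(dtype=float)
    if arr.shape[0] < 10:
        raise DataError("scale-free fit needs at least 10 genes")
    k = arr.sum(axis=1) - 1.0  # exclude the unit diagonal
    return ScaleFreeFit(
        power=adj.power,
        r_squared=float(_scale_free_r2(k, n_bins)),
        mean_connectivity=float(k.mean()),
    )


def soft_threshold_scan(corr: pd.DataFrame, powers=range(1, 13),
                        n_bins: int = 10) -> pd.DataFrame:
    """Scale-free fit table over candidate powers (one row per power)."""
    records = []
    for p in powers:
        fit = scale_free_fit(soft_threshold_adjacency(corr, power=p), n_bins=n_bins)
        records.append(
            {"power": fit.power, "r_squared": fit.r_squared,
             "mean_connectivity": fit.mean_connectivity}
        )
    return pd.DataFrame.from_records(records)


def topological_overlap(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    For i != j, with ``l_ij = sum_u a_iu a_uj`` over shared neighbours
    ``u != i, j`` and connectivity ``k_i = sum_{u != i} a_iu``:

        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    The diagonal is 1. Entries lie in [0, 1] and combine the direct edge
    with the weight of shared neighbourhoods.
    """
    a = adj.values.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.values.index, columns=adj.values.columns)
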