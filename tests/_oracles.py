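"""Independent brute-force oracles used to check the vectorised paths.

Everything here is written as plain loops / first-principles formulas and
stays independent of the implementation modules it checks.
"""

from __future__ import annotations

import math

import numpy as np


def covariance_sum_loop(x: np.ndarray, include_diagonal: bool = True) -> np.ndarray:
    """Double-loop per-gene sum of pairwise sample covariances (n-1 denom)."""
    g, n = x.shape
    out = np.zeros(g)
    for i in range(g):
        for j in range(g):
            if not include_diagonal and i == j:
                continue
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            out[i] += float(np.dot(xi, xj)) / (n - 1)
    return out


def best_1d_two_means_split(values: np.ndarray):
    """Exhaustive threshold search for the optimal 1-D 2-means partition.

    The optimum of 2-means in one dimension is a threshold on the sorted
    values; returns a boolean mask marking the cluster with larger mean.
    """
    order = np.argsort(values)
    v = values[order]
    best_ss, best_k = np.inf, 1
    for k in range(1, len(v)):
        lo, hi = v[:k], v[k:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best_ss - 1e-12:
            best_ss, best_k = ss, k
    keep = np.zeros(len(v), dtype=bool)
    keep[order[best_k:]] = True  # upper cluster has the larger mean
    return keep


def tom_loop(a: np.ndarray) -> np.ndarray:
    """Triple-loop unsigned topological overlap."""
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return out


def bicor_pair(x: np.ndarray, y: np.ndarray, cap: float = 9.0,
               max_p_outliers: float = 0.1) -> float:
    """Direct-formula biweight midcorrelation of two vectors, with the
    side-wise rescaling that keeps at most ``max_p_outliers`` of each side at
    zero weight."""

    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (cap * mad)
        low = max(-float(np.quantile(u, max_p_outliers)), 1.0)
        high = max(float(np.quantile(u, 1.0 - max_p_outliers)), 1.0)
        u = np.array([ui / low if ui < 0 else ui / high for ui in u])
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    xt, yt = transform(x), transform(y)
    return float(np.dot(xt, yt) / (np.linalg.norm(xt) * np.linalg.norm(yt)))


def hypergeom_upper_tail(a: int, K: int, n: int, N: int) -> float:
    """P[X >= a] for X ~ Hypergeometric(N population, K type, n drawn),
    computed as an explicit tail sum of binomial-coefficient ratios."""
    denom = math.comb(N, n)
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / denom
    return total


def average_linkage_loop(d: np.ndarray) -> list:
    """Naive O(n^3) average-linkage agglomeration on a dissimilarity matrix.

    Returns merge records (id_a, id_b, height, size) with cluster ids
    numbered as scipy does (leaves 0..n-1, then n, n+1, ...).
    """
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = members
        merges.append((a, b, dist, len(members)))
        next_id += 1
    return merges


def first_pc_eig(xs: np.ndarray):
    """First right principal axis via eigendecomposition of X^T X
    (independent of the SVD route). Returns (unit vector, variance ratio)."""
    gram = xs.T @ xs
    w, v = np.linalg.eigh(gram)
    profile = v[:, -1]
    var = float(w[-1] / w.sum()) if w.sum() else 0.0
    return profile, var


def top_k_pairs_by_sort(a: np.ndarray, fraction: float):
    """All pairs (i, j, w) whose weight ties or beats the k-th largest
    off-diagonal weight, via a full sort."""
    n = a.shape[0]
    pairs = [(i, j, a[i, j]) for i in range(n) for j in range(i + 1, n)]
    weights = sorted((w for _, _, w in pairs), reverse=True)
    k = math.ceil(fraction * len(pairs))
    threshold = weights[k - 1]
    return {(i, j) for i, j, w in pairs if w >= threshold}, threshold


def scale_free_r2_loop(k: np.ndarray, n_bins: int) -> float:
    """Equal-width-bin log-log regression of the connectivity distribution,
    with plain least squares and the signed-R^2 convention."""
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    pts = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (k >= lo) & (k < hi) if b < n_bins - 1 else (k >= lo) & (k <= hi)
        if mask.sum() == 0 or k[mask].mean() <= 0:
            continue
        pts.append((np.log10(k[mask].mean()), np.log10(mask.mean())))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    xbar, ybar = xs.mean(), ys.mean()
    slope = ((xs - xbar) * (ys - ybar)).sum() / ((xs - xbar) ** 2).sum()
    resid = ys - (ybar + slope * (xs - xbar))
    r2 = 1 - (resid**2).sum() / ((ys - ybar) ** 2).sum()
    return -r2 if slope > 0 else r2
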