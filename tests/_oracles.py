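"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the simplex
grid search enumerates candidate fraction vectors directly, the cluster
validation indices are computed from their textbook definitions with
explicit loops, and the hypergeometric tail is an exact sum of binomial
coefficients.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def simplex_grid(n_dims: int, resolution: float) -> np.ndarray:
    """All points of the probability simplex with coordinates k*resolution."""
    steps = int(round(1.0 / resolution))
    if n_dims == 1:
        return np.array([[1.0]])
    if n_dims == 2:
        a = np.arange(steps + 1)
        return np.column_stack([a, steps - a]) / steps
    if n_dims == 3:
        pts = [
            (i, j, steps - i - j)
            for i in range(steps + 1)
            for j in range(steps + 1 - i)
        ]
        return np.asarray(pts, dtype=float) / steps
    raise ValueError("grid oracle supports at most 3 dimensions")


def grid_search_objective(P: np.ndarray, m: np.ndarray, resolution: float = 1e-3):
    """Minimum of ||m - P f||^2 over the simplex grid; returns (f, objective).

    Evaluated through the quadratic expansion so the full grid is cheap:
    ||m||^2 - 2 (P^T m) . f + f^T (P^T P) f.
    """
    G = simplex_grid(P.shape[1], resolution)
    PtP = P.T @ P
    Ptm = P.T @ m
    obj = (
        float(m @ m)
        - 2.0 * (G @ Ptm)
        + np.einsum("ij,jk,ik->i", G, PtP, G)
    )
    best = int(np.argmin(obj))
    return G[best], float(obj[best])


def grid_bound(P: np.ndarray, resolution: float = 1e-3) -> float:
    """Upper bound on grid-vs-true objective gap from grid spacing.

    The objective is quadratic with Hessian 2 P^T P; the nearest grid point
    to the optimum is within L2 distance resolution * sqrt(S), so the gap
    is at most lambda_max(P^T P) * S * resolution^2.
    """
    lam = float(np.linalg.eigvalsh(P.T @ P).max())
    return lam * P.shape[1] * resolution**2


def silhouette_brute(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from the definition, with s(i)=0 for singletons."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(
            D[i, labels == lab].mean()
            for lab in np.unique(labels)
            if lab != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def calinski_harabasz_brute(X: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio from the definition."""
    n, k = len(X), len(np.unique(labels))
    grand = X.mean(axis=0)
    ssb = ssw = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        c = pts.mean(axis=0)
        ssb += len(pts) * float(((c - grand) ** 2).sum())
        ssw += float(((pts - c) ** 2).sum())
    return (ssb / (k - 1)) / (ssw / (n - k))


def davies_bouldin_brute(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst centroid-scaled similarity."""
    labs = np.unique(labels)
    centroids = np.array([X[labels == lab].mean(axis=0) for lab in labs])
    scatter = np.array(
        [
            np.sqrt(((X[labels == lab] - c) ** 2).sum(axis=1)).mean()
            for lab, c in zip(labs, centroids)
        ]
    )
    k = len(labs)
    worst = []
    for i in range(k):
        ratios = [
            (scatter[i] + scatter[j])
            / np.sqrt(((centroids[i] - centroids[j]) ** 2).sum())
            for j in range(k)
            if j != i
        ]
        worst.append(max(ratios))
    return float(np.mean(worst))


def hypergeom_tail_enumeration(
    overlap: int, cluster_size: int, term_in_bg: int, bg_size: int
) -> float:
    """P(X >= overlap) by summing the exact pmf over all feasible overlaps."""
    denom = comb(bg_size, cluster_size)
    total = 0
    for x in range(overlap, min(cluster_size, term_in_bg) + 1):
        total += comb(term_in_bg, x) * comb(bg_size - term_in_bg, cluster_size - x)
    return total / denom


def spearman_brute(x, y) -> float:
    """Spearman rho via Pearson on explicitly computed average ranks."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
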