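"""ECoSigClust: consensus clustering of gene-signature correlation profiles.

The stage correlates each gene's expression with each signature's exposure
(Spearman), keeps genes significant for at least one signature at a nominal
threshold, and clusters the genes by their correlation *patterns*: k-means
is run many times from random starts, pairwise co-clustering frequencies
form a consensus matrix, and average-linkage hierarchical clustering of
``1 - consensus`` yields the final partition. The number of clusters is
chosen by internal validation indices (Silhouette, Calinski-Harabasz,
Davies-Bouldin) over a candidate range, with an explicit manual override
for interpretability-driven choices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata
from scipy.stats import t as t_dist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "spearman",
    "CorrelationProfile",
    "correlate_expression_signatures",
    "select_significant_genes",
    "consensus_kmeans",
    "cut_consensus",
    "validation_indices",
    "ClusterResult",
    "choose_k",
    "cluster_mean_correlation",
    "associate_exposure_covariate",
]


def _spearman_p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n-2 degrees of freedom."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * t_dist.sf(np.abs(t), df=n - 2)
    # |rho| = 1 gives infinite t -> p = 0; report smallest positive instead
    p = np.where(np.isfinite(t), p, np.finfo(float).tiny)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def spearman(
    x: np.ndarray, y: np.ndarray, exact: bool = False
) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    The two-sided p-value uses the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` with ``n-2`` df; with
    ``exact=True`` (intended for n < 10) the p is instead the exact
    permutation tail P(|rho_perm| >= |rho|) over all pairings.
    Constant input gives ``(nan, 1.0)`` — correlation undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), 1.0
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise ValueError("exact permutation p is for n < 10")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    return rho, float(_spearman_p_from_rho(np.array([rho]), n)[0])


@dataclass
class CorrelationProfile:
    """Per-gene Spearman statistics against every signature.

    ``rho`` and ``pval`` are genes x signatures; genes with constant
    expression are flagged in ``constant`` and carry rho = nan, p = 1.
    """

    rho: pd.DataFrame
    pval: pd.DataFrame
    constant: pd.Series


def correlate_expression_signatures(
    expression: pd.DataFrame, exposures: pd.DataFrame
) -> CorrelationProfile:
    """Vectorized Spearman of every gene against every signature exposure.

    ``expression`` is genes x samples; ``exposures`` samples x signatures,
    with identical sample sets in identical order.
    """
    if list(expression.columns) != list(exposures.index):
        raise ValueError("expression samples and exposure samples differ")
    n = expression.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    X = expression.to_numpy(dtype=float)
    E = exposures.to_numpy(dtype=float)
    rx = np.apply_along_axis(rankdata, 1, X)
    re = np.apply_along_axis(rankdata, 0, E)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    re_c = re - re.mean(axis=0, keepdims=True)
    x_sd = np.sqrt((rx_c**2).sum(axis=1))
    e_sd = np.sqrt((re_c**2).sum(axis=0))
    const_gene = x_sd == 0
    const_sig = e_sd == 0
    denom = np.outer(np.where(const_gene, 1.0, x_sd), np.where(const_sig, 1.0, e_sd))
    rho = (rx_c @ re_c) / denom
    rho[const_gene, :] = np.nan
    rho[:, const_sig] = np.nan
    pval = np.where(np.isnan(rho), 1.0, _spearman_p_from_rho(rho, n))
    genes = list(expression.index)
    sigs = list(exposures.columns)
    return CorrelationProfile(
        rho=pd.DataFrame(rho, index=genes, columns=sigs),
        pval=pd.DataFrame(pval, index=genes, columns=sigs),
        constant=pd.Series(const_gene, index=genes, name="constant"),
    )


def select_significant_genes(
    profile: CorrelationProfile, alpha: float = 0.05
) -> list[str]:
    """Genes significantly correlated (nominal p < alpha) with >= 1 signature.

    No multiple-testing correction is applied at this screening step.
    """
    min_p = profile.pval.min(axis=1)
    selected = [g for g in profile.pval.index if min_p[g] < alpha]
    if not selected:
        raise ValueError("no gene passed the significance screen")
    return selected


def consensus_kmeans(
    features: pd.DataFrame,
    k: int,
    n_runs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Co-clustering frequencies over repeated random-start k-means runs.

    Each run is Lloyd's algorithm on the Euclidean geometry of the
    correlation rows, initialized from k data points drawn uniformly at
    random (run r uses random state ``seed + r``). Entry (i, j) of the
    result is the fraction of runs in which genes i and j share a cluster.
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError("k must be smaller than the number of items")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct feature rows than clusters")
    M = np.zeros((n, n))
    for r in range(n_runs):
        km = KMeans(
            n_clusters=k, init="random", n_init=1, random_state=int(seed) + r
        ).fit(X)
        labels = km.labels_
        M += labels[:, None] == labels[None, :]
    M /= n_runs
    np.fill_diagonal(M, 1.0)
    ids = list(features.index)
    return pd.DataFrame(M, index=ids, columns=ids)


def cut_consensus(consensus: pd.DataFrame, k: int) -> pd.Series:
    """Average-linkage hierarchical cut of the consensus matrix into k groups.

    Distance is ``1 - consensus``; the result is deterministic given the
    matrix. Cluster labels are relabeled 1..k by first appearance.
    """
    n = consensus.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k exceeds number of items")
    D = 1.0 - consensus.to_numpy(dtype=float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[i] = relabel[lab]
    return pd.Series(labels, index=list(consensus.index), name="cluster")


def validation_indices(
    features: pd.DataFrame, assignment: pd.Series
) -> dict[str, float]:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin on Euclidean rows.

    Returns ``nan`` for an index undefined for the given partition (e.g.
    silhouette when every item is its own cluster).
    """
    X = features.to_numpy(dtype=float)
    labels = assignment.reindex(features.index).to_numpy()
    n_labels = len(np.unique(labels))
    if n_labels < 2:
        raise ValueError("validation indices need >= 2 clusters")
    out: dict[str, float] = {}
    try:
        out["silhouette"] = float(silhouette_score(X, labels))
    except ValueError:
        out["silhouette"] = float("nan")
    try:
        out["calinski_harabasz"] = float(calinski_harabasz_score(X, labels))
    except (ValueError, ZeroDivisionError):
        out["calinski_harabasz"] = float("nan")
    try:
        out["davies_bouldin"] = float(davies_bouldin_score(X, labels))
    except (ValueError, ZeroDivisionError):
        out["davies_bouldin"] = float("nan")
    return out


@dataclass
class ClusterResult:
    """Chosen partition plus the per-k validation trace."""

    k: int
    assignment: pd.Series
    cluster_mean_rho: pd.DataFrame
    validation: pd.DataFrame  # index = candidate k, columns = the 3 indices


def choose_k(
    features: pd.DataFrame,
    k_range: range | list[int] = range(5, 51),
    n_runs: int = 100,
    seed: int = 0,
    k_override: int | None = None,
) -> ClusterResult:
    """Consensus-cluster at each candidate k and pick the partition.

    For every k the pipeline is consensus k-means, then a hierarchical cut
    of the consensus matrix, then the three validation indices on the
    resulting partition. The default choice maximizes silhouette; all three
    indices are always reported so a manual, interpretability-driven
    ``k_override`` can be justified and honored.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    n = features.shape[0]
    for k in ks:
        if not (2 <= k < n):
            raise ValueError(f"candidate k={k} outside (2, n_items)")
    assignments: dict[int, pd.Series] = {}
    rows = []
    for k in ks:
        M = consensus_kmeans(features, k, n_runs=n_runs, seed=seed)
        assignment = cut_consensus(M, k)
        idx = validation_indices(features, assignment)
        assignments[k] = assignment
        rows.append({"k": k, **idx})
    validation = pd.DataFrame(rows).set_index("k")
    if k_override is not None:
        if k_override not in assignments:
            raise ValueError(f"k_override={k_override} not in candidate range")
        best_k = int(k_override)
    else:
        sil = validation["silhouette"]
        best_k = int(sil.idxmax()) if sil.notna().any() else ks[0]
    assignment = assignments[best_k]
    return ClusterResult(
        k=best_k,
        assignment=assignment,
        cluster_mean_rho=cluster_mean_correlation(features, assignment),
        validation=validation,
    )


def cluster_mean_correlation(
    rho: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """Arithmetic mean correlation row per cluster (heatmap source)."""
    aligned = assignment.reindex(rho.index)
    if aligned.isna().any():
        raise ValueError("assignment does not cover all genes in the profile")
    means = rho.groupby(aligned).mean()
    means.index = [int(c) for c in means.index]
    means.index.name = "cluster"
    return means


def associate_exposure_covariate(
    exposures: pd.DataFrame,
    covariate: pd.Series,
    kind: str = "continuous",
) -> pd.DataFrame:
    """Association of each signature's exposure with a per-sample covariate.

    ``kind='continuous'`` or ``'ordinal'`` uses Spearman (e.g. age, tumor
    grade); ``'binary'`` uses the two-sided Wilcoxon rank-sum test with the
    tie-corrected normal approximation (e.g. smoking status). Missing
    covariate values are dropped pairwise. A constant covariate is flagged
    with statistic nan and p = 1.
    """
    cov = covariate.reindex(exposures.index)
    mask = cov.notna()
    if int(mask.sum()) < 4:
        raise ValueError("need at least 4 samples with a covariate value")
    cov = cov[mask]
    rows = []
    for sig in exposures.columns:
        x = exposures.loc[mask, sig].to_numpy(dtype=float)
        if kind in ("continuous", "ordinal"):
            stat, p = spearman(x, cov.to_numpy(dtype=float))
        elif kind == "binary":
            groups = cov.astype(float)
            levels = np.unique(groups)
            if len(levels) != 2:
                stat, p = float("nan"), 1.0
            else:
                a = x[groups.to_numpy() == levels[0]]
                b = x[groups.to_numpy() == levels[1]]
                res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown covariate kind: {kind!r}")
        if math.isnan(stat):
            p = 1.0
        rows.append({"signature": sig, "statistic": stat, "pvalue": p})
    return pd.DataFrame(rows).set_index("signature")
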