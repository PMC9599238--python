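"""Reference-based cell-type deconvolution of bulk expression.

Bulk samples and cell-type reference profiles are put on a common CPM
scale, low-expression genes are dropped, marker genes are chosen per cell
type by fold change, and per-sample fractions are estimated by
non-negative least squares on the marker space with renormalization onto
the simplex. Lineage subsets (epithelial / immune) are renormalized
fraction blocks whose correlation with signature exposures is the stage's
readout.

This is a deliberately open, fully testable estimator occupying the
analysis slot that hosted nu-SVR deconvolution services fill: the analysis
contract downstream (simplex fractions fed to Spearman) is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .ecosigclust import spearman


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: per-sample totals scaled to 1,000,000."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-total samples: {bad}")
    return counts * (1_000_000.0 / totals)


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0) -> pd.DataFrame:
    """CPM-normalize and keep genes with max CPM strictly above ``min_cpm``."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    normalized = cpm(counts)
    keep = normalized.max(axis=1) > min_cpm
    if not keep.any():
        raise ValueError("no gene passed the CPM filter")
    return normalized.loc[keep]


def select_markers(
    reference: pd.DataFrame, n_markers: int = 50
) -> pd.DataFrame:
    """Top-``n_markers`` genes per cell type by log fold change.

    Fold change compares a type's profile value to the mean of the other
    types (pseudocount 1); ties break by gene id. Returns the reference
    restricted to the union of markers.
    """
    X = reference.to_numpy(dtype=float)
    T = X.shape[1]
    if T < 2:
        raise ValueError("need at least 2 cell types")
    marker_genes: set[str] = set()
    genes = np.array(reference.index)
    for t in range(T):
        others = np.delete(X, t, axis=1).mean(axis=1)
        lfc = np.log2((X[:, t] + 1.0) / (others + 1.0))
        order = np.lexsort((genes, -lfc))
        marker_genes.update(genes[order[:n_markers]])
    keep = [g for g in reference.index if g in marker_genes]
    return reference.loc[keep]


@dataclass
class FractionResult:
    """Simplex cell-type fractions plus per-sample NNLS residuals.

    Samples where the NNLS weights were all zero (no signal) are flagged.
    """

    fractions: pd.DataFrame
    residual: pd.Series
    zero_signal: pd.Series


def estimate_fractions(
    bulk_cpm: pd.DataFrame,
    reference_cpm: pd.DataFrame,
    n_markers: int = 50,
) -> FractionResult:
    """NNLS deconvolution of bulk profiles on marker-restricted references.

    Per sample, solve ``min ||b - R w||_2, w >= 0`` over the shared marker
    gene space and renormalize the weights to fractions summing to 1.
    """
    markers = select_markers(reference_cpm, n_markers=n_markers)
    shared = [g for g in markers.index if g in bulk_cpm.index]
    if not shared:
        raise ValueError("no shared genes between bulk and reference markers")
    R = markers.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        corr = np.corrcoef(R.T)
        pairs = [
            (markers.columns[i], markers.columns[j])
            for i in range(R.shape[1])
            for j in range(i + 1, R.shape[1])
            if corr[i, j] > 0.999
        ]
        raise ValueError(
            f"reference is rank-deficient on markers; collinear type pairs: {pairs}"
        )
    B = bulk_cpm.loc[shared].to_numpy(dtype=float)
    n_samples = B.shape[1]
    T = R.shape[1]
    fractions = np.zeros((n_samples, T))
    residual = np.zeros(n_samples)
    zero_signal = np.zeros(n_samples, dtype=bool)
    for j in range(n_samples):
        w, rnorm = nnls(R, B[:, j])
        s = w.sum()
        if s == 0:
            zero_signal[j] = True
        else:
            fractions[j] = w / s
        residual[j] = rnorm
    samples = list(bulk_cpm.columns)
    return FractionResult(
        fractions=pd.DataFrame(
            fractions, index=samples, columns=list(reference_cpm.columns)
        ),
        residual=pd.Series(residual, index=samples, name="nnls_residual"),
        zero_signal=pd.Series(zero_signal, index=samples, name="zero_signal"),
    )


def subset_fractions(
    fractions: pd.DataFrame,
    lineage_map: dict[str, str],
    lineage: str,
) -> pd.DataFrame:
    """Restrict fractions to one lineage and renormalize rows onto the simplex.

    Rows with zero total lineage fraction are left all-zero (flagged by the
    caller via the row sum).
    """
    types = [t for t in fractions.columns if lineage_map.get(t) == lineage]
    if not types:
        raise ValueError(f"no cell type in lineage {lineage!r}")
    sub = fractions[types]
    totals = sub.sum(axis=1)
    safe = totals.replace(0.0, 1.0)
    return sub.div(safe, axis=0)


def correlate_fractions_signatures(
    fractions: pd.DataFrame, exposures: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman of each cell type's fraction with each signature's exposure.

    Returns (rho, p) tables of shape cell types x signatures; samples must
    align exactly.
    """
    if list(fractions.index) != list(exposures.index):
        raise ValueError("fraction and exposure samples are misaligned")
    if fractions.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    rho = np.zeros((fractions.shape[1], exposures.shape[1]))
    pval = np.ones_like(rho)
    for i, ct in enumerate(fractions.columns):
        for j, sig in enumerate(exposures.columns):
            r, p = spearman(
                fractions[ct].to_numpy(dtype=float),
                exposures[sig].to_numpy(dtype=float),
            )
            rho[i, j] = r
            pval[i, j] = p
    ct_ids = list(fractions.columns)
    sig_ids = list(exposures.columns)
    return (
        pd.DataFrame(rho, index=ct_ids, columns=sig_ids),
        pd.DataFrame(pval, index=ct_ids, columns=sig_ids),
    )
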