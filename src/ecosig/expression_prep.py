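"""Count normalization and donor harmonization for the correlation stage.

The downstream statistic is Spearman correlation across samples, so a full
variance-stabilizing transform is not required; counts are normalized with
median-of-ratios size factors and a ``log2(x/sf + 1)`` transform, which is
monotone per sample and pluggable should a heavier transform be wanted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    For each sample j, the factor is the median over reference genes of
    ``count_gj / geometric_mean_g``, where reference genes are those with
    nonzero counts in every sample.

    Raises
    ------
    ValueError
        If fewer than 2 samples, or no gene is nonzero in all samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative counts")
    all_nonzero = (X > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    ref = X[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=list(counts.columns), name="size_factor")


def normalize_log(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Size-factor-normalized ``log2(count/factor + 1)`` expression values."""
    f = factors.reindex(counts.columns)
    if (f <= 0).any() or f.isna().any():
        raise ValueError("size factors must be positive and cover all samples")
    return np.log2(counts.div(f, axis=1) + 1.0)


def harmonize_donors(
    exposures: pd.DataFrame,
    expression: pd.DataFrame,
    id_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Restrict exposures (samples x signatures) and expression (genes x
    samples) to their common donors, in a shared deterministic order.

    ``id_map`` maps expression sample ids to exposure sample ids when the
    two tables use different barcodes for the same donor. Returns the
    aligned pair plus the ids dropped from either side.
    """
    id_map = id_map or {}
    expr_to_donor = {c: id_map.get(c, c) for c in expression.columns}
    exposure_ids = set(exposures.index)
    shared = sorted(
        {d for d in expr_to_donor.values() if d in exposure_ids}
    )
    if not shared:
        raise ValueError("no donor has both exposures and expression")
    donor_to_expr: dict[str, str] = {}
    for expr_id, donor in expr_to_donor.items():
        donor_to_expr.setdefault(donor, expr_id)
    expr_cols = [donor_to_expr[d] for d in shared]
    dropped = sorted(
        (set(exposures.index) - set(shared))
        | {c for c in expression.columns if expr_to_donor[c] not in shared}
    )
    aligned_exposures = exposures.loc[shared]
    aligned_expression = expression[expr_cols]
    aligned_expression.columns = shared
    return aligned_exposures, aligned_expression, dropped
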