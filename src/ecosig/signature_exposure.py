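"""Refitting SBS96 mutation catalogs against reference signatures.

Each sample's L1-normalized mutation spectrum ``m`` is decomposed over a
fixed column-stochastic signature matrix ``P`` by constrained least squares

    minimize || m - P f ||_2^2   subject to  f >= 0,  sum(f) = 1,

the quadratic-programming refitting formulation used for COSMIC signature
exposure estimation. Exposures are the optimal fractions scaled back to the
sample's mutation total. Rare signatures are then pruned with the
cohort-level activity rule (present in at least ``min_sample_frac`` of
samples and responsible for at least ``min_mutation_frac`` of all
mutations) and the catalog is refit on the active subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls


def _check_alignment(catalog: pd.DataFrame, signatures: pd.DataFrame) -> None:
    cat_labels = list(catalog.index)
    sig_labels = list(signatures.index)
    if len(cat_labels) != len(sig_labels):
        raise ValueError(
            f"catalog has {len(cat_labels)} categories, "
            f"signatures have {len(sig_labels)}"
        )
    for got, want in zip(cat_labels, sig_labels):
        if got != want:
            raise ValueError(
                f"category mismatch between catalog and signatures: "
                f"{got!r} vs {want!r}"
            )
    if (catalog.to_numpy() < 0).any():
        raise ValueError("catalog contains negative counts")


def _solve_simplex_lsq(P: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimize ||m - P f||^2 over the probability simplex.

    Active-set strategy: a heavily weighted NNLS row enforces the sum
    constraint and identifies the support (exact zeros), then the
    equality-constrained least squares on that support is solved through
    its KKT system, giving the optimum to machine precision.
    """
    S = P.shape[1]

    def obj(f: np.ndarray) -> float:
        r = P @ f - m
        return float(r @ r)

    if S == 1:
        return np.ones(1), obj(np.ones(1))
    lam = 1e4
    aug_A = np.vstack([P, lam * np.ones((1, S))])
    aug_b = np.concatenate([m, [lam]])
    f0, _ = _nnls(aug_A, aug_b)
    support = f0 > 1e-12
    if support.sum() == 0:
        support[:] = True
    PA = P[:, support]
    k = int(support.sum())
    # KKT system of min ||m - PA fA||^2 s.t. sum(fA) = 1
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * PA.T @ PA
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * PA.T @ m, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
        fA = sol[:k]
    except np.linalg.LinAlgError:
        fA = f0[support] / f0[support].sum()
    f = np.zeros(S)
    if (fA >= -1e-12).all():
        f[support] = np.clip(fA, 0.0, None)
    else:  # polish left the feasible set; keep the NNLS point
        f[support] = f0[support]
    f /= f.sum()
    return f, obj(f)


@dataclass
class ExposureResult:
    """Refit exposures plus per-sample QP diagnostics.

    ``exposures`` holds attributed mutation counts (samples x signatures);
    ``objective`` is the per-sample optimal value of the simplex least
    squares (0 for zero-mutation samples).
    """

    exposures: pd.DataFrame
    objective: pd.Series

    @property
    def fractions(self) -> pd.DataFrame:
        """Row-normalized exposures; zero-mutation rows stay all-zero."""
        totals = self.exposures.sum(axis=1)
        safe = totals.replace(0.0, 1.0)
        return self.exposures.div(safe, axis=0)


def estimate_exposures(
    catalog: pd.DataFrame, signatures: pd.DataFrame
) -> ExposureResult:
    """Per-sample simplex-constrained least-squares exposure estimates.

    Parameters
    ----------
    catalog
        96 x N nonnegative counts, index = SBS category labels.
    signatures
        96 x S column-stochastic reference, same category order.
    """
    _check_alignment(catalog, signatures)
    P = signatures.to_numpy(dtype=float)
    exposures = np.zeros((catalog.shape[1], P.shape[1]))
    objective = np.zeros(catalog.shape[1])
    for j, sample in enumerate(catalog.columns):
        m = catalog[sample].to_numpy(dtype=float)
        total = m.sum()
        if total == 0:
            continue
        f, obj = _solve_simplex_lsq(P, m / total)
        exposures[j] = f * total
        objective[j] = obj
    return ExposureResult(
        exposures=pd.DataFrame(
            exposures, index=list(catalog.columns), columns=list(signatures.columns)
        ),
        objective=pd.Series(objective, index=list(catalog.columns), name="objective"),
    )


def select_active_signatures(
    exposures: pd.DataFrame,
    min_sample_frac: float = 0.05,
    min_mutation_frac: float = 0.01,
    presence_frac: float = 0.01,
    blocklist: list[str] | None = None,
) -> list[str]:
    """Cohort-level activity filter for refit signatures.

    A signature is kept iff it is *present* (per-sample fraction above
    ``presence_frac``) in at least ``min_sample_frac`` of samples AND it
    accounts for at least ``min_mutation_frac`` of all attributed mutations.
    ``blocklist`` removes known-artifact signatures (e.g. the 8-oxo-guanine
    sequencing artifact SBS45) regardless of activity.
    """
    totals = exposures.sum(axis=1)
    safe = totals.replace(0.0, 1.0)
    fractions = exposures.div(safe, axis=0)
    n = exposures.shape[0]
    grand_total = float(exposures.to_numpy().sum())
    if grand_total == 0:
        raise ValueError("all exposures are zero")
    block = set(blocklist or [])
    active = []
    for sig in exposures.columns:
        if sig in block:
            continue
        sample_frac = float((fractions[sig] > presence_frac).sum()) / n
        mutation_frac = float(exposures[sig].sum()) / grand_total
        if sample_frac >= min_sample_frac and mutation_frac >= min_mutation_frac:
            active.append(sig)
    if not active:
        raise ValueError(
            "no signature passed the activity filter; relax min_sample_frac "
            "or min_mutation_frac"
        )
    return active


def refit_active(
    catalog: pd.DataFrame,
    signatures: pd.DataFrame,
    active_ids: list[str],
) -> ExposureResult:
    """Re-estimate exposures restricted to the active signature subset."""
    if not active_ids:
        raise ValueError("active_ids is empty")
    unknown = [s for s in active_ids if s not in signatures.columns]
    if unknown:
        raise KeyError(f"unknown signature ids: {unknown}")
    return estimate_exposures(catalog, signatures[active_ids])


def reconstruction_error(
    catalog: pd.DataFrame,
    signatures: pd.DataFrame,
    exposures: pd.DataFrame,
) -> pd.Series:
    """Per-sample L2 error between normalized spectrum and reconstruction.

    Zero-mutation samples get error 0 by convention.
    """
    _check_alignment(catalog, signatures)
    if list(exposures.columns) != list(signatures.columns):
        raise ValueError("exposure signature ids do not match signature matrix")
    P = signatures.to_numpy(dtype=float)
    errors = np.zeros(catalog.shape[1])
    for j, sample in enumerate(catalog.columns):
        m = catalog[sample].to_numpy(dtype=float)
        total = m.sum()
        if total == 0:
            continue
        e = exposures.loc[sample].to_numpy(dtype=float)
        f = e / e.sum() if e.sum() > 0 else np.zeros_like(e)
        errors[j] = float(np.linalg.norm(m / total - P @ f))
    return pd.Series(errors, index=list(catalog.columns), name="reconstruction_error")
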