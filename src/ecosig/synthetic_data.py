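"""Synthetic cohorts with planted signature/expression/cell-composition structure.

Every downstream stage of the pipeline (QP refitting, ECoSigClust,
deconvolution) is validated against data whose generating truth is known.
This module produces:

* a column-stochastic reference signature matrix over the 96 SBS categories,
* per-sample exposures (Dirichlet fractions scaled to a mutation burden),
* multinomial SBS96 catalogs consistent with those exposures,
* a gene expression count matrix in which gene *clusters* are linked to
  signature exposures through a rank-based latent model, and
* cell-type reference profiles plus bulk mixtures whose true fractions are
  tied to exposures through a softmax link.

All generators are deterministic given ``SimConfig.seed``; each stage draws
from its own child stream so adding a stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .sbs import sbs96_categories

_STAGE_SIGNATURES = 1
_STAGE_EXPOSURES = 2
_STAGE_CATALOG = 3
_STAGE_EXPRESSION = 4
_STAGE_CELLS = 5

#: default airway-flavored cell panel: 3 epithelial + 3 immune types
DEFAULT_CELL_TYPES = ("basal", "ciliated", "goblet", "t_cell", "b_cell", "macrophage")
DEFAULT_LINEAGE = {
    "basal": "epithelial",
    "ciliated": "epithelial",
    "goblet": "epithelial",
    "t_cell": "immune",
    "b_cell": "immune",
    "macrophage": "immune",
}


def default_effect_matrix(n_clusters: int, n_signatures: int) -> np.ndarray:
    """Distinct sign patterns linking each gene cluster to signatures.

    Cluster ``c`` gets weight +1 on signature ``c mod S`` and -1 on
    ``(c+1) mod S``, yielding well-separated correlation centroids for any
    ``n_clusters <= n_signatures``.
    """
    eff = np.zeros((n_clusters, n_signatures))
    for c in range(n_clusters):
        eff[c, c % n_signatures] = 1.0
        if n_signatures > 1:
            eff[c, (c + 1) % n_signatures] = -1.0
    return eff


def default_fraction_link(
    cell_types: tuple[str, ...], n_signatures: int
) -> np.ndarray:
    """Positive link of the goblet-like type (index 2) to the SBS4-like
    signature (index 2, the smoking slot in the default panel)."""
    link = np.zeros((len(cell_types), n_signatures))
    t = min(2, len(cell_types) - 1)
    s = min(2, n_signatures - 1)
    link[t, s] = 1.0
    return link


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the shape of the motivating lung-cohort analysis at
    desk scale: 60 donors, six active signatures, four planted expression
    clusters of 75 genes each, 10,000 mutations per sample, and a six-type
    epithelial/immune cell panel.
    """

    n_samples: int = 60
    n_genes: int = 360
    n_signatures: int = 6
    n_clusters: int = 4
    genes_per_cluster: int = 75
    mutations_per_sample: int | np.ndarray = 10_000
    effect_matrix: np.ndarray | None = None
    noise_sd: float = 0.1
    dirichlet_concentration: float = 1.0
    mean_count: float = 1000.0
    n_cell_types: int = 6
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    lineage_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINEAGE))
    fraction_link: np.ndarray | None = None
    fraction_noise_sd: float = 0.1
    markers_per_type: int = 25
    n_background_genes: int = 100
    marker_fold: float = 50.0
    bulk_library_size: float = 1_000_000.0
    bulk_poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if self.n_signatures < 2:
            raise ValueError("need at least 2 signatures")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters cannot exceed n_genes")
        if self.n_clusters * self.genes_per_cluster > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.effect_matrix is None:
            self.effect_matrix = default_effect_matrix(
                self.n_clusters, self.n_signatures
            )
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.effect_matrix.shape != (self.n_clusters, self.n_signatures):
            raise ValueError("effect_matrix must be n_clusters x n_signatures")
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if len(self.cell_types) != self.n_cell_types:
            self.cell_types = tuple(f"cell_type_{t}" for t in range(self.n_cell_types))
            self.lineage_map = {
                t: ("epithelial" if i < (self.n_cell_types + 1) // 2 else "immune")
                for i, t in enumerate(self.cell_types)
            }
        missing = [t for t in self.cell_types if t not in self.lineage_map]
        if missing:
            raise ValueError(f"lineage_map missing cell types: {missing}")
        if self.fraction_link is None:
            self.fraction_link = default_fraction_link(
                self.cell_types, self.n_signatures
            )
        self.fraction_link = np.asarray(self.fraction_link, dtype=float)
        if self.fraction_link.shape != (self.n_cell_types, self.n_signatures):
            raise ValueError("fraction_link must be n_cell_types x n_signatures")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic child stream for one generator stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stage])

    @property
    def sample_ids(self) -> list[str]:
        return [f"sample_{i:03d}" for i in range(self.n_samples)]

    @property
    def signature_ids(self) -> list[str]:
        return [f"SBS_sim{s + 1}" for s in range(self.n_signatures)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene_{g:05d}" for g in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted truth for recovery tests.

    ``cluster_of_gene`` maps every expression gene to cluster ids 1..k, with
    0 marking null (unplanted) genes.
    """

    true_exposures: pd.DataFrame
    true_cluster_of_gene: pd.Series
    true_fractions: pd.DataFrame


def make_signature_matrix(
    n_categories: int,
    n_signatures: int,
    concentration: float = 0.5,
    seed: int = 0,
    max_cosine: float = 0.95,
    max_retries: int = 200,
) -> pd.DataFrame:
    """Random column-stochastic reference signatures over SBS96 categories.

    Columns are Dirichlet draws; any column whose cosine similarity to an
    earlier column reaches ``max_cosine`` is redrawn, so the basis is
    identifiable for refitting.
    """
    if n_categories != 96:
        raise ValueError("SBS signatures are defined over 96 categories")
    if n_signatures < 1:
        raise ValueError("need at least 1 signature")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng([int(seed) % (2**31), _STAGE_SIGNATURES])
    cols: list[np.ndarray] = []
    for _ in range(n_signatures):
        for _attempt in range(max_retries):
            cand = rng.dirichlet(np.full(n_categories, concentration))
            ok = all(
                float(cand @ c) / (np.linalg.norm(cand) * np.linalg.norm(c))
                < max_cosine
                for c in cols
            )
            if ok:
                cols.append(cand)
                break
        else:
            raise RuntimeError(
                "could not draw a sufficiently dissimilar signature column"
            )
    probs = np.column_stack(cols)
    return pd.DataFrame(
        probs,
        index=sbs96_categories(),
        columns=[f"SBS_sim{s + 1}" for s in range(n_signatures)],
    )


def simulate_exposures(config: SimConfig) -> pd.DataFrame:
    """Per-sample exposures: Dirichlet fractions x mutation burden.

    Row sums equal ``mutations_per_sample`` exactly (exposures are real
    valued; the catalog simulator rounds totals).
    """
    rng = config.rng(_STAGE_EXPOSURES)
    alpha = np.full(config.n_signatures, config.dirichlet_concentration)
    fractions = rng.dirichlet(alpha, size=config.n_samples)
    totals = np.broadcast_to(
        np.asarray(config.mutations_per_sample, dtype=float), (config.n_samples,)
    )
    exposures = fractions * totals[:, None]
    return pd.DataFrame(
        exposures, index=config.sample_ids, columns=config.signature_ids
    )


def simulate_catalog(
    exposures: pd.DataFrame, signatures: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Multinomial SBS96 catalog consistent with given exposures.

    Each sample's total is the (rounded) exposure row sum; category
    probabilities are the exposure-fraction mixture of signature columns.
    Catalog column sums therefore equal the rounded exposure row sums.
    """
    if list(exposures.columns) != list(signatures.columns):
        raise ValueError(
            "signature ids of exposures and signature matrix do not match"
        )
    rng = np.random.default_rng([int(seed) % (2**31), _STAGE_CATALOG])
    P = signatures.to_numpy()
    counts = np.zeros((P.shape[0], exposures.shape[0]), dtype=np.int64)
    for j, (_, row) in enumerate(exposures.iterrows()):
        total = int(round(float(row.sum())))
        if total == 0:
            continue
        frac = row.to_numpy() / row.sum()
        probs = P @ frac
        probs = probs / probs.sum()
        counts[:, j] = rng.multinomial(total, probs)
    return pd.DataFrame(
        counts, index=signatures.index, columns=list(exposures.index)
    )


def _rank_standardize(x: np.ndarray) -> np.ndarray:
    """Map values to normal scores via average ranks (Blom-style).

    Monotone in ``x``, so planted links survive any monotone downstream
    normalization.
    """
    r = rankdata(x, method="average")
    return norm.ppf(r / (len(x) + 1.0))


def simulate_expression(
    exposures: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression counts with exposure-linked gene clusters.

    A gene in cluster ``c`` has latent log-expression
    ``sum_s effect[c, s] * z(exposure_s) + N(0, noise_sd)`` where ``z`` is the
    per-signature rank standardization; counts are
    ``round(mean_count * exp(latent))`` (a single global scale, so the
    planted monotone links are preserved exactly at ``noise_sd = 0``).
    Returns the count matrix (genes x samples) and the gene -> cluster map
    (1..k; 0 for null genes).
    """
    rng = config.rng(_STAGE_EXPRESSION)
    z = np.column_stack(
        [_rank_standardize(exposures[c].to_numpy()) for c in exposures.columns]
    )  # samples x signatures
    n_planted = config.n_clusters * config.genes_per_cluster
    cluster_of_gene = np.zeros(config.n_genes, dtype=int)
    latent = np.zeros((config.n_genes, config.n_samples))
    for c in range(config.n_clusters):
        lo = c * config.genes_per_cluster
        hi = lo + config.genes_per_cluster
        cluster_of_gene[lo:hi] = c + 1
        latent[lo:hi, :] = (config.effect_matrix[c] @ z.T)[None, :]
    if config.noise_sd > 0:
        latent += rng.normal(0.0, config.noise_sd, size=latent.shape)
    counts = np.rint(config.mean_count * np.exp(latent)).astype(np.int64)
    expr = pd.DataFrame(
        counts, index=config.gene_ids, columns=list(exposures.index)
    )
    truth = pd.Series(cluster_of_gene, index=config.gene_ids, name="cluster")
    assert (truth > 0).sum() == n_planted
    return expr, truth


def simulate_cell_mixtures(
    exposures: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell-type reference profiles, bulk mixtures, and true fractions.

    Reference profiles get ``markers_per_type`` marker genes each (boosted
    ``marker_fold``-fold in their own type) on top of a shared baseline.
    True fractions are ``softmax(fraction_link @ z(exposures) + noise)`` per
    sample; bulk counts are the reference-weighted mixture scaled to
    ``bulk_library_size``, with optional Poisson sampling.
    """
    if config.markers_per_type < 20:
        raise ValueError("need at least 20 marker genes per cell type")
    rng = config.rng(_STAGE_CELLS)
    T = config.n_cell_types
    n_ref_genes = T * config.markers_per_type + config.n_background_genes
    gene_ids = [f"ref_gene_{g:05d}" for g in range(n_ref_genes)]

    baseline = rng.gamma(shape=2.0, scale=5.0, size=n_ref_genes) + 0.5
    jitter = rng.lognormal(mean=0.0, sigma=0.2, size=(n_ref_genes, T))
    profiles = baseline[:, None] * jitter
    for t in range(T):
        lo = t * config.markers_per_type
        hi = lo + config.markers_per_type
        profiles[lo:hi, t] *= config.marker_fold
    # equalize per-type totals so mixing fractions are the same quantity the
    # CPM-space deconvolution estimates (equal mRNA yield per unit fraction)
    profiles *= 10_000.0 / profiles.sum(axis=0)

    z = np.column_stack(
        [_rank_standardize(exposures[c].to_numpy()) for c in exposures.columns]
    )
    logits = z @ config.fraction_link.T  # samples x cell types
    if config.fraction_noise_sd > 0:
        logits = logits + rng.normal(
            0.0, config.fraction_noise_sd, size=logits.shape
        )
    logits -= logits.max(axis=1, keepdims=True)
    fractions = np.exp(logits)
    fractions /= fractions.sum(axis=1, keepdims=True)

    bulk_expected = profiles @ fractions.T  # genes x samples
    bulk_expected *= config.bulk_library_size / bulk_expected.sum(axis=0)
    if config.bulk_poisson:
        bulk = rng.poisson(bulk_expected).astype(np.int64)
    else:
        bulk = bulk_expected

    ref_df = pd.DataFrame(profiles, index=gene_ids, columns=list(config.cell_types))
    bulk_df = pd.DataFrame(bulk, index=gene_ids, columns=list(exposures.index))
    frac_df = pd.DataFrame(
        fractions, index=list(exposures.index), columns=list(config.cell_types)
    )
    return ref_df, bulk_df, frac_df


@dataclass
class SimData:
    """One fully simulated cohort plus its ground truth."""

    config: SimConfig
    signatures: pd.DataFrame
    catalog: pd.DataFrame
    expression: pd.DataFrame
    cell_reference: pd.DataFrame
    bulk: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(config: SimConfig) -> SimData:
    """Run all generators with child seeds derived from ``config.seed``."""
    signatures = make_signature_matrix(
        96, config.n_signatures, concentration=0.5, seed=config.seed
    )
    exposures = simulate_exposures(config)
    catalog = simulate_catalog(exposures, signatures, seed=config.seed)
    expression, cluster_of_gene = simulate_expression(exposures, config)
    reference, bulk, fractions = simulate_cell_mixtures(exposures, config)
    truth = GroundTruth(
        true_exposures=exposures,
        true_cluster_of_gene=cluster_of_gene,
        true_fractions=fractions,
    )
    return SimData(
        config=config,
        signatures=signatures,
        catalog=catalog,
        expression=expression,
        cell_reference=reference,
        bulk=bulk,
        truth=truth,
    )
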