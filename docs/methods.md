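# Methods

This note documents the statistical procedures, the synthetic-data model
used to validate them, the numerical choices, and the limitations. It is
written for a reader who wants to know exactly what the package computes
and what the passing tests do and do not demonstrate.

## 1. Exposure refitting

Each sample's SBS96 spectrum is refit against a fixed column-stochastic
signature matrix by simplex-constrained least squares on the L1-normalized
spectrum: minimize `||m − P f||²` subject to `f ≥ 0`, `Σ f = 1`. Exposures
are `f` scaled by the sample's total mutation count; samples with zero
mutations get all-zero exposures and, by convention, zero objective and
reconstruction error.

**Solver.** The problem is a small convex QP (S ≤ ~80 in practice, 96
residuals). It is solved by an active-set strategy: a non-negative least
squares solve on the system augmented with a heavily weighted sum row
(weight 1e4) identifies the support with exact zeros; the
equality-constrained least squares on that support is then solved through
its KKT system. This yields the optimum to machine precision — the unit
tests require the objective to match a brute-force 1e-3 simplex grid
search within the grid's quadratic resolution bound
`λ_max(PᵀP)·S·(1e-3)²`, and signatures outside the true support come back
exactly zero. Only the optimum is contractual; the solver is replaceable.

**Activity filter.** A signature is kept when (a) its per-sample exposure
fraction exceeds `presence_frac` (default 0.01) in at least
`min_sample_frac` (default 0.05) of samples, and (b) it carries at least
`min_mutation_frac` (default 0.01) of all attributed mutations. "Present
in a sample" needs an explicit numeric definition because QP solutions
carry numerical dust; a strict nonzero test would be meaningless. The 1%
presence cutoff is the package's choice. Artifact signatures (e.g. SBS45,
attributed to 8-oxo-guanine damage introduced during sequencing) are
handled by a caller-supplied blocklist rather than hard-coded names.
Whether the filter runs on an initial full refit or on externally supplied
exposures is the caller's choice: `select_active_signatures` accepts any
exposure table.

## 2. Expression preparation

Counts are normalized with median-of-ratios size factors (the reference
genes are those with nonzero counts in every sample) followed by
`log2(count/sf + 1)`. A dispersion-fitted variance-stabilizing transform
is deliberately not used: every downstream statistic is Spearman
correlation across samples, which depends only on within-gene ranks, so a
monotone per-sample transform is sufficient; the transform is exposed as a
separate function and can be swapped. Donor harmonization restricts
exposures and expression to their common donors (optionally through a
barcode→donor map) in a shared sorted order and reports dropped ids.

## 3. ECoSigClust

**Correlation screen.** Spearman rho with average-rank ties; two-sided p
from `t = ρ√((n−2)/(1−ρ²))` with n−2 df, used at all n (an exact
permutation p is available behind a flag for n < 10). Constant genes are
flagged with ρ = NaN, p = 1. Genes with nominal p < alpha (default 0.05)
for at least one signature are selected; no multiple-testing correction is
applied at this screening stage, intentionally — the screen feeds a
clustering step, not an inference.

Correlations are computed against exposure *counts* by default; with
equal per-sample totals this is identical to using fractions (Spearman is
rank-based), and a caller can pass fractions instead.

**Consensus clustering.** Features are the per-gene rho vectors — not
p-values, not ranks — because the clustering targets correlation
*patterns*. For each candidate k, k-means (Euclidean, Lloyd, random
data-point initialization — run r seeded `seed + r`) is run `n_runs`
(default 100) times; the consensus matrix holds pairwise co-clustering
frequencies; average-linkage hierarchical clustering of `1 − M` cut at k
gives the partition. The consensus matrix is built per k, the standard
construction, which also lets each k be scored. Cluster labels are
renumbered by first appearance, making the cut deterministic given M.

**Choosing k.** Silhouette, Calinski–Harabasz and Davies–Bouldin are
computed on the rho feature space for every candidate k (defaults 5–50;
the recovery tests use 2–10 around a planted k = 4). The default choice
maximizes silhouette — a single reproducible rule — while all three
indices are reported and a `k_override` is honored, because in real
analyses the final k is often a judgment call balancing the indices
against interpretability. Undefined indices (e.g. all-singleton
partitions) are reported as NaN rather than guessed.

**Covariate association.** Exposure vs. continuous/ordinal covariates
(age, tumor grade) uses Spearman; vs. binary covariates (smoking status)
the two-sided Wilcoxon rank-sum with tie-corrected normal approximation.
Missing covariate values are dropped pairwise; constant covariates are
flagged (statistic NaN, p = 1).

## 4. Enrichment

Per cluster, terms are tested by the upper-tail hypergeometric
`P(X ≥ overlap)` with the **clustered genes as the background** — the
relevant null is "is this term concentrated in this cluster relative to
the other clusters", not relative to the genome. Terms are intersected
with the background first; q-values are Benjamini–Hochberg within each
cluster (the multiple-testing procedure is the package's choice; raw p is
always reported). Gene sets come from a caller-supplied GMT file — no
ontology is bundled, no DAG propagation is performed.

## 5. Deconvolution

Bulk counts and reference profiles are CPM-normalized; genes with no
sample exceeding CPM 1 are dropped. Markers are the top `m` (default 50)
genes per cell type by `log2((type+1)/(mean of others+1))` fold change,
ties broken by gene id. Per sample, NNLS of the bulk marker vector on the
reference marker columns gives weights renormalized to sum 1; the NNLS
residual is reported per sample, all-zero-weight samples are flagged, and
a rank-deficient marker reference raises an error naming collinear type
pairs. Estimation is invariant to global scaling of a bulk profile.
Lineage subsets (epithelial / immune) renormalize the restricted fraction
block onto the simplex; their Spearman correlation with exposures is the
stage's readout.

This NNLS estimator deliberately occupies the analysis slot that hosted
nu-SVR deconvolution services fill. The downstream contract — simplex
fractions fed to rank correlations — is identical, and every step is
open and testable. No batch correction between bulk and reference is
attempted.

## 6. Synthetic-data model

The generator produces a full cohort with known truth; all stages share a
single integer seed with fixed per-stage child streams, so outputs are
bit-reproducible and adding a stage never perturbs another.

- **Signatures**: Dirichlet(0.5) columns over the 96 categories; columns
  with pairwise cosine similarity ≥ 0.95 are redrawn (bounded retries) so
  the refitting basis is identifiable.
- **Exposures**: symmetric Dirichlet(1) fractions per sample scaled to
  `mutations_per_sample` (default 10,000 — an exome-scale burden for a
  heavily mutagenized cohort at desk scale). Row sums are exact.
- **Catalogs**: multinomial draws with category probabilities
  `P · f`; column sums equal (rounded) exposure row sums by construction.
- **Expression**: a gene in cluster c has latent log-expression
  `Σ_s E[c,s]·z_s + N(0, noise_sd)` where `z_s` is the rank-based normal
  score of exposure s; counts are `round(1000·exp(latent))`. The rank
  standardization makes planted links invariant to any monotone
  normalization downstream, and the single global count scale (rather
  than per-sample library scaling) keeps the planted monotone links exact
  at `noise_sd = 0`. Default: 4 clusters × 75 genes, effects ±1 in
  distinct sign patterns, `noise_sd = 0.1`, 60 samples, 6 signatures.
- **Cell mixtures**: 6 default airway-flavored types (3 epithelial,
  3 immune), 25 planted markers per type boosted 50-fold over a shared
  gamma baseline, plus 100 background genes. Profiles are normalized to a
  common per-type total so a mixing fraction contributes equal mRNA —
  this makes the generator's fractions the same quantity the CPM-space
  deconvolution estimates. True fractions are
  `softmax(fraction_link·z(exposures) + N(0, 0.1))`; the default link ties
  the goblet-like type positively to the smoking-like signature slot.
  Bulk is the profile-weighted mixture scaled to a 10⁶ library with
  optional Poisson sampling.

**What the generator does not emulate**: realistic trinucleotide genome
composition, signature-specific flat-vs-spiky profiles, overdispersed
(non-multinomial) mutation counts, gene–gene co-expression beyond the
planted clusters, compositional mRNA differences between cell types,
tumor purity, and batch structure. Passing recovery tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance on TCGA-scale real data.

## 7. Calibration notes

With S compositional exposure columns (Dirichlet fractions share a fixed
total), per-gene screening tests across signatures are weakly negatively
rank-correlated (≈ −1/(S−1) pairwise). For two-sided tests this dependence
*raises* the probability that all S tests accept, so the null selection
rate sits slightly below the independence reference `1 − 0.95^S` — about
1 percentage point at S = 6, n = 60. The calibration test asserts the
independence value within two binomial standard errors at the generator's
default seed; the small conservative bias is expected and harmless (the
screen admits slightly fewer null genes than the nominal rate).

The hypergeometric test is discrete and therefore conservative at small
counts; the calibration test uses large counts (background 1000, term 150,
cluster 200) where the attained level approaches the nominal one from
below.

## 8. Problem sizes

Recovery analyses run at: 20–60 samples; 300 genes (4 planted clusters of
75) for cluster recovery and 5,000 genes for null calibration; 10,000
mutations per sample; 6 cell types with 50 bulk samples; candidate k 2–10
with 100 consensus runs per k. These sizes give high-signal recovery
targets (ARI ≥ 0.9, RMSE < 0.05, fraction error < 0.02) while keeping the
full suite and the acceptance script fast on a single CPU.

## 9. Known limitations

- The QP refit assumes the reference basis is correct and complete;
  misspecified references bias exposures (no de novo extraction is
  provided).
- The Spearman t-approximation is slightly anti-conservative at very
  small n; the exact permutation option exists for n < 10.
- Consensus k-means with Forgy initialization can under-split at large k
  when clusters are highly unbalanced; the consensus matrix mitigates but
  does not eliminate this.
- NNLS deconvolution has no error model for reference misspecification;
  residuals are reported but not calibrated.
- The pipeline is single-threaded by design; all stages are fast at the
  supported problem sizes.
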