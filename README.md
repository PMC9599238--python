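# ecosig

Joint analysis of tumor-derived **mutational-signature exposures** and
**gene expression**, with downstream **cell-type composition** analysis —
built as a reusable, fully tested pipeline.

Mutagenic processes (tobacco smoke, APOBEC activity, clock-like aging
processes) each leave a characteristic multinomial footprint over the 96
trinucleotide-context single-base-substitution categories (SBS96). Given a
cohort's SBS96 mutation catalogs, a reference signature matrix, and matched
expression data, this package answers three questions:

1. **How much of each sample's mutation burden does each signature
   explain?** Per-sample quadratic-programming refitting, plus a
   cohort-level activity filter for rare signatures.
2. **Which gene-expression programs track signature exposure?**
   ECoSigClust: Spearman screening of every gene against every signature,
   then consensus k-means clustering of the per-gene correlation profiles,
   with internal validation indices to choose the cluster count, and
   hypergeometric gene-set enrichment per cluster.
3. **Does cellular composition shift with exposure?** Reference-based
   NNLS deconvolution of bulk samples into cell-type fractions, and
   Spearman correlation of epithelial / immune lineage fractions with
   exposures.

## The core models

**Refitting.** For a sample's L1-normalized spectrum `m` (96-vector) and a
column-stochastic reference `P` (96 × S), exposures solve

```
min_f || m − P f ||²   s.t.  f ≥ 0,  Σ_s f_s = 1
```

and are reported as `f × (total mutations)`. A signature is *active* in the
cohort if it is present (fraction > 1%) in ≥ 5% of samples and carries
≥ 1% of all attributed mutations; the catalog is then refit on the active
subset. Known-artifact signatures (e.g. SBS45, an 8-oxo-guanine sequencing
artifact) can be excluded via a blocklist.

**ECoSigClust.** Each gene g gets a profile `ρ_g = (ρ_g1 … ρ_gS)` of
Spearman correlations with the S signature exposures; genes with nominal
p < 0.05 for at least one signature are kept. K-means is run 100 times from
random starts for each candidate k; the consensus matrix `M_ij` (fraction
of runs where genes i, j co-cluster) is cut by average-linkage hierarchical
clustering at distance `1 − M`. Silhouette, Calinski–Harabasz and
Davies–Bouldin indices are reported for every k; the default choice
maximizes silhouette, with an explicit override for
interpretability-driven choices.

**Deconvolution.** Bulk and single-cell-derived reference profiles are
CPM-normalized (genes with no CPM > 1 dropped); per cell type the top
fold-change marker genes are selected; per sample, non-negative least
squares on the marker space yields weights renormalized onto the simplex.

A synthetic-data module generates catalogs, exposures, expression and cell
mixtures with *planted* structure (known exposures, known gene clusters,
known fractions) so every stage has a recovery test.

## Worked example

```python
from ecosig import SimConfig, simulate_dataset, estimate_exposures
from ecosig.ecosigclust import (
    correlate_expression_signatures, select_significant_genes, choose_k,
)

config = SimConfig(n_samples=60, n_genes=300, n_clusters=4,
                   genes_per_cluster=75, noise_sd=0.1, seed=11)
data = simulate_dataset(config)

refit = estimate_exposures(data.catalog, data.signatures)
profile = correlate_expression_signatures(data.expression, refit.exposures)
genes = select_significant_genes(profile, alpha=0.05)
result = choose_k(profile.rho.loc[genes], k_range=range(2, 11),
                  n_runs=100, seed=11)
print("selected genes:", len(genes))
print("silhouette-optimal k:", result.k)
print(result.cluster_mean_rho.round(2))
```

Output:

```
selected genes: 300
silhouette-optimal k: 4
         SBS_sim1  SBS_sim2  SBS_sim3  SBS_sim4  SBS_sim5  SBS_sim6
cluster
1            0.82     -0.80     -0.04     -0.13      0.04      0.04
2           -0.09      0.73     -0.72      0.12     -0.19      0.14
3           -0.02     -0.01      0.80     -0.77      0.28     -0.23
4           -0.03      0.04     -0.25      0.81     -0.80      0.14
```

All 300 planted genes pass the screen, the silhouette-optimal k equals the
planted cluster count, and each cluster's mean correlation row recovers
its planted ±1 effect pattern (cluster c: positive on signature c,
negative on signature c+1), attenuated by expression noise and refitting
error. The mean absolute error of the refit exposure fractions against the
planted truth in this run is 0.0064.

## Command line

```bash
ecosig simulate   --outdir fixture --seed 4            # synthetic cohort
ecosig refit      --catalog fixture/catalog.tsv --signatures fixture/signatures.tsv --outdir out
ecosig cluster    --exposures out/exposures_active.tsv --expression fixture/expression.tsv --outdir out
ecosig enrich     --assignment out/cluster_assignment.tsv --genesets sets.gmt --out out/enrichment.tsv
ecosig deconvolve --bulk fixture/bulk.tsv --reference fixture/reference.tsv --out out/fractions.tsv
ecosig run-all    --config pipeline.yaml               # everything, with a manifest
```

`run-all` writes a `manifest.json` with SHA-256 checksums of every stage
output; re-running the same config reproduces the checksums bit for bit.

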