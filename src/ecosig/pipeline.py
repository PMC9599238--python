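"""End-to-end orchestration: refit -> cluster -> enrich -> deconvolve.

``run_pipeline`` executes the full analysis behind one YAML-configurable
``PipelineConfig``, writing every stage output as TSV/JSON plus a manifest
with SHA-256 checksums and the parameters used, so any stage can be
re-checked for bit-identical reproduction.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io
from .deconvolution import (
    cpm,
    cpm_filter,
    correlate_fractions_signatures,
    estimate_fractions,
    subset_fractions,
)
from .ecosigclust import (
    choose_k,
    correlate_expression_signatures,
    select_significant_genes,
)
from .enrichment import enrich_clusters, read_gmt
from .expression_prep import harmonize_donors, normalize_log, size_factors
from .signature_exposure import (
    estimate_exposures,
    refit_active,
    select_active_signatures,
)
from .synthetic_data import SimConfig, simulate_dataset

logger = logging.getLogger("ecosig")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the analysis defaults: nominal alpha 0.05 for the
    gene screen, 5%-of-samples / 1%-of-mutations signature activity filter,
    CPM > 1 gene filter, candidate k from 5 to 50 with 100 k-means runs.
    """

    catalog: str = ""
    signatures: str = ""
    expression: str = ""
    bulk: str = ""          # raw counts for deconvolution; defaults to `expression`
    reference: str = ""
    lineage: str = ""
    genesets: str = ""      # optional GMT; enrichment skipped when empty
    alpha: float = 0.05
    min_sample_frac: float = 0.05
    min_mutation_frac: float = 0.01
    presence_frac: float = 0.01
    signature_blocklist: list[str] = field(default_factory=list)
    min_cpm: float = 1.0
    k_min: int = 5
    k_max: int = 50
    k_override: int | None = None
    n_runs: int = 100
    n_markers: int = 50
    seed: int = 0
    outdir: str = "ecosig_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = io.read_yaml(path) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest.

    Stage order: exposure refit, activity filter, active-subset refit,
    expression normalization, donor harmonization, gene-signature
    correlation, significance screen, consensus clustering with k
    selection, cluster mean correlations, optional gene-set enrichment,
    CPM filtering, NNLS deconvolution, and lineage-subset
    fraction-signature correlations.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, writer, obj) -> None:
        path = outdir / name
        writer(obj, path)
        outputs[name] = path

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("refit")
        catalog = io.read_catalog(config.catalog)
        signatures = io.read_catalog(config.signatures)
        initial = estimate_exposures(catalog, signatures)
        emit("exposures_initial.tsv", io.write_exposures, initial.exposures)

        stage("select_active")
        active = select_active_signatures(
            initial.exposures,
            min_sample_frac=config.min_sample_frac,
            min_mutation_frac=config.min_mutation_frac,
            presence_frac=config.presence_frac,
            blocklist=config.signature_blocklist,
        )

        stage("refit_active")
        refit = refit_active(catalog, signatures, active)
        exposures = refit.exposures
        emit("exposures_active.tsv", io.write_exposures, exposures)

        stage("normalize_expression")
        counts = io.read_matrix(config.expression)
        factors = size_factors(counts)
        normalized = normalize_log(counts, factors)

        stage("harmonize_donors")
        exposures_h, expression_h, dropped = harmonize_donors(
            exposures, normalized
        )
        if dropped:
            logger.info("dropped %d unmatched ids", len(dropped))

        stage("correlate")
        profile = correlate_expression_signatures(expression_h, exposures_h)
        rho_out = profile.rho.copy()
        rho_out.index.name = "gene"
        emit("correlation_rho.tsv", io.write_matrix, rho_out)
        pval_out = profile.pval.copy()
        pval_out.index.name = "gene"
        emit("correlation_pval.tsv", io.write_matrix, pval_out)

        stage("select_genes")
        selected = select_significant_genes(profile, alpha=config.alpha)

        stage("choose_k")
        features = profile.rho.loc[selected]
        result = choose_k(
            features,
            k_range=range(config.k_min, config.k_max + 1),
            n_runs=config.n_runs,
            seed=config.seed,
            k_override=config.k_override,
        )
        assignment_out = result.assignment.to_frame()
        assignment_out.index.name = "gene"
        emit("cluster_assignment.tsv", io.write_matrix, assignment_out)
        emit("cluster_mean_rho.tsv", io.write_matrix, result.cluster_mean_rho)
        emit("validation_indices.tsv", io.write_matrix, result.validation)

        stage("enrichment")
        if config.genesets:
            genesets = read_gmt(config.genesets)
            table = enrich_clusters(result.assignment, genesets)
            emit(
                "enrichment.tsv",
                lambda df, p: df.to_csv(p, sep="\t", index=False),
                table,
            )
        else:
            logger.warning("no gene sets configured; enrichment skipped")

        stage("deconvolution")
        bulk_counts = (
            io.read_matrix(config.bulk) if config.bulk else counts
        )
        bulk_cpm = cpm_filter(bulk_counts, min_cpm=config.min_cpm)
        reference = io.read_matrix(config.reference)
        reference_cpm = cpm(reference)
        frac_result = estimate_fractions(
            bulk_cpm, reference_cpm, n_markers=config.n_markers
        )
        emit("cell_fractions.tsv", io.write_matrix, frac_result.fractions)

        stage("fraction_signature_correlation")
        lineage_map = io.read_lineage_map(config.lineage)
        shared = [s for s in frac_result.fractions.index if s in exposures.index]
        fr = frac_result.fractions.loc[shared]
        ex = exposures.loc[shared]
        for lineage in ("epithelial", "immune"):
            types = [t for t in fr.columns if lineage_map.get(t) == lineage]
            if not types:
                logger.warning("no %s cell types; subset skipped", lineage)
                continue
            sub = subset_fractions(fr, lineage_map, lineage)
            rho, pval = correlate_fractions_signatures(sub, ex)
            emit(f"fractions_{lineage}.tsv", io.write_matrix, sub)
            emit(f"fraction_signature_rho_{lineage}.tsv", io.write_matrix, rho)
            emit(f"fraction_signature_pval_{lineage}.tsv", io.write_matrix, pval)
    except Exception as exc:  # noqa: BLE001 - surface the failing stage
        raise RuntimeError(
            f"pipeline failed: {exc} (check the inputs of the stage named in "
            f"the log above)"
        ) from exc

    manifest = {
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, Path)
        },
        "active_signatures": active,
        "n_selected_genes": len(selected),
        "chosen_k": result.k,
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def write_fixture_dir(config: SimConfig, outdir) -> dict[str, str]:
    """Simulate a full cohort and write it as pipeline-ready input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(config)
    io.write_catalog(data.catalog, outdir / "catalog.tsv")
    io.write_catalog(data.signatures, outdir / "signatures.tsv")
    io.write_matrix(data.expression, outdir / "expression.tsv")
    io.write_matrix(data.cell_reference, outdir / "reference.tsv")
    io.write_matrix(data.bulk, outdir / "bulk.tsv")
    io.write_lineage_map(config.lineage_map, outdir / "lineage.tsv")
    io.write_exposures(data.truth.true_exposures, outdir / "true_exposures.tsv")
    truth = {
        "cluster_of_gene": {
            g: int(c) for g, c in data.truth.true_cluster_of_gene.items()
        },
        "true_fractions": {
            s: [float(v) for v in row]
            for s, row in data.truth.true_fractions.iterrows()
        },
    }
    io.write_json(truth, outdir / "truth.json")
    cfg = {
        k: (v.tolist() if hasattr(v, "tolist") else list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
        if k != "lineage_map"
    }
    cfg["lineage_map"] = dict(config.lineage_map)
    io.write_yaml(cfg, outdir / "sim_config.yaml")
    return {p.name: str(p) for p in sorted(outdir.iterdir())}
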