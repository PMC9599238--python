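"""Hypergeometric over-representation of gene sets within clusters.

The background universe is the set of clustered genes (not the genome):
terms are intersected with that background before testing, and the upper
tail P(X >= overlap) is computed for X ~ Hypergeom(bg, term_in_bg,
cluster_size). Benjamini-Hochberg q-values are reported within each
cluster; raw p-values are always kept alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_upper(
    overlap: int, cluster_size: int, term_in_bg: int, bg_size: int
) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap).

    X counts term genes in a draw of ``cluster_size`` from a background of
    ``bg_size`` genes of which ``term_in_bg`` belong to the term.
    """
    consistent = (
        0 <= overlap <= min(cluster_size, term_in_bg)
        and term_in_bg <= bg_size
        and cluster_size <= bg_size
    )
    if not consistent:
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, cluster={cluster_size}, "
            f"term={term_in_bg}, background={bg_size}"
        )
    if overlap == 0:
        return 1.0
    # survival function at overlap-1 gives P(X >= overlap)
    return float(hypergeom.sf(overlap - 1, bg_size, term_in_bg, cluster_size))


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT gene-set file: term_id, description, member genes."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if genes:
                sets[term] = (desc, genes)
    return sets


def enrich_clusters(
    assignment: pd.Series,
    genesets: dict[str, tuple[str, list[str]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(cluster, term) over-representation table.

    ``assignment`` maps gene -> cluster id; its genes form the background.
    Terms with no background member are excluded. Rows are sorted by
    (cluster, p); ``q`` is BH-adjusted within each cluster.
    """
    background = set(assignment.index)
    if not background:
        raise ValueError("empty background")
    bg_size = len(background)
    rows = []
    for cluster_id, members in assignment.groupby(assignment):
        cluster_genes = set(members.index)
        for term, (desc, genes) in genesets.items():
            term_genes = set(genes) & background
            if not term_genes:
                continue
            overlap = len(term_genes & cluster_genes)
            p = hypergeom_upper(
                overlap, len(cluster_genes), len(term_genes), bg_size
            )
            rows.append(
                {
                    "cluster": cluster_id,
                    "term": term,
                    "description": desc,
                    "overlap": overlap,
                    "cluster_size": len(cluster_genes),
                    "term_in_bg": len(term_genes),
                    "bg_size": bg_size,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for cluster_id, idx in table.groupby("cluster").groups.items():
        _, q, _, _ = multipletests(table.loc[idx, "p"], method="fdr_bh")
        table.loc[idx, "q"] = q
    table["significant"] = table["q"] < alpha
    return table.sort_values(["cluster", "p"], kind="stable").reset_index(drop=True)
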