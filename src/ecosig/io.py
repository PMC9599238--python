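"""Tab-delimited readers/writers for the pipeline's file formats.

Catalogs and signature matrices use the COSMIC dialect: a ``MutationType``
first column with labels like ``A[C>A]A`` and one column per sample or
signature. Expression, reference and fraction tables are plain TSV with a
header of sample / cell-type ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .sbs import validate_categories


def read_catalog(path) -> pd.DataFrame:
    """Read a COSMIC-dialect SBS96 matrix (catalog or signatures)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "MutationType"
    validate_categories(df.index)
    return df


def write_catalog(df: pd.DataFrame, path) -> None:
    df = df.copy()
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    """Generic row-labeled TSV matrix (genes x samples, etc.)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_exposures(exposures: pd.DataFrame, path) -> None:
    """Samples x signatures exposure TSV with a trailing Total column."""
    out = exposures.copy()
    out["Total"] = out.sum(axis=1)
    out.index.name = "Sample"
    out.to_csv(path, sep="\t")


def read_exposures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.drop(columns=["Total"], errors="ignore")


def read_lineage_map(path) -> dict[str, str]:
    """Two-column TSV: cell type, lineage (epithelial/immune/other)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "lineage"])
    return dict(zip(df["cell_type"], df["lineage"]))


def write_lineage_map(lineage_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for ct, lin in lineage_map.items():
            fh.write(f"{ct}\t{lin}\n")


def write_gmt(genesets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in genesets.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
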