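"""Typed TSV/BED/MTX readers and writers for every pipeline table.

All tabular artifacts are TSV with explicit headers; gene annotation is also
accepted as BED (0-based half-open, converted to the internal 1-based
inclusive convention on read); single-cell counts are Matrix Market plus
gene and cell TSVs.  Schema validation is strict: a header that does not
match the expected column list raises with the missing/extra columns named.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

SCHEMAS: Dict[str, Dict[str, type]] = {
    "index_snps": {"snp_id": str, "chrom": str, "pos": int},
    "annotation": {"gene_id": str, "chrom": str, "start": int, "end": int, "strand": str, "tss": int},
    "candidates": {"locus_id": str, "snp_id": str, "gene_id": str, "tss_distance": int, "is_closest": bool},
    "features": {"gene_id": str, "fantom5": float, "hic": float, "dist_tss": float},
    "de": {"gene_id": str, "p": float},
    "cpg": {"cpg_id": str, "gene_id": str, "p": float, "log2fc": float},
    "network": {"gene_a": str, "gene_b": str, "weight": float},
    "methyl_scores": {"gene_id": str, "k": int, "z_m": float, "p_gene": float},
    "posterior": {
        "locus_id": str, "snp_id": str, "gene_id": str, "frequency": float,
        "selected": bool, "converged": bool, "sweeps": int, "seed": int,
    },
    "prgenes": {"gene_id": str, "loci": str, "n_loci": int, "max_frequency": float},
    "eqtl": {
        "gene_id": str, "tissue": str, "snp_id": str, "pos": int,
        "effect_allele": str, "other_allele": str, "eaf": float,
        "beta_exp": float, "se_exp": float, "p_exp": float,
    },
    "outcome": {
        "snp_id": str, "effect_allele": str, "other_allele": str,
        "eaf": float, "beta_out": float, "se_out": float,
    },
    "mr_results": {
        "gene_id": str, "tissue": str, "method": str, "estimate": float,
        "se": float, "p": float, "fdr": float, "n_snps": int,
    },
    "cells": {"cell_id": str, "cell_type": str},
    "enrichment": {"cell_type": str, "overlap": int, "p_raw": float},
}


class SchemaError(ValueError):
    """Raised when a table's header does not match its schema."""


def _check_columns(columns: Sequence[str], schema_name: str) -> None:
    expected = list(SCHEMAS[schema_name])
    got = list(columns)
    if got != expected:
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        raise SchemaError(
            f"table does not match schema {schema_name!r}: "
            f"missing columns {missing}, extra columns {extra}"
        )


def write_table(df: pd.DataFrame, path, schema: Optional[str] = None) -> None:
    """Write a TSV with header; if a schema is named, validate columns first."""
    if schema is not None:
        _check_columns(df.columns, schema)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a schema-validated TSV with typed columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df.columns, schema)
    for col, typ in SCHEMAS[schema].items():
        if typ is int:
            df[col] = df[col].astype(np.int64)
        elif typ is float:
            df[col] = df[col].astype(float)
        elif typ is bool:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def read_bed_annotation(path) -> pd.DataFrame:
    """Gene annotation from BED6 (chrom, start, end, name, score, strand).

    BED is 0-based half-open; internal coordinates are 1-based inclusive, so
    start -> start + 1 and end is unchanged.  The TSS is the start for +
    strand and the end for - strand.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str, "strand": str},
    )
    start1 = bed["start"] + 1
    end1 = bed["end"]
    tss = np.where(bed["strand"] == "+", start1, end1)
    return pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "start": start1.astype(np.int64),
            "end": end1.astype(np.int64),
            "strand": bed["strand"],
            "tss": tss.astype(np.int64),
        }
    )


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t", index=True, index_label="snp_id")


def read_ld_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="snp_id")


def write_counts_mtx(counts: pd.DataFrame, labels: pd.Series, outdir) -> None:
    """Counts as Matrix Market (genes x cells) + gene and cell TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "counts.mtx"), sparse.coo_matrix(counts.to_numpy()))
    pd.DataFrame({"gene_id": counts.index}).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame({"cell_id": counts.columns, "cell_type": labels.loc[counts.columns].to_numpy()})
    write_table(cells, outdir / "cells.tsv", schema="cells")


def read_counts_mtx(outdir) -> Tuple[pd.DataFrame, pd.Series]:
    outdir = Path(outdir)
    mat = spio.mmread(str(outdir / "counts.mtx")).toarray()
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", dtype=str)["gene_id"]
    cells = read_table(outdir / "cells.tsv", schema="cells")
    counts = pd.DataFrame(mat.astype(np.int64), index=genes.to_numpy(), columns=cells["cell_id"].to_numpy())
    counts.index.name = "gene_id"
    labels = pd.Series(cells["cell_type"].to_numpy(), index=cells["cell_id"].to_numpy(), name="cell_type")
    labels.index.name = "cell_id"
    return counts, labels


def network_to_edges(graph) -> pd.DataFrame:
    rows = [
        {"gene_a": min(a, b), "gene_b": max(a, b), "weight": float(d.get("weight", 1.0))}
        for a, b, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).sort_values(
        ["gene_a", "gene_b"]
    ).reset_index(drop=True)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
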