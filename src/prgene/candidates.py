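"""Candidate risk-gene extraction around GWAS index SNPs.

Every gene whose body intersects the 2-Mb window centered on an index SNP is
a candidate risk gene of that locus (TSS-only membership is available as an
option).  Distances are index-SNP-to-TSS in base pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = ["locus_id", "snp_id", "gene_id", "tss_distance", "is_closest"]


def tss_distance(snp_pos: int, tss: int, snp_chrom=None, gene_chrom=None) -> int:
    """Absolute base-pair distance from an index SNP to a gene's TSS.

    If chromosome labels are supplied they must match.
    """
    if snp_chrom is not None and gene_chrom is not None and snp_chrom != gene_chrom:
        raise ValueError(f"SNP on {snp_chrom} and gene on {gene_chrom}: distance undefined")
    return int(abs(int(snp_pos) - int(tss)))


def extract_candidates(
    index_snps: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = 2_000_000,
    membership: str = "overlap",
) -> pd.DataFrame:
    """Candidate genes in the window of width ``window_bp`` centered per SNP.

    membership="overlap" (default) includes a gene iff its [start, end]
    interval intersects [pos - window_bp/2, pos + window_bp/2] on the same
    chromosome; membership="tss" requires the TSS itself to fall inside the
    window.  Loci with no candidate gene are dropped with a warning.  The
    locus_id equals the snp_id (one index SNP anchors one locus).  Exactly
    one gene per locus is flagged is_closest (minimum TSS distance, ties to
    the lexicographically smallest gene_id).
    """
    if window_bp <= 0 or window_bp % 2 != 0:
        raise ValueError("window_bp must be a positive even number of base pairs")
    if membership not in ("overlap", "tss"):
        raise ValueError(f"unknown membership rule {membership!r}")
    half = window_bp // 2

    known_chroms = set(annotation["chrom"])
    unknown = set(index_snps["chrom"]) - known_chroms
    if unknown:
        raise ValueError(f"index SNPs on chromosomes absent from the annotation: {sorted(unknown)}")

    rows = []
    for snp in index_snps.sort_values("snp_id").itertuples(index=False):
        lo, hi = snp.pos - half, snp.pos + half
        same = annotation[annotation["chrom"] == snp.chrom]
        if membership == "overlap":
            hit = same[(same["start"] <= hi) & (same["end"] >= lo)]
        else:
            hit = same[(same["tss"] >= lo) & (same["tss"] <= hi)]
        if len(hit) == 0:
            logger.warning("locus %s has no candidate gene in its window; dropped", snp.snp_id)
            continue
        dist = np.abs(hit["tss"].to_numpy(dtype=np.int64) - int(snp.pos))
        sub = pd.DataFrame(
            {
                "locus_id": snp.snp_id,
                "snp_id": snp.snp_id,
                "gene_id": hit["gene_id"].to_numpy(),
                "tss_distance": dist,
            }
        ).sort_values(["tss_distance", "gene_id"], kind="mergesort")
        flags = np.zeros(len(sub), dtype=bool)
        flags[0] = True  # minimum distance, lexicographic tie-break via the sort
        sub["is_closest"] = flags
        rows.append(sub.sort_values("gene_id", kind="mergesort"))
    if not rows:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    out = pd.concat(rows, ignore_index=True)
    return out[CANDIDATE_COLUMNS]
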