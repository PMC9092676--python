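"""Gene-level methylation scores from CpG-level differential statistics.

Promoter-region CpGs serve as the surrogate for gene-level methylation.
Each CpG's two-sided p-value and the sign of its log2 fold change are
converted to a signed z-score, the per-gene z-scores are combined by
Stouffer's method (sum over sqrt(k)), and the combined z is reversed to a
two-sided gene-level p-value.

Sign convention: the default ("corrected") is z = sign(log2FC) * Phi^-1(1 - p/2),
so significant hypermethylation gives a large positive z.  The "literal"
variant z = sign(log2FC) * Phi^-1(p/2) (which negates the z for p < 1) is
kept behind a flag.
"""

from __future__ import annotations

import logging
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

_TINY = np.nextafter(0.0, 1.0)  # smallest positive double, for clipping
# floor for p-values entering the inverse normal CDF: ndtri is finite here
# (~ -37) whereas subnormal arguments underflow to -inf
_MIN_P = 1e-300


def cpg_signed_z(p, log2fc, convention: str = "corrected"):
    """Signed z-score of one CpG from its two-sided p-value and fold-change sign.

    |z| = Phi^-1(1 - p/2); sign(z) = sign(log2fc).  z = 0 when p = 1 or
    log2fc = 0.  Accepts scalars or arrays.  p must lie in (0, 1].
    """
    p_arr = np.asarray(p, dtype=float)
    fc = np.asarray(log2fc, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if convention == "corrected":
        # Phi^-1(1 - p/2) computed as -Phi^-1(p/2): stable for very small p
        magnitude = -special.ndtri(p_arr / 2.0)
    elif convention == "literal":
        magnitude = special.ndtri(p_arr / 2.0)
    else:
        raise ValueError(f"unknown sign convention {convention!r}")
    z = np.sign(fc) * magnitude
    if np.isscalar(p) and np.isscalar(log2fc):
        return float(z)
    return z


def combine_stouffer(z_values) -> float:
    """Stouffer combination: sum(z) / sqrt(k) over k z-scores."""
    z = np.asarray(list(z_values) if not isinstance(z_values, np.ndarray) else z_values, dtype=float)
    if z.size == 0:
        raise ValueError("cannot combine an empty list of z-scores")
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    return float(z.sum() / np.sqrt(z.size))


def gene_methyl_pvalue(z_m) -> float:
    """Two-sided normal tail of a combined gene-level z-score.

    p = 2 * (1 - Phi(|z|)), clipped to the smallest positive double on
    underflow so downstream logs stay finite.
    """
    z = np.asarray(z_m, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    p = 2.0 * special.ndtr(-np.abs(z))
    p = np.clip(p, _TINY, 1.0)
    if np.isscalar(z_m):
        return float(p)
    return p


def assign_cpgs_to_genes(cpg_table: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Partition annotated CpG records by gene_id.

    CpGs with a missing/empty gene annotation are excluded and counted in the
    log.  Raises on an empty input table.
    """
    if cpg_table is None or len(cpg_table) == 0:
        raise ValueError("CpG table is empty")
    annotated = cpg_table[cpg_table["gene_id"].notna() & (cpg_table["gene_id"] != "")]
    n_dropped = len(cpg_table) - len(annotated)
    if n_dropped:
        logger.warning("%d CpG records without a gene annotation were excluded", n_dropped)
    return {g: sub.reset_index(drop=True) for g, sub in annotated.groupby("gene_id", sort=True)}


def score_genes(cpg_table: pd.DataFrame, convention: str = "corrected") -> pd.DataFrame:
    """Gene-level methylation scores (gene_id, k, z_m, p_gene) from CpG records.

    Input p-values equal to 0 are clipped to the smallest positive double
    before the inverse-normal transform; CpGs with log2fc exactly 0
    contribute z = 0 (no directional evidence).
    """
    groups = assign_cpgs_to_genes(cpg_table)
    rows: List[dict] = []
    for gene_id, sub in groups.items():
        p = np.clip(sub["p"].to_numpy(dtype=float), _MIN_P, 1.0)
        z = cpg_signed_z(p, sub["log2fc"].to_numpy(dtype=float), convention=convention)
        z_m = combine_stouffer(np.atleast_1d(z))
        rows.append(
            {"gene_id": gene_id, "k": len(sub), "z_m": z_m, "p_gene": gene_methyl_pvalue(z_m)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "k", "z_m", "p_gene"])
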