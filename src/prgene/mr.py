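"""Two-sample Mendelian randomization of expression on outcome.

Per gene x tissue: the cis-eQTL instruments below a raw p-value threshold
(1e-4) are LD-clumped (greedy, removing SNPs with r^2 > 0.001 within 10 Mb
of a better-ranked SNP), harmonized against the outcome summary statistics
(sign flips for swapped alleles, ambiguous palindromic SNPs dropped), and
the causal effect is estimated with the Wald ratio when a single instrument
remains or fixed-effect inverse-variance weighting (IVW) otherwise.
Benjamini-Hochberg FDR is applied within each tissue's batch of genes.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_AMBIGUOUS_EAF = (0.42, 0.58)


def select_instruments(eqtl_table: pd.DataFrame, p_threshold: float = 1e-4) -> pd.DataFrame:
    """Keep cis-eQTL SNPs with p_exp strictly below the threshold.

    Genes whose instruments are all filtered out are dropped and logged.
    """
    kept = eqtl_table[eqtl_table["p_exp"] < p_threshold].copy()
    lost = set(eqtl_table["gene_id"]) - set(kept["gene_id"])
    if lost:
        logger.info("%d genes lost all instruments at p < %g", len(lost), p_threshold)
    return kept.reset_index(drop=True)


def ld_clump(
    instruments: pd.DataFrame,
    ld_matrix: pd.DataFrame,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Greedy LD clumping within one gene's instrument set.

    Repeatedly keep the smallest-p_exp SNP and remove every other SNP with
    r^2 > r2_threshold within window_bp of it.  A missing LD entry is
    treated as r^2 = 1 (conservative) and logged.
    """
    if len(instruments) == 0:
        return instruments.copy()
    df = instruments.sort_values(["p_exp", "snp_id"], kind="mergesort").reset_index(drop=True)
    keep: list[int] = []
    alive = np.ones(len(df), dtype=bool)
    snps = df["snp_id"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    for i in range(len(df)):
        if not alive[i]:
            continue
        keep.append(i)
        for j in range(i + 1, len(df)):
            if not alive[j]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            try:
                r2 = float(ld_matrix.loc[snps[i], snps[j]])
            except KeyError:
                r2 = np.nan
            if np.isnan(r2):
                logger.warning("missing LD entry (%s, %s); treated as r2=1", snps[i], snps[j])
                r2 = 1.0
            if r2 > r2_threshold:
                alive[j] = False
    return df.iloc[keep].reset_index(drop=True)


def harmonize(merged: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effect alleles with the exposure alleles.

    ``merged`` carries per-SNP exposure columns (effect_allele, other_allele,
    eaf, beta_exp, se_exp) and outcome columns (effect_allele_out,
    other_allele_out, beta_out, se_out).  Swapped orientations flip the sign
    of beta_out; palindromic SNPs (A/T or C/G) with exposure eaf inside
    [0.42, 0.58] are dropped as ambiguous; incompatible allele sets are
    dropped with a log entry.
    """
    rows = []
    n_palindromic = n_incompatible = 0
    for rec in merged.to_dict("records"):
        ea, oa = rec["effect_allele"], rec["other_allele"]
        eao, oao = rec["effect_allele_out"], rec["other_allele_out"]
        if frozenset((ea, oa)) in _PALINDROMIC:
            eaf = rec.get("eaf", np.nan)
            if np.isnan(eaf) or _AMBIGUOUS_EAF[0] <= eaf <= _AMBIGUOUS_EAF[1]:
                n_palindromic += 1
                continue
        if (eao, oao) == (ea, oa):
            pass
        elif (eao, oao) == (oa, ea):
            rec["beta_out"] = -rec["beta_out"]
        else:
            n_incompatible += 1
            continue
        rows.append(rec)
    if n_palindromic:
        logger.info("dropped %d ambiguous palindromic SNPs", n_palindromic)
    if n_incompatible:
        logger.warning("dropped %d SNPs with incompatible allele sets", n_incompatible)
    return pd.DataFrame(rows, columns=merged.columns)


def wald_ratio(beta_out: float, se_out: float, beta_exp: float) -> Tuple[float, float]:
    """Single-instrument Wald ratio: (beta_out/beta_exp, se_out/|beta_exp|)."""
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def ivw(beta_exp, beta_out, se_out) -> Tuple[float, float]:
    """Fixed-effect inverse-variance-weighted estimate over >= 2 instruments.

    estimate = sum(w * bx * by) / sum(w * bx^2),  w = 1/se_out^2;
    se = 1 / sqrt(sum(w * bx^2)).  Equivalent to weighted regression of
    beta_out on beta_exp through the origin.
    """
    bx = np.asarray(beta_exp, dtype=float)
    by = np.asarray(beta_out, dtype=float)
    so = np.asarray(se_out, dtype=float)
    if bx.size < 2:
        raise ValueError("IVW needs at least 2 instruments; use wald_ratio")
    w = 1.0 / so**2
    denom = float(np.sum(w * bx**2))
    est = float(np.sum(w * bx * by)) / denom
    se = 1.0 / np.sqrt(denom)
    return est, float(se)


def _normal_p(est: float, se: float) -> float:
    return float(2.0 * special.ndtr(-abs(est / se))) if se > 0 else np.nan


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_mr(
    eqtl_table: pd.DataFrame,
    outcome_table: pd.DataFrame,
    ld_matrix: pd.DataFrame,
    p_threshold: float = 1e-4,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
    fdr_per_tissue: bool = True,
) -> pd.DataFrame:
    """Full per-gene x tissue MR: filter, clump, harmonize, estimate, BH-FDR.

    Returns rows (gene_id, tissue, method, estimate, se, p, fdr, n_snps);
    method is "wald_ratio" iff exactly one instrument survived clumping and
    harmonization, "ivw" otherwise.
    """
    instruments = select_instruments(eqtl_table, p_threshold)
    out_cols = outcome_table.rename(
        columns={
            "effect_allele": "effect_allele_out",
            "other_allele": "other_allele_out",
            "eaf": "eaf_out",
        }
    )
    results = []
    for (gene, tissue), sub in instruments.groupby(["gene_id", "tissue"], sort=True):
        clumped = ld_clump(sub, ld_matrix, r2_threshold, window_bp)
        merged = clumped.merge(out_cols, on="snp_id", how="inner")
        if len(merged) < len(clumped):
            logger.warning(
                "gene %s tissue %s: %d instruments missing from the outcome data",
                gene, tissue, len(clumped) - len(merged),
            )
        harm = harmonize(merged)
        if len(harm) == 0:
            logger.info("gene %s tissue %s: no instrument survived harmonization", gene, tissue)
            continue
        if len(harm) == 1:
            r = harm.iloc[0]
            est, se = wald_ratio(float(r["beta_out"]), float(r["se_out"]), float(r["beta_exp"]))
            method = "wald_ratio"
        else:
            est, se = ivw(harm["beta_exp"], harm["beta_out"], harm["se_out"])
            method = "ivw"
        results.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "method": method,
                "estimate": est,
                "se": se,
                "p": _normal_p(est, se),
                "n_snps": len(harm),
            }
        )
    res = pd.DataFrame(
        results, columns=["gene_id", "tissue", "method", "estimate", "se", "p", "n_snps"]
    )
    if len(res) == 0:
        res["fdr"] = pd.Series(dtype=float)
        return res
    if fdr_per_tissue:
        res["fdr"] = np.nan
        for tissue, sub in res.groupby("tissue"):
            res.loc[sub.index, "fdr"] = bh_adjust(sub["p"].to_numpy())
    else:
        res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res[["gene_id", "tissue", "method", "estimate", "se", "p", "fdr", "n_snps"]]
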