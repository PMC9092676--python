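"""Per-gene evidence integration: whitening, tail p-values, Fisher product.

Continuous regulatory features (FANTOM5-like linkage, Hi-C contact, distance
to TSS) are decorrelated with the Mahalanobis transformation so each column
is approximately standard normal, converted to one-sided tail p-values in
the direction that counts as evidence, concatenated with differential
expression and gene-level methylation p-values, and combined per gene with
Fisher's product.  The product is carried in log space as
log_bf = -sum(ln p) over non-missing entries — a monotone increasing
function of significance that acts as the Bayes-factor surrogate in the
Gibbs sampler's model-selection conditional.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

_TINY = np.nextafter(0.0, 1.0)

#: default evidence orientation per feature column
DEFAULT_ORIENTATION = {
    "fantom5": "larger",
    "hic": "larger",
    "dist_tss": "smaller",
}


def decorrelate_features(features: pd.DataFrame) -> pd.DataFrame:
    """Mahalanobis whitening: y = Sigma^(-1/2) (x - mu) per row.

    mu and Sigma are estimated from rows with no missing entries; rows with
    any missing value whiten to all-NaN (the transform mixes columns).
    Constant columns are dropped with a warning; a singular covariance is
    ridge-regularized by lambda*I with lambda = 1e-6 * trace / m.
    The output sample covariance over complete rows is ~ identity.
    """
    if features is None or features.shape[1] < 1:
        raise ValueError("feature matrix needs at least one column")
    X = features.astype(float)
    complete = X.dropna()
    if len(complete) < 2:
        raise ValueError("need at least 2 complete rows to estimate the covariance")
    keep = [c for c in X.columns if complete[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        logger.warning("constant feature columns dropped before whitening: %s", dropped)
    if not keep:
        raise ValueError("all feature columns are constant")
    X = X[keep]
    complete = complete[keep]

    mu = complete.mean().to_numpy()
    cov = np.atleast_2d(np.cov(complete.to_numpy(), rowvar=False, ddof=1))
    m = cov.shape[0]
    # whiten on the correlation scale: scale-robust when features have very
    # different units (e.g. base pairs vs. linkage scores); the output sample
    # covariance over complete rows is the identity either way
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() <= 1e-10:
        lam = 1e-6 * np.trace(corr) / m
        logger.warning("near-singular covariance; ridge-regularized with lambda=%.3g", lam)
        eigval = eigval + lam
    c_half = eigvec @ np.diag(1.0 / np.sqrt(eigval)) @ eigvec.T  # symmetric inverse sqrt
    w_half = c_half @ np.diag(1.0 / sd)

    out = np.full((len(X), m), np.nan)
    ok = X.notna().all(axis=1).to_numpy()
    out[ok] = (X.to_numpy()[ok] - mu) @ w_half.T
    return pd.DataFrame(out, index=features.index, columns=keep)


def feature_pvalues(
    whitened: pd.DataFrame, orientation: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """One-sided standard-normal tail p-values in the evidence direction.

    orientation maps column -> "larger" (larger score is evidence,
    p = 1 - Phi(y)) or "smaller" (p = Phi(y)).  Missing input stays missing.
    """
    if orientation is None:
        orientation = DEFAULT_ORIENTATION
    out = {}
    for col in whitened.columns:
        try:
            direction = orientation[col]
        except KeyError:
            raise ValueError(f"no evidence orientation configured for feature {col!r}") from None
        y = whitened[col].to_numpy(dtype=float)
        if direction == "larger":
            p = special.ndtr(-y)
        elif direction == "smaller":
            p = special.ndtr(y)
        else:
            raise ValueError(f"orientation for {col!r} must be 'larger' or 'smaller', got {direction!r}")
        out[f"p_{col}"] = np.where(np.isnan(y), np.nan, np.clip(p, _TINY, 1.0))
    return pd.DataFrame(out, index=whitened.index)


def _check_unique(df: pd.DataFrame, source: str) -> None:
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5]
        raise ValueError(f"duplicate gene_id in {source}: {list(dups)}")


def assemble_pvalue_matrix(
    feature_ps: pd.DataFrame, de_ps: pd.DataFrame, methyl_ps: pd.DataFrame
) -> pd.DataFrame:
    """Outer-join per-source p-values on gene_id into one matrix.

    feature_ps: gene_id + p_* columns; de_ps: (gene_id, p); methyl_ps:
    (gene_id, p_gene).  Missing entries stay NaN — they are skipped by the
    Fisher combination, not imputed as 1.
    """
    for df, src in ((feature_ps, "features"), (de_ps, "differential expression"), (methyl_ps, "methylation")):
        _check_unique(df, src)
    fp = feature_ps.set_index("gene_id")
    de = de_ps.set_index("gene_id")["p"].rename("p_de")
    me = methyl_ps.set_index("gene_id")["p_gene"].rename("p_methyl")
    mat = fp.join(de, how="outer").join(me, how="outer")
    n_missing = int(mat.isna().sum().sum())
    if n_missing:
        logger.info("p-value matrix has %d missing entries (skipped in the Fisher product)", n_missing)
    return mat.sort_index()


def fisher_log_evidence(p_values: pd.DataFrame) -> pd.DataFrame:
    """Fisher's product in log space: log_bf = -sum(ln p) over non-missing p.

    Returns a frame (gene_id index, df = number of combined p-values,
    log_bf).  A gene with no observed p-value gets log_bf = 0 with a warning.
    Zeros are clipped to the smallest positive double.
    """
    P = p_values.to_numpy(dtype=float)
    if np.any(P[~np.isnan(P)] <= 0.0) or np.any(P[~np.isnan(P)] > 1.0):
        P = np.where(np.isnan(P), np.nan, np.clip(P, _TINY, 1.0))
    with np.errstate(invalid="ignore"):
        neg_log = -np.log(P)
    df_count = (~np.isnan(P)).sum(axis=1)
    log_bf = np.nansum(neg_log, axis=1)
    empty = df_count == 0
    if empty.any():
        logger.warning("%d genes have no observed p-values; log_bf set to 0", int(empty.sum()))
        log_bf[empty] = 0.0
    return pd.DataFrame({"df": df_count, "log_bf": log_bf}, index=p_values.index)


def build_evidence(
    features: pd.DataFrame,
    de_table: pd.DataFrame,
    methyl_scores: pd.DataFrame,
    orientation: Optional[Dict[str, str]] = None,
    feature_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Full evidence table from raw inputs.

    features: gene_id + continuous feature columns; de_table: (gene_id, p);
    methyl_scores: output of :func:`prgene.methylation.score_genes`.
    Returns rows (gene_id, p_<feature>..., p_de, p_methyl, df, log_bf).
    """
    _check_unique(features, "features")
    if feature_columns is None:
        feature_columns = [c for c in features.columns if c != "gene_id"]
    X = features.set_index("gene_id")[list(feature_columns)]
    Y = decorrelate_features(X)
    fp = feature_pvalues(Y, orientation).reset_index()
    mat = assemble_pvalue_matrix(fp, de_table, methyl_scores)
    bf = fisher_log_evidence(mat)
    out = mat.join(bf).reset_index().rename(columns={"index": "gene_id"})
    if "gene_id" not in out.columns:
        out = out.rename(columns={mat.index.name or "gene_id": "gene_id"})
    return out
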