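"""Cell-type-specificity enrichment analysis (CSEA) for gene sets.

From a labeled single-cell count matrix: genes with more than 95% zero
counts are filtered out; per gene and cell type a Welch t statistic compares
log1p library-size-normalized expression in that type's cells against all
other cells; each cell type's specificity panel is the top fraction of
background genes by t; a query gene set is tested against each panel with a
one-sided Fisher's exact test (hypergeometric upper tail).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Set

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def filter_genes(counts: pd.DataFrame, zero_fraction: float = 0.95) -> pd.DataFrame:
    """Remove genes whose zero-count cell fraction strictly exceeds the cutoff.

    A gene zero in exactly 95% of cells is kept ("more than" is strict).
    """
    if counts is None or counts.size == 0:
        raise ValueError("count matrix is empty")
    zf = (counts.to_numpy() == 0).mean(axis=1)
    kept = counts.loc[zf <= zero_fraction]
    logger.info("gene filter: kept %d of %d genes", len(kept), len(counts))
    return kept


def normalize_log1p(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log1p of library-size-normalized counts (counts / colsum * scale)."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    x = counts.to_numpy(dtype=float) / lib * scale
    return pd.DataFrame(np.log1p(x), index=counts.index, columns=counts.columns)


def cell_type_t_stats(filtered: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Welch t statistic per (gene, cell type): this type's cells vs the rest.

    Expression is log1p library-size-normalized before the comparison.
    Zero-variance comparisons yield t = 0; cell types with fewer than 2
    cells are excluded with a warning.
    """
    labels = labels.loc[filtered.columns]
    types = sorted(labels.unique())
    expr = normalize_log1p(filtered).to_numpy()
    out = {}
    for ct in types:
        mask = (labels == ct).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            logger.warning("cell type %s has fewer than 2 cells on one side; excluded", ct)
            continue
        a, b = expr[:, mask], expr[:, ~mask]
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        denom = np.sqrt(va / mask.sum() + vb / (~mask).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, (ma - mb) / denom, 0.0)
        out[ct] = t
    if len(out) < 2:
        raise ValueError("need at least 2 usable cell types")
    return pd.DataFrame(out, index=filtered.index)


@dataclass
class SpecificityPanel:
    """Per-cell-type specific gene sets over a filtered background."""

    background: Set[str]
    per_cell_type: Dict[str, Set[str]]
    t_stats: pd.DataFrame


def build_specificity_panels(t_stats: pd.DataFrame, top_fraction: float = 0.05) -> SpecificityPanel:
    """Top ceil(top_fraction * |background|) genes by t per cell type.

    Ties broken deterministically by gene_id; panels may overlap across cell
    types.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    background = set(t_stats.index)
    k = math.ceil(top_fraction * len(background))
    panels = {}
    for ct in t_stats.columns:
        order = sorted(zip(-t_stats[ct].to_numpy(), t_stats.index))
        panels[ct] = {g for _, g in order[:k]}
    return SpecificityPanel(background=background, per_cell_type=panels, t_stats=t_stats)


def enrich(query_genes: Iterable[str], panel: SpecificityPanel) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of a query set in each panel.

    The query is intersected with the background first; per cell type the
    2x2 table (query∩panel, query∖panel, panel∖query, rest) is tested with
    the hypergeometric upper tail.  Returns (cell_type, overlap, p_raw).
    """
    query = set(query_genes) & panel.background
    if not query:
        raise ValueError("query has no gene in the panel background")
    N = len(panel.background)
    n = len(query)
    rows = []
    for ct in sorted(panel.per_cell_type):
        spec = panel.per_cell_type[ct]
        K = len(spec)
        overlap = len(query & spec)
        # P(X >= overlap), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append({"cell_type": ct, "overlap": overlap, "p_raw": min(1.0, p)})
    return pd.DataFrame(rows, columns=["cell_type", "overlap", "p_raw"])


def run_csea(
    counts: pd.DataFrame,
    labels: pd.Series,
    query_genes: Iterable[str],
    zero_fraction: float = 0.95,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Filter, build panels, and test a query set; returns the enrichment table."""
    filtered = filter_genes(counts, zero_fraction)
    t = cell_type_t_stats(filtered, labels)
    panel = build_specificity_panels(t, top_fraction)
    return enrich(query_genes, panel)
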