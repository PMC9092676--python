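"""Synthetic multi-omics data with planted ground truth.

Every pipeline input — genome annotation, index SNPs, regulatory features,
differential-expression and CpG methylation summaries, a weighted gene
network, eQTL/outcome summary statistics with an LD matrix, and a labeled
single-cell count matrix — is generated from one :class:`SimulationConfig`
with a known truth set (one planted risk gene per locus, a true causal
effect for Mendelian randomization, disjoint marker gene sets per cell
type), so each downstream stage can be tested for recovery.

Signal model: planted genes draw omics p-values from Beta(1/effect_strength, 1),
which equals Uniform(0, 1) at effect_strength = 1 and concentrates at 0 as
effect_strength grows; all null p-values are Uniform(0, 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

from .config import SimulationConfig

# fixed spawn keys: one independent child stream per generator
_STREAM_GENOME = 1
_STREAM_LOCI = 2
_STREAM_EVIDENCE = 3
_STREAM_MR = 4
_STREAM_SC = 5

_NON_PALINDROMIC_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


class GenerationError(RuntimeError):
    """Raised when the requested synthetic design cannot be realized."""


@dataclass
class TruthSet:
    """Ground truth planted by the generators.

    planted_gene_by_locus maps locus_id -> the single true risk gene whose
    body lies inside the locus's 2-Mb window; theta_mr is the true causal
    effect of expression on outcome; marker_genes_by_cell_type maps each cell
    type to a disjoint set of marker genes.
    """

    planted_gene_by_locus: Dict[str, str]
    theta_mr: float
    marker_genes_by_cell_type: Dict[str, Set[str]]

    @property
    def planted_genes(self) -> Set[str]:
        return set(self.planted_gene_by_locus.values())


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def generate_genome(config: SimulationConfig) -> pd.DataFrame:
    """Lay down a gene annotation (gene_id, chrom, start, end, strand, tss).

    Genes are placed sequentially per chromosome with random gaps calibrated
    so that a 2-Mb window contains about ``candidates_per_locus_target``
    genes.  Coordinates are 1-based inclusive; the TSS is the start for +
    strand genes and the end for - strand genes.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENOME)
    spacing = 2_000_000 / config.candidates_per_locus_target
    per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per_chrom[: config.n_genes % config.n_chrom] += 1

    width = max(5, len(str(config.n_genes)))
    rows = []
    gene_index = 0
    for c in range(config.n_chrom):
        pos = 1
        for _ in range(int(per_chrom[c])):
            gap = int(rng.uniform(0.6, 1.4) * spacing)
            start = pos + gap
            length = int(rng.integers(5_000, 60_000))
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + length
            rows.append(
                {
                    "gene_id": f"G{gene_index:0{width}d}",
                    "chrom": f"chr{c + 1}",
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": start if strand == "+" else end,
                }
            )
            gene_index += 1
            pos = start
    ann = pd.DataFrame(rows)
    return ann


def generate_loci_and_truth(
    config: SimulationConfig, annotation: pd.DataFrame, window_bp: int = 2_000_000
) -> Tuple[pd.DataFrame, TruthSet, nx.Graph]:
    """Place index SNPs, plant one risk gene per locus, and build the network.

    Each index SNP is dropped near a randomly chosen planted gene so that the
    gene body lies well inside the 2-Mb candidate window and the window holds
    at least two candidates.  The weighted undirected gene network connects
    planted-gene pairs with probability ``module_edge_prob`` and all other
    pairs with ``background_edge_prob``.  Disjoint marker gene sets (for the
    single-cell stage) are drawn from the remaining genes, except that the
    first cell type's markers are seeded with the planted genes so the
    disease gene set is cell-type specific by construction.
    """
    if annotation is None or len(annotation) == 0:
        raise GenerationError("annotation is empty")
    rng = _rng(config, _STREAM_LOCI)
    half = window_bp // 2

    ann = annotation.sort_values("gene_id").reset_index(drop=True)
    order = rng.permutation(len(ann))
    planted: list[int] = []
    snp_rows = []
    truth_map: Dict[str, str] = {}
    placed_by_chrom: Dict[str, list] = {}
    for idx in order:
        if len(planted) == config.n_loci:
            break
        gene = ann.iloc[idx]
        offset = int(rng.integers(-half // 2, half // 2 + 1))
        pos = max(1, int(gene["tss"]) + offset)
        # loci windows are kept disjoint so each window holds exactly one
        # planted gene (no cross-locus signal leakage)
        if any(abs(pos - q) < window_bp for q in placed_by_chrom.get(gene["chrom"], [])):
            continue
        same = ann[ann["chrom"] == gene["chrom"]]
        n_cand = int(((same["start"] <= pos + half) & (same["end"] >= pos - half)).sum())
        if n_cand < 2:
            continue
        # the planted gene must itself be a candidate of its window
        if not (gene["start"] <= pos + half and gene["end"] >= pos - half):
            continue
        locus_i = len(planted)
        snp_id = f"rs{locus_i:04d}"
        snp_rows.append({"snp_id": snp_id, "chrom": gene["chrom"], "pos": pos})
        truth_map[snp_id] = gene["gene_id"]
        placed_by_chrom.setdefault(gene["chrom"], []).append(pos)
        planted.append(idx)
    if len(planted) < config.n_loci:
        raise GenerationError(
            f"annotation too sparse: placed {len(planted)} of {config.n_loci} loci"
        )
    index_snps = pd.DataFrame(snp_rows)

    # weighted network: dense module on planted genes, sparse background
    genes = ann["gene_id"].to_numpy()
    planted_set = set(truth_map.values())
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    in_module = np.isin(genes[iu], list(planted_set)) & np.isin(genes[ju], list(planted_set))
    p_edge = np.where(in_module, config.module_edge_prob, config.background_edge_prob)
    keep = rng.random(len(iu)) < p_edge
    weights = rng.uniform(0.5, 1.5, size=int(keep.sum()))
    for a, b, w in zip(genes[iu[keep]], genes[ju[keep]], weights):
        graph.add_edge(a, b, weight=float(w))

    # disjoint marker sets; first cell type carries the planted genes
    non_planted = [g for g in genes if g not in planted_set]
    rng.shuffle(non_planted)
    markers: Dict[str, Set[str]] = {}
    pool = iter(non_planted)
    planted_sorted = sorted(planted_set)
    for t in range(config.n_cell_types):
        name = f"CT{t + 1}"
        if t == 0:
            chosen = list(planted_sorted[: config.markers_per_type])
            while len(chosen) < config.markers_per_type:
                chosen.append(next(pool))
        else:
            chosen = list(itertools.islice(pool, config.markers_per_type))
            if len(chosen) < config.markers_per_type:
                raise GenerationError("not enough genes for disjoint marker sets")
        markers[name] = set(chosen)

    truth = TruthSet(
        planted_gene_by_locus=truth_map,
        theta_mr=config.theta_mr,
        marker_genes_by_cell_type=markers,
    )
    return index_snps, truth, graph


def _planted_pvalues(rng: np.random.Generator, n: int, effect_strength: float) -> np.ndarray:
    # Beta(1/s, 1): Uniform at s=1, concentrates at 0 as s grows
    return rng.beta(1.0 / effect_strength, 1.0, size=n)


def generate_evidence(
    config: SimulationConfig, candidates: pd.DataFrame, truth: TruthSet
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate regulatory features, DE p-values, and CpG methylation records.

    Returns (feature table, DE table, CpG table).  Non-planted genes get
    Uniform(0,1) p-values and standard-normal feature scores; planted genes
    get Beta(1/effect_strength, 1) p-values, feature scores shifted to the
    matching normal quantile, and sign-consistent CpG fold changes (so the
    Stouffer combination does not cancel the planted methylation signal).
    The distance-to-TSS feature is taken from the candidate table (minimum
    over loci for genes under several windows).
    """
    if candidates is None or len(candidates) == 0:
        raise GenerationError("candidate table is empty")
    rng = _rng(config, _STREAM_EVIDENCE)
    genes = np.sort(candidates["gene_id"].unique())
    is_planted = np.isin(genes, list(truth.planted_genes))
    n = len(genes)
    s = config.effect_strength

    def signal_scores(size: int) -> np.ndarray:
        # normal quantile matching a Beta(1/s, 1) upper-tail p-value;
        # Phi^-1(1 - p) = -Phi^-1(p), stable for very small p
        p = np.clip(_planted_pvalues(rng, size, s), 1e-300, 1.0)
        return -special.ndtri(p)

    fantom5 = rng.normal(size=n)
    hic = rng.normal(size=n)
    k_planted = int(is_planted.sum())
    fantom5[is_planted] = signal_scores(k_planted)
    hic[is_planted] = signal_scores(k_planted)
    dist = candidates.groupby("gene_id")["tss_distance"].min()
    features = pd.DataFrame(
        {
            "gene_id": genes,
            "fantom5": fantom5,
            "hic": hic,
            "dist_tss": dist.loc[genes].to_numpy(dtype=float),
        }
    )

    p_de = rng.uniform(size=n)
    p_de[is_planted] = _planted_pvalues(rng, k_planted, s)
    de = pd.DataFrame({"gene_id": genes, "p": p_de})

    lo, hi = config.cpgs_per_gene
    cpg_rows = []
    cpg_i = 0
    for g, pl in zip(genes, is_planted):
        k = int(rng.integers(lo, hi + 1))
        if pl:
            p = _planted_pvalues(rng, k, s)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * (0.5 + np.abs(rng.normal(size=k)))
        else:
            p = rng.uniform(size=k)
            lfc = rng.normal(size=k)
        for pj, fj in zip(p, lfc):
            cpg_rows.append(
                {"cpg_id": f"cg{cpg_i:07d}", "gene_id": g, "p": float(pj), "log2fc": float(fj)}
            )
            cpg_i += 1
    cpg = pd.DataFrame(cpg_rows)
    return features, de, cpg


def generate_mr_data(
    config: SimulationConfig,
    truth: TruthSet,
    genes: Optional[Sequence[str]] = None,
    theta: Optional[float] = None,
    tissue: str = "tissue_1",
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-gene cis-eQTL instruments, outcome GWAS effects, and LD.

    For each gene, ``n_instruments`` SNPs get exposure effects drawn away
    from zero (|beta_exp| in [0.1, 0.5]) with small standard errors so they
    pass the p < 1e-4 instrument filter, and outcome effects
    beta_out = theta * beta_exp + mr_noise_scale * se_out * N(0, 1).
    The LD matrix is block-diagonal per gene, AR(1) in r squared to r^2
    (positive semi-definite by construction).  Alleles are non-palindromic.
    """
    if config.n_instruments < 1:
        raise GenerationError("n_instruments must be >= 1")
    rng = _rng(config, _STREAM_MR)
    if genes is None:
        genes = sorted(truth.planted_genes)
    if theta is None:
        theta = truth.theta_mr

    m = config.n_instruments
    eqtl_rows, out_rows = [], []
    blocks = []
    snp_ids_all = []
    for gi, g in enumerate(genes):
        base = 1_000_000 * (gi + 1)
        betas = rng.uniform(0.1, 0.5, size=m) * rng.choice([-1.0, 1.0], size=m)
        # eQTL z-scores drawn in [6, 15]: every instrument passes p < 1e-4
        se_exp = np.abs(betas) / rng.uniform(6.0, 15.0, size=m)
        se_out = rng.uniform(0.02, 0.05, size=m)
        beta_out = theta * betas + config.mr_noise_scale * se_out * rng.normal(size=m)
        eaf = rng.uniform(0.05, 0.95, size=m)
        allele_idx = rng.integers(0, len(_NON_PALINDROMIC_ALLELE_PAIRS), size=m)
        snp_ids = [f"snp_{g}_{j}" for j in range(m)]
        snp_ids_all.extend(snp_ids)
        for j in range(m):
            z = betas[j] / se_exp[j]
            ea, oa = _NON_PALINDROMIC_ALLELE_PAIRS[allele_idx[j]]
            eqtl_rows.append(
                {
                    "gene_id": g,
                    "tissue": tissue,
                    "snp_id": snp_ids[j],
                    "pos": base + 50_000 * j,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": float(eaf[j]),
                    "beta_exp": float(betas[j]),
                    "se_exp": float(se_exp[j]),
                    "p_exp": float(2.0 * special.ndtr(-abs(z))),
                }
            )
            out_rows.append(
                {
                    "snp_id": snp_ids[j],
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": float(eaf[j]),
                    "beta_out": float(beta_out[j]),
                    "se_out": float(se_out[j]),
                }
            )
        r = config.ld_adjacent_r
        block = (r ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))) ** 2
        blocks.append(block)

    n_all = len(snp_ids_all)
    ld = np.zeros((n_all, n_all))
    off = 0
    for block in blocks:
        k = block.shape[0]
        ld[off : off + k, off : off + k] = block
        off += k
    ld_df = pd.DataFrame(ld, index=snp_ids_all, columns=snp_ids_all)
    return pd.DataFrame(eqtl_rows), pd.DataFrame(out_rows), ld_df


def generate_sc_counts(
    config: SimulationConfig,
    truth: TruthSet,
    gene_ids: Optional[Iterable[str]] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Simulate a labeled negative-binomial single-cell count matrix.

    Marker genes have their mean multiplied by 2**marker_log2fc in their own
    cell type only.  Returns (counts: genes x cells DataFrame, labels: Series
    of cell type per cell).
    """
    if config.n_cell_types < 2:
        raise GenerationError("n_cell_types must be >= 2")
    rng = _rng(config, _STREAM_SC)
    if gene_ids is None:
        gene_ids = generate_genome(config)["gene_id"]
    genes = np.asarray(sorted(gene_ids))
    n_genes = len(genes)
    cell_types = [f"CT{t + 1}" for t in range(config.n_cell_types)]

    base_mean = rng.lognormal(mean=-0.5, sigma=1.2, size=n_genes)
    fc = 2.0 ** config.marker_log2fc
    disp = config.nb_dispersion

    cols = {}
    labels = {}
    cell_i = 0
    for ct in cell_types:
        mu = base_mean.copy()
        marker_mask = np.isin(genes, list(truth.marker_genes_by_cell_type.get(ct, set())))
        mu[marker_mask] *= fc
        for _ in range(config.n_cells_per_type):
            cell = f"cell_{cell_i:05d}"
            if disp > 0:
                size = 1.0 / disp
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            cols[cell] = counts
            labels[cell] = ct
            cell_i += 1
    counts_df = pd.DataFrame(cols, index=genes)
    counts_df.index.name = "gene_id"
    labels_s = pd.Series(labels, name="cell_type")
    labels_s.index.name = "cell_id"
    return counts_df, labels_s
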