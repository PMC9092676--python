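"""Pipeline orchestration: simulate -> prioritize -> mr -> csea.

Each stage reads and writes the TSV/BED/MTX dialects defined in
:mod:`prgene.io`; ``run_all`` chains the four stages and writes a run
manifest (config, seeds, output checksums, row counts, convergence flags)
as the final artifact.  All randomness flows from the configured seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import __version__
from .candidates import extract_candidates
from .config import ConfigurationError, SimulationConfig
from .csea import build_specificity_panels, cell_type_t_stats, enrich, filter_genes
from .evidence import build_evidence
from .gibbs import GibbsSampler, select_prgenes
from .io import (
    network_to_edges,
    read_bed_annotation,
    read_counts_mtx,
    read_ld_matrix,
    read_table,
    sha256_of,
    write_counts_mtx,
    write_json,
    write_ld_matrix,
    write_table,
)
from .methylation import score_genes
from .mr import run_mr
from .network import network_from_edges
from .simulate import (
    generate_evidence,
    generate_genome,
    generate_loci_and_truth,
    generate_mr_data,
    generate_sc_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunables of the non-simulation stages (config-file sections)."""

    window_bp: int = 2_000_000
    restart_prob: float = 0.5
    prior_epsilon: Optional[float] = None
    threshold: float = 0.01
    check_every: int = 100
    burn_in: int = 500
    max_sweeps: int = 20_000
    mr_p_threshold: float = 1e-4
    mr_r2_threshold: float = 0.001
    mr_window_bp: int = 10_000_000
    csea_zero_fraction: float = 0.95
    csea_top_fraction: float = 0.05


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(raw.get("simulation", {}))
        known = set(PipelineParams.__dataclass_fields__)
        flat = {}
        for section in ("prioritize", "mr", "csea"):
            flat.update(raw.get(section, {}) or {})
        unknown = set(flat) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline parameter(s): {sorted(unknown)}")
        params = PipelineParams(**flat)
        if seed is None and "seed" in raw:
            seed = int(raw["seed"])
        if seed is not None:
            sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": int(seed)})
        return cls(simulation=sim, params=params)


def simulate_stage(config: SimulationConfig, outdir) -> Dict[str, int]:
    """Generate and write every pipeline input; returns per-table row counts."""
    outdir = Path(outdir)
    ann = generate_genome(config)
    snps, truth, graph = generate_loci_and_truth(config, ann)
    cand = extract_candidates(snps, ann)
    features, de, cpg = generate_evidence(config, cand, truth)
    eqtl, outcome, ld = generate_mr_data(config, truth)
    counts, labels = generate_sc_counts(config, truth, ann["gene_id"])

    write_table(ann, outdir / "annotation.tsv", schema="annotation")
    write_table(snps, outdir / "index_snps.tsv", schema="index_snps")
    edges = network_to_edges(graph)
    write_table(edges, outdir / "network.tsv", schema="network")
    write_table(features, outdir / "features.tsv", schema="features")
    write_table(de, outdir / "de.tsv", schema="de")
    write_table(cpg, outdir / "cpg.tsv", schema="cpg")
    write_table(eqtl, outdir / "eqtl.tsv", schema="eqtl")
    write_table(outcome, outdir / "outcome.tsv", schema="outcome")
    write_ld_matrix(ld, outdir / "ld_matrix.tsv")
    write_counts_mtx(counts, labels, outdir / "sc")
    write_json(
        {
            "synthetic": True,
            "planted_gene_by_locus": truth.planted_gene_by_locus,
            "theta_mr": truth.theta_mr,
            "marker_genes_by_cell_type": {k: sorted(v) for k, v in truth.marker_genes_by_cell_type.items()},
        },
        outdir / "truth.json",
    )
    return {
        "annotation": len(ann), "index_snps": len(snps), "network_edges": len(edges),
        "features": len(features), "de": len(de), "cpg": len(cpg),
        "eqtl": len(eqtl), "outcome": len(outcome), "sc_genes": len(counts),
        "sc_cells": counts.shape[1],
    }


def prioritize_stage(indir, outdir, seed: int, params: PipelineParams) -> Dict[str, object]:
    """Candidates -> methylation scores -> evidence -> Gibbs posterior."""
    indir, outdir = Path(indir), Path(outdir)
    snps = read_table(indir / "index_snps.tsv", schema="index_snps")
    bed = indir / "annotation.bed"
    if bed.exists():
        ann = read_bed_annotation(bed)
    else:
        ann = read_table(indir / "annotation.tsv", schema="annotation")
    features = read_table(indir / "features.tsv", schema="features")
    de = read_table(indir / "de.tsv", schema="de")
    cpg = read_table(indir / "cpg.tsv", schema="cpg")
    edges = read_table(indir / "network.tsv", schema="network")

    cand = extract_candidates(snps, ann, window_bp=params.window_bp)
    write_table(cand, outdir / "candidates.tsv", schema="candidates")
    methyl = score_genes(cpg)
    write_table(methyl, outdir / "methyl_scores.tsv", schema="methyl_scores")
    evidence = build_evidence(features, de, methyl)
    write_table(evidence, outdir / "evidence.tsv")

    graph = network_from_edges(edges)
    sampler = GibbsSampler(
        cand, evidence, graph,
        restart_prob=params.restart_prob, epsilon=params.prior_epsilon, seed=seed,
    )
    posterior = sampler.run(
        threshold=params.threshold, check_every=params.check_every,
        burn_in=params.burn_in, max_sweeps=params.max_sweeps,
    )
    write_table(posterior, outdir / "posterior.tsv", schema="posterior")
    prg = select_prgenes(posterior)
    write_table(prg, outdir / "prgenes.tsv", schema="prgenes")
    return {
        "candidates": len(cand), "evidence": len(evidence), "posterior": len(posterior),
        "prgenes": len(prg), "converged": bool(posterior["converged"].all()),
        "sweeps": int(posterior["sweeps"].iloc[0]),
    }


def mr_stage(indir, outdir, params: PipelineParams) -> Dict[str, int]:
    """Two-sample MR on the simulated eQTL instruments and outcome GWAS."""
    indir, outdir = Path(indir), Path(outdir)
    eqtl = read_table(indir / "eqtl.tsv", schema="eqtl")
    outcome = read_table(indir / "outcome.tsv", schema="outcome")
    ld = read_ld_matrix(indir / "ld_matrix.tsv")
    res = run_mr(
        eqtl, outcome, ld,
        p_threshold=params.mr_p_threshold,
        r2_threshold=params.mr_r2_threshold,
        window_bp=params.mr_window_bp,
    )
    write_table(res, outdir / "mr_results.tsv", schema="mr_results")
    return {"mr_results": len(res), "mr_fdr_significant": int((res["fdr"] < 0.05).sum())}


def csea_stage(indir, outdir, params: PipelineParams) -> Dict[str, int]:
    """Cell-type-specificity enrichment of the prioritized gene set."""
    indir, outdir = Path(indir), Path(outdir)
    counts, labels = read_counts_mtx(indir / "sc")
    prg = read_table(outdir / "prgenes.tsv", schema="prgenes")
    filtered = filter_genes(counts, params.csea_zero_fraction)
    t = cell_type_t_stats(filtered, labels)
    panel = build_specificity_panels(t, params.csea_top_fraction)
    result = enrich(prg["gene_id"], panel)
    write_table(result, outdir / "enrichment.tsv", schema="enrichment")
    panel_rows = [
        {"cell_type": ct, "gene_id": g}
        for ct in sorted(panel.per_cell_type)
        for g in sorted(panel.per_cell_type[ct])
    ]
    import pandas as pd

    write_table(pd.DataFrame(panel_rows), outdir / "panels.tsv")
    return {"enrichment_rows": len(result), "panel_genes": len(panel_rows)}


MANIFEST_FILES = [
    "annotation.tsv", "index_snps.tsv", "network.tsv", "features.tsv", "de.tsv",
    "cpg.tsv", "eqtl.tsv", "outcome.tsv", "ld_matrix.tsv", "truth.json",
    "sc/counts.mtx", "sc/genes.tsv", "sc/cells.tsv",
    "candidates.tsv", "methyl_scores.tsv", "evidence.tsv", "posterior.tsv",
    "prgenes.tsv", "mr_results.tsv", "enrichment.tsv", "panels.tsv",
]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all four stages and write the run manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, object] = {}
    logger.info("[simulate] generating synthetic inputs")
    counts.update(simulate_stage(config.simulation, outdir))
    logger.info("[prioritize] running candidate extraction, evidence, Gibbs sampler")
    counts.update(prioritize_stage(outdir, outdir, config.simulation.seed, config.params))
    logger.info("[mr] running two-sample Mendelian randomization")
    counts.update(mr_stage(outdir, outdir, config.params))
    logger.info("[csea] running cell-type-specificity enrichment")
    counts.update(csea_stage(outdir, outdir, config.params))

    manifest = {
        "tool_version": __version__,
        "seed": config.simulation.seed,
        "config": {
            "simulation": config.simulation.to_dict(),
            "params": {k: getattr(config.params, k) for k in PipelineParams.__dataclass_fields__},
        },
        "row_counts": counts,
        "checksums": {
            name: sha256_of(outdir / name) for name in MANIFEST_FILES if (outdir / name).exists()
        },
    }
    write_json(manifest, outdir / "manifest.json")
    logger.info("[done] manifest written to %s", outdir / "manifest.json")
    return manifest
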