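"""Simulation configuration.

A single dataclass drives every synthetic generator so that one seed fixes
the whole pipeline's inputs byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-omics study.

    The defaults describe the reference study conditions used throughout the
    tests: 20 GWAS loci with roughly 30 candidate genes in each 2-Mb window,
    planted risk genes whose omics p-values are drawn Beta(1/effect_strength, 1),
    a gene network in which planted genes form a dense module, a planted
    causal effect of expression on outcome for Mendelian randomization, and a
    labeled negative-binomial single-cell count matrix with marker genes.

    Parameters
    ----------
    seed
        Root seed; every generator derives an independent child stream from
        it, so a fixed seed reproduces all outputs exactly.
    n_chrom, n_genes
        Genome shape. Genes are laid down sequentially per chromosome with
        spacing calibrated so a 2-Mb window holds about
        ``candidates_per_locus_target`` genes.
    n_loci
        Number of index SNPs / risk loci; one risk gene is planted per locus.
    n_features
        Number of continuous regulatory features (FANTOM5-like linkage,
        Hi-C contact, distance to TSS by default).
    cpgs_per_gene
        Inclusive (low, high) range for the number of promoter CpGs per gene.
    effect_strength
        Concentration of planted p-values: planted genes draw
        p ~ Beta(1/effect_strength, 1).  1 is the null (Uniform); larger
        values push planted p-values toward 0.
    module_edge_prob, background_edge_prob
        Edge probabilities within the planted-gene module and elsewhere.
    theta_mr
        True causal effect of exposure (expression) on outcome used by the
        MR data generator.
    n_instruments
        cis-eQTL instruments simulated per gene.
    mr_noise_scale
        Multiplier on the outcome-noise standard deviation (0 gives exact
        per-SNP ratios equal to ``theta_mr``).
    ld_adjacent_r
        AR(1) correlation between adjacent instruments; the LD matrix is the
        elementwise square (r^2) of the AR(1) correlation matrix.
    n_cell_types, n_cells_per_type, markers_per_type, marker_log2fc
        Single-cell design: cell types, cells per type, disjoint marker
        genes per type, and the log2 fold change of a marker in its own type.
    nb_dispersion
        Negative-binomial dispersion (Var = mu + dispersion * mu^2).
    """

    seed: int = 0
    n_chrom: int = 8
    n_genes: int = 1200
    n_loci: int = 20
    candidates_per_locus_target: int = 30
    n_features: int = 3
    cpgs_per_gene: Tuple[int, int] = (2, 8)
    effect_strength: float = 10.0
    module_edge_prob: float = 0.3
    background_edge_prob: float = 0.01
    theta_mr: float = 0.5
    n_instruments: int = 10
    mr_noise_scale: float = 1.0
    ld_adjacent_r: float = 0.02
    n_cell_types: int = 5
    n_cells_per_type: int = 200
    markers_per_type: int = 20
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.5

    def __post_init__(self) -> None:
        self.cpgs_per_gene = tuple(self.cpgs_per_gene)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_chrom": self.n_chrom,
            "n_genes": self.n_genes,
            "n_loci": self.n_loci,
            "candidates_per_locus_target": self.candidates_per_locus_target,
            "n_features": self.n_features,
            "n_instruments": self.n_instruments,
            "n_cell_types": self.n_cell_types,
            "n_cells_per_type": self.n_cells_per_type,
            "markers_per_type": self.markers_per_type,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        for name, value in (
            ("module_edge_prob", self.module_edge_prob),
            ("background_edge_prob", self.background_edge_prob),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.effect_strength <= 0:
            raise ConfigurationError("effect_strength must be positive")
        lo, hi = self.cpgs_per_gene
        if lo < 1 or hi < lo:
            raise ConfigurationError("cpgs_per_gene must be a range (low, high) with 1 <= low <= high")
        if self.mr_noise_scale < 0:
            raise ConfigurationError("mr_noise_scale must be >= 0")
        if not -1.0 < self.ld_adjacent_r < 1.0:
            raise ConfigurationError("ld_adjacent_r must lie in (-1, 1)")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if int(self.seed) != self.seed:
            raise ConfigurationError("seed must be an integer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cpgs_per_gene"] = list(self.cpgs_per_gene)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
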