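import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from prgene.candidates import extract_candidates
from prgene.config import SimulationConfig
from prgene.simulate import generate_genome, generate_loci_and_truth

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def small_config():
    """Compact study: 4 loci, ~10 candidates per window, tiny single-cell design."""
    return SimulationConfig(
        seed=7,
        n_chrom=2,
        n_genes=80,
        n_loci=4,
        candidates_per_locus_target=10,
        n_cell_types=3,
        n_cells_per_type=30,
        markers_per_type=5,
        n_instruments=5,
    )


@pytest.fixture
def small_world(small_config):
    """Genome, index SNPs, truth, network, and candidates for the small study."""
    ann = generate_genome(small_config)
    snps, truth, graph = generate_loci_and_truth(small_config, ann)
    cand = extract_candidates(snps, ann)
    return {"config": small_config, "annotation": ann, "snps": snps, "truth": truth,
            "network": graph, "candidates": cand}


@pytest.fixture
def toy_annotation():
    rows = [
        ("GA", "chr1", 4_150_000, 4_210_000, "+"),
        ("GB", "chr1", 5_100_000, 5_150_000, "-"),
        ("GC", "chr1", 6_100_000, 6_200_000, "+"),
        ("GD", "chr2", 5_000_000, 5_050_000, "+"),
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    return df
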