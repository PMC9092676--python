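"""Synthetic-data generators: determinism, planted signal, ground-truth shape."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from prgene.candidates import extract_candidates
from prgene.config import ConfigurationError, SimulationConfig
from prgene.simulate import (
    generate_evidence,
    generate_genome,
    generate_loci_and_truth,
    generate_mr_data,
    generate_sc_counts,
)


def test_genome_is_deterministic_and_sized(small_config):
    a = generate_genome(small_config)
    b = generate_genome(small_config)
    pdt.assert_frame_equal(a, b)
    assert len(a) == small_config.n_genes
    assert a["gene_id"].is_unique


def test_tss_lies_within_gene_body(small_config):
    ann = generate_genome(small_config)
    assert ((ann["tss"] >= ann["start"]) & (ann["tss"] <= ann["end"])).all()
    plus = ann["strand"] == "+"
    assert (ann.loc[plus, "tss"] == ann.loc[plus, "start"]).all()
    assert (ann.loc[~plus, "tss"] == ann.loc[~plus, "end"]).all()


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(module_edge_prob=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(effect_strength=0)


def test_planted_genes_are_candidates_of_their_loci(small_world):
    cand = small_world["candidates"]
    for locus, gene in small_world["truth"].planted_gene_by_locus.items():
        sub = cand[cand["locus_id"] == locus]
        assert len(sub) >= 2
        assert gene in set(sub["gene_id"])


def test_full_module_edge_prob_gives_planted_clique(small_config):
    cfg = SimulationConfig(**{**small_config.to_dict(), "module_edge_prob": 1.0,
                              "background_edge_prob": 0.0, "n_loci": 5})
    ann = generate_genome(cfg)
    _, truth, graph = generate_loci_and_truth(cfg, ann)
    planted = sorted(truth.planted_genes)
    assert len(planted) == 5
    for i, a in enumerate(planted):
        for b in planted[i + 1:]:
            assert graph.has_edge(a, b)
    # background prob 0: every edge lies inside the planted module
    for a, b in graph.edges:
        assert a in truth.planted_genes and b in truth.planted_genes


def test_planted_genes_have_higher_degree_when_module_denser(small_config):
    diffs = []
    for seed in range(50):
        cfg = SimulationConfig(**{**small_config.to_dict(), "seed": seed})
        ann = generate_genome(cfg)
        _, truth, graph = generate_loci_and_truth(cfg, ann)
        deg = dict(graph.degree)
        planted = truth.planted_genes
        d_p = np.mean([deg[g] for g in planted])
        d_b = np.mean([deg[g] for g in graph.nodes if g not in planted])
        diffs.append(d_p - d_b)
    assert np.mean(diffs) > 0


def test_marker_sets_are_disjoint(small_world):
    sets = list(small_world["truth"].marker_genes_by_cell_type.values())
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            assert not (a & b)


def test_effect_strength_one_matches_null(small_world):
    cfg = SimulationConfig(**{**small_world["config"].to_dict(), "effect_strength": 1.0})
    feats, de, cpg = generate_evidence(cfg, small_world["candidates"], small_world["truth"])
    planted = small_world["truth"].planted_genes
    p_pl = de.loc[de["gene_id"].isin(planted), "p"]
    # Beta(1,1) = Uniform: planted p-values indistinguishable from null
    from scipy import stats
    assert stats.kstest(p_pl, "uniform").pvalue > 0.01


def test_planted_pvalues_stochastically_smaller_over_seeds(small_world):
    means_planted, means_null = [], []
    for seed in range(20):
        cfg = SimulationConfig(**{**small_world["config"].to_dict(), "seed": seed,
                                  "effect_strength": 10.0})
        ann = generate_genome(cfg)
        snps, truth, _ = generate_loci_and_truth(cfg, ann)
        cand = extract_candidates(snps, ann)
        _, de, _ = generate_evidence(cfg, cand, truth)
        mask = de["gene_id"].isin(truth.planted_genes)
        means_planted.append(de.loc[mask, "p"].mean())
        means_null.append(de.loc[~mask, "p"].mean())
    assert np.mean(means_planted) < np.mean(means_null)


def test_planted_signal_monotone_in_effect_strength(small_world):
    """Raising effect_strength never raises the expected planted p-value."""
    grand_means = []
    for strength in (1.0, 5.0, 25.0):
        means = []
        for seed in range(20):
            cfg = SimulationConfig(**{**small_world["config"].to_dict(), "seed": seed,
                                      "effect_strength": strength})
            ann = generate_genome(cfg)
            snps, truth, _ = generate_loci_and_truth(cfg, ann)
            cand = extract_candidates(snps, ann)
            _, de, _ = generate_evidence(cfg, cand, truth)
            means.append(de.loc[de["gene_id"].isin(truth.planted_genes), "p"].mean())
        grand_means.append(np.mean(means))
    assert grand_means[0] > grand_means[1] > grand_means[2]


def test_cpg_counts_respect_configured_range(small_world):
    cfg = small_world["config"]
    _, _, cpg = generate_evidence(cfg, small_world["candidates"], small_world["truth"])
    k = cpg.groupby("gene_id").size()
    lo, hi = cfg.cpgs_per_gene
    assert k.between(lo, hi).all()


def test_mr_data_noiseless_ratios_equal_theta(small_config):
    cfg = SimulationConfig(**{**small_config.to_dict(), "mr_noise_scale": 0.0, "theta_mr": 0.5})
    truth_genes = ["GX", "GY"]
    from prgene.simulate import TruthSet
    truth = TruthSet({"l1": "GX", "l2": "GY"}, 0.5, {})
    eqtl, outcome, ld = generate_mr_data(cfg, truth, genes=truth_genes)
    merged = eqtl.merge(outcome, on="snp_id")
    np.testing.assert_allclose(merged["beta_out"] / merged["beta_exp"], 0.5)
    # LD matrix: unit diagonal, symmetric, PSD
    L = ld.to_numpy()
    np.testing.assert_allclose(np.diag(L), 1.0)
    np.testing.assert_allclose(L, L.T)
    assert np.linalg.eigvalsh(L).min() > -1e-10


def test_mr_instruments_pass_default_filter(small_world):
    eqtl, _, _ = generate_mr_data(small_world["config"], small_world["truth"])
    assert (eqtl["p_exp"] < 1e-4).all()
    assert (eqtl["beta_exp"] != 0).all()


def test_sc_counts_shape_and_marker_means(small_config):
    maxima = []
    for seed in range(10):
        cfg = SimulationConfig(**{**small_config.to_dict(), "seed": seed})
        ann = generate_genome(cfg)
        _, truth, _ = generate_loci_and_truth(cfg, ann)
        counts, labels = generate_sc_counts(cfg, truth, ann["gene_id"])
        assert counts.shape == (cfg.n_genes, cfg.n_cell_types * cfg.n_cells_per_type)
        assert len(labels) == counts.shape[1]
        for ct, markers in truth.marker_genes_by_cell_type.items():
            per_type = counts.T.groupby(labels).mean().T  # gene x type means
            for g in markers:
                maxima.append(per_type.loc[g].idxmax() == ct)
    assert np.mean(maxima) > 0.95


def test_sc_counts_deterministic(small_world):
    cfg, truth = small_world["config"], small_world["truth"]
    a, la = generate_sc_counts(cfg, truth, small_world["annotation"]["gene_id"])
    b, lb = generate_sc_counts(cfg, truth, small_world["annotation"]["gene_id"])
    pdt.assert_frame_equal(a, b)
    pdt.assert_series_equal(la, lb)
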