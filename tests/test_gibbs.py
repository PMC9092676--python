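"""Gibbs prioritizer: conditionals, convergence, oracle equivalence, recovery."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from prgene.gibbs import GibbsSampler, exact_stationary_oracle, select_prgenes


def _cand(mapping):
    rows = [
        {"locus_id": locus, "snp_id": locus, "gene_id": g}
        for locus, genes in mapping.items()
        for g in genes
    ]
    return pd.DataFrame(rows)


def _ev(log_bf):
    return pd.DataFrame({"gene_id": list(log_bf), "log_bf": list(log_bf.values())})


def test_init_state_argmax_and_tie_rule():
    cand = _cand({"L1": ["A", "B"], "L2": ["C", "D"]})
    ev = _ev({"A": 2.0, "B": 1.0, "C": 1.0, "D": 1.0})
    s = GibbsSampler(cand, ev, seed=0)
    assert s.selection == {"L1": "A", "L2": "C"}  # tie at L2 -> smallest id
    assert all((c == 0).all() for c in s.counts.values())
    s2 = GibbsSampler(cand, ev, seed=0)
    assert s2.selection == s.selection


def test_missing_evidence_locus_rejected():
    cand = _cand({"L1": ["A", "B"]})
    with pytest.raises(ValueError):
        GibbsSampler(cand, _ev({"X": 1.0}), seed=0)


def test_single_locus_conditional_matches_bf_ratio():
    cand = _cand({"L1": ["A", "B"]})
    ev = _ev({"A": np.log(3.0), "B": 0.0})
    s = GibbsSampler(cand, ev, network=None, seed=0)
    probs = s.conditional_probs("L1", {})
    np.testing.assert_allclose(probs, [0.75, 0.25], atol=1e-12)


def test_empty_network_conditional_is_evidence_only():
    g = nx.Graph()  # no edges: priors must be uniform
    cand = _cand({"L1": ["A", "B", "C"]})
    ev = _ev({"A": 1.0, "B": 2.0, "C": 3.0})
    s = GibbsSampler(cand, ev, network=g, seed=0)
    probs = s.conditional_probs("L1", {})
    w = np.exp([1.0, 2.0, 3.0])
    np.testing.assert_allclose(probs, w / w.sum(), atol=1e-12)


def test_single_locus_long_run_frequencies():
    cand = _cand({"L1": ["A", "B"]})
    ev = _ev({"A": np.log(3.0), "B": 0.0})
    s = GibbsSampler(cand, ev, seed=1)
    post = s.run_fixed(50_000, burn_in=100)
    fA = post.set_index("gene_id").loc["A", "frequency"]
    assert fA == pytest.approx(0.75, abs=0.01)


def test_oracle_single_locus_matches_analytic_conditional():
    cand = _cand({"L1": ["A", "B"]})
    ev = _ev({"A": np.log(3.0), "B": 0.0})
    marg = exact_stationary_oracle(cand, ev)
    assert marg["L1"]["A"] == pytest.approx(0.75, abs=1e-10)
    assert sum(marg["L1"].values()) == pytest.approx(1.0, abs=1e-10)


def test_oracle_factorizes_without_network():
    """With no network the loci are independent: joint marginals are per-locus posteriors."""
    cand = _cand({"L1": ["A", "B"], "L2": ["C", "D"]})
    ev = _ev({"A": np.log(3.0), "B": 0.0, "C": np.log(4.0), "D": 0.0})
    marg = exact_stationary_oracle(cand, ev)
    assert marg["L1"]["A"] == pytest.approx(0.75, abs=1e-10)
    assert marg["L2"]["C"] == pytest.approx(0.8, abs=1e-10)


def test_oracle_refuses_large_instances():
    cand = _cand({f"L{i}": [f"G{i}_{j}" for j in range(9)] for i in range(5)})
    ev = _ev({f"G{i}_{j}": 0.0 for i in range(5) for j in range(9)})
    with pytest.raises(ValueError, match="oracle limit"):
        exact_stationary_oracle(cand, ev)


def _network_instance():
    """3 loci x 3 candidates with a nontrivial network coupling the loci."""
    cand = _cand({
        "L1": ["A1", "A2", "A3"],
        "L2": ["B1", "B2", "B3"],
        "L3": ["C1", "C2", "C3"],
    })
    rng = np.random.default_rng(42)
    ev = _ev({g: float(rng.uniform(0, 1.5)) for g in cand["gene_id"]})
    g = nx.Graph()
    g.add_nodes_from(cand["gene_id"])
    module = [("A1", "B1"), ("B1", "C1"), ("A1", "C1"), ("A2", "B3"), ("C2", "B2")]
    for a, b in module:
        g.add_edge(a, b, weight=1.0)
    return cand, ev, g


def test_gibbs_frequencies_match_exact_stationary_marginals():
    cand, ev, g = _network_instance()
    marg = exact_stationary_oracle(cand, ev, g, restart_prob=0.5)
    s = GibbsSampler(cand, ev, g, restart_prob=0.5, seed=3)
    post = s.run_fixed(20_000, burn_in=500)
    for locus, sub in post.groupby("locus_id"):
        for row in sub.itertuples(index=False):
            assert row.frequency == pytest.approx(marg[locus][row.gene_id], abs=0.02)


def test_run_is_reproducible_under_fixed_seed():
    cand, ev, g = _network_instance()
    a = GibbsSampler(cand, ev, g, seed=5).run()
    b = GibbsSampler(cand, ev, g, seed=5).run()
    pd.testing.assert_frame_equal(a, b)


def test_cross_seed_selection_agreement(small_world):
    """Independent chains select the same genes; frequencies agree within 0.05."""
    from prgene.evidence import build_evidence
    from prgene.methylation import score_genes
    from prgene.simulate import generate_evidence

    cfg, truth = small_world["config"], small_world["truth"]
    feats, de, cpg = generate_evidence(cfg, small_world["candidates"], truth)
    ev = build_evidence(feats, de, score_genes(cpg))
    runs = []
    for seed in (11, 12):
        s = GibbsSampler(small_world["candidates"], ev, small_world["network"], seed=seed)
        runs.append(s.run(burn_in=200, max_sweeps=5_000))
    a, b = (r.set_index(["locus_id", "gene_id"]) for r in runs)
    sel_a = a[a["selected"]].index
    sel_b = b[b["selected"]].index
    assert set(sel_a) == set(sel_b)
    assert np.abs(a["frequency"] - b["frequency"]).max() < 0.05


def test_null_evidence_uniform_network_gives_uniform_frequencies():
    cand = _cand({"L1": ["A", "B", "C", "D"]})
    ev = _ev({g: 0.0 for g in "ABCD"})
    s = GibbsSampler(cand, ev, seed=9)
    post = s.run_fixed(20_000, burn_in=100)
    np.testing.assert_allclose(post["frequency"], 0.25, atol=0.02)


def test_convergence_criterion_and_flags():
    cand = _cand({"L1": ["A", "B"]})
    ev = _ev({"A": np.log(3.0), "B": 0.0})
    # an infinite threshold stops at the first check
    post = GibbsSampler(cand, ev, seed=0).run(threshold=np.inf, check_every=50, burn_in=10)
    assert post["converged"].all()
    assert post["sweeps"].iloc[0] == 50
    # a tiny max_sweeps cannot converge
    post2 = GibbsSampler(cand, ev, seed=0).run(threshold=1e-12, burn_in=10, max_sweeps=200)
    assert not post2["converged"].any()
    with pytest.raises(ValueError):
        GibbsSampler(cand, ev, seed=0).run(threshold=0.0)


def test_frequencies_per_locus_sum_to_one():
    cand, ev, g = _network_instance()
    post = GibbsSampler(cand, ev, g, seed=4).run(burn_in=100, max_sweeps=2_000)
    sums = post.groupby("locus_id")["frequency"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def test_select_prgenes_aggregates_multi_locus_genes():
    post = pd.DataFrame(
        {
            "locus_id": ["L1", "L1", "L2", "L2", "L3", "L3"],
            "snp_id": ["L1", "L1", "L2", "L2", "L3", "L3"],
            "gene_id": ["A", "B", "A", "C", "D", "E"],
            "frequency": [0.6, 0.4, 0.9, 0.1, 0.5, 0.5],
            "selected": [True, False, True, False, True, False],
            "converged": [True] * 6,
            "sweeps": [100] * 6,
            "seed": [0] * 6,
        }
    )
    out = select_prgenes(post).set_index("gene_id")
    assert out.loc["A", "n_loci"] == 2
    assert out.loc["A", "loci"] == "L1,L2"
    # frequency tie at L3 -> lexicographically smallest gene id
    assert "D" in out.index and "E" not in out.index
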