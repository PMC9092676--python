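"""Two-sample MR: instrument selection, clumping, harmonization, estimators, FDR."""

import numpy as np
import pandas as pd
import pytest

from prgene.config import SimulationConfig
from prgene.mr import (
    bh_adjust,
    harmonize,
    ivw,
    ld_clump,
    run_mr,
    select_instruments,
    wald_ratio,
)
from prgene.simulate import TruthSet, generate_mr_data


def _instr(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "snp_id", "pos", "p_exp"])


def test_instrument_threshold_is_strict():
    tbl = _instr([
        ("G", "t", "s1", 100, 2e-5),
        ("G", "t", "s2", 200, 2e-4),
        ("G", "t", "s3", 300, 1e-4),  # boundary: not strictly below
    ])
    kept = select_instruments(tbl, p_threshold=1e-4)
    assert set(kept["snp_id"]) == {"s1"}


def test_instrument_filter_matches_bruteforce():
    rng = np.random.default_rng(0)
    tbl = _instr([("G", "t", f"s{i}", i, float(p)) for i, p in enumerate(rng.uniform(0, 1e-3, 50))])
    kept = select_instruments(tbl)
    expected = {r.snp_id for r in tbl.itertuples() if r.p_exp < 1e-4}
    assert set(kept["snp_id"]) == expected


def _ld(snps, r2):
    n = len(snps)
    m = np.full((n, n), np.nan)
    np.fill_diagonal(m, 1.0)
    df = pd.DataFrame(m, index=snps, columns=snps)
    for (a, b), v in r2.items():
        df.loc[a, b] = df.loc[b, a] = v
    return df


def test_clump_removes_correlated_nearby_snp():
    instr = _instr([("G", "t", "s1", 1_000_000, 1e-8), ("G", "t", "s2", 2_000_000, 1e-6)])
    kept = ld_clump(instr, _ld(["s1", "s2"], {("s1", "s2"): 0.9}))
    assert list(kept["snp_id"]) == ["s1"]  # smaller p wins


def test_clump_keeps_low_r2_pair():
    instr = _instr([("G", "t", "s1", 1_000_000, 1e-8), ("G", "t", "s2", 2_000_000, 1e-6)])
    kept = ld_clump(instr, _ld(["s1", "s2"], {("s1", "s2"): 0.0005}))
    assert set(kept["snp_id"]) == {"s1", "s2"}  # r2 <= 0.001 boundary: kept


def test_clump_ignores_pairs_beyond_window():
    instr = _instr([("G", "t", "s1", 1_000_000, 1e-8), ("G", "t", "s2", 16_000_000, 1e-6)])
    kept = ld_clump(instr, _ld(["s1", "s2"], {("s1", "s2"): 0.9}))
    assert set(kept["snp_id"]) == {"s1", "s2"}  # 15 Mb apart: outside 10 Mb


def test_clump_missing_ld_treated_as_linked(caplog):
    instr = _instr([("G", "t", "s1", 1_000_000, 1e-8), ("G", "t", "s2", 2_000_000, 1e-6)])
    with caplog.at_level("WARNING"):
        kept = ld_clump(instr, _ld(["s1", "s2"], {}))
    assert list(kept["snp_id"]) == ["s1"]


def test_clump_output_never_violates_threshold_randomized():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(2, 12))
        snps = [f"s{i}" for i in range(n)]
        pos = rng.integers(1, 30_000_000, size=n)
        r = rng.uniform(-0.9, 0.9)
        r2 = (r ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))) ** 2
        ld = pd.DataFrame(r2, index=snps, columns=snps)
        instr = _instr([("G", "t", s, int(p), float(pe))
                        for s, p, pe in zip(snps, pos, rng.uniform(0, 1e-4, n))])
        kept = ld_clump(instr, ld)
        for i, a in kept.iterrows():
            for j, b in kept.iterrows():
                if i < j and abs(int(a["pos"]) - int(b["pos"])) <= 10_000_000:
                    assert ld.loc[a["snp_id"], b["snp_id"]] <= 0.001


def _merged(ea, oa, eao, oao, eaf=0.2, beta_out=0.25):
    return pd.DataFrame([{
        "snp_id": "s1", "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta_exp": 0.5, "se_exp": 0.05,
        "effect_allele_out": eao, "other_allele_out": oao,
        "beta_out": beta_out, "se_out": 0.1,
    }])


def test_harmonize_same_orientation_unchanged():
    out = harmonize(_merged("A", "G", "A", "G"))
    assert out["beta_out"].iloc[0] == 0.25


def test_harmonize_swapped_alleles_flip_sign():
    out = harmonize(_merged("A", "G", "G", "A"))
    assert out["beta_out"].iloc[0] == -0.25


def test_harmonize_drops_ambiguous_palindromic_snp():
    assert len(harmonize(_merged("A", "T", "A", "T", eaf=0.50))) == 0
    # palindromic but unambiguous frequency: kept
    assert len(harmonize(_merged("A", "T", "A", "T", eaf=0.10))) == 1


def test_harmonize_drops_incompatible_alleles(caplog):
    with caplog.at_level("WARNING"):
        out = harmonize(_merged("A", "G", "A", "C"))
    assert len(out) == 0


def test_wald_ratio_examples():
    est, se = wald_ratio(0.25, 0.1, 0.5)
    assert (est, se) == (pytest.approx(0.5), pytest.approx(0.2))
    assert wald_ratio(0.0, 0.1, 0.5)[0] == 0.0
    with pytest.raises(ZeroDivisionError):
        wald_ratio(0.25, 0.1, 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_wald_ratio_matches_delta_oracle(seed):
    rng = np.random.default_rng(seed)
    bo, so, bx = rng.normal(), abs(rng.normal()) + 0.01, rng.normal() + 2.0
    est, se = wald_ratio(bo, so, bx)
    assert est == pytest.approx(bo / bx)
    assert se == pytest.approx(so / abs(bx))


def test_ivw_identities():
    # two identical SNPs reduce to the common Wald ratio
    est, _ = ivw([0.5, 0.5], [0.25, 0.25], [0.1, 0.1])
    assert est == pytest.approx(0.5)
    # zero-noise synthetic: exact recovery of theta
    bx = np.array([0.2, -0.3, 0.4])
    est2, _ = ivw(bx, 0.5 * bx, [0.1, 0.2, 0.1])
    assert est2 == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(ValueError):
        ivw([0.5], [0.25], [0.1])


def test_ivw_matches_weighted_regression_through_origin():
    rng = np.random.default_rng(2)
    bx = rng.uniform(0.1, 0.5, 8)
    so = rng.uniform(0.05, 0.2, 8)
    by = 0.7 * bx + rng.normal(0, so)
    est, se = ivw(bx, by, so)
    w = 1 / so**2
    beta_hat = np.sum(w * bx * by) / np.sum(w * bx**2)
    assert est == pytest.approx(beta_hat)
    assert se == pytest.approx(1 / np.sqrt(np.sum(w * bx**2)))


def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def test_bh_examples_and_property():
    np.testing.assert_allclose(bh_adjust([1.0]), [1.0])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    rng = np.random.default_rng(3)
    for _ in range(200):
        p = rng.uniform(size=int(rng.integers(1, 25)))
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, _bh_bruteforce(p), atol=1e-12)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()


def test_run_mr_dispatch_and_sign_recovery():
    cfg = SimulationConfig(seed=5, n_instruments=6)
    genes = [f"G{i}" for i in range(40)]
    truth = TruthSet({}, 0.5, {})
    eqtl, outcome, ld = generate_mr_data(cfg, truth, genes=genes, theta=0.5)
    res = run_mr(eqtl, outcome, ld)
    assert len(res) == 40
    assert ((res["method"] == "wald_ratio") == (res["n_snps"] == 1)).all()
    assert (np.sign(res["estimate"]) == 1.0).mean() >= 0.95
    assert (res["fdr"] >= res["p"] - 1e-15).all()


def test_run_mr_single_instrument_uses_wald_ratio():
    cfg = SimulationConfig(seed=6, n_instruments=1, mr_noise_scale=0.0)
    eqtl, outcome, ld = generate_mr_data(cfg, TruthSet({}, 0.5, {}), genes=["G1"])
    res = run_mr(eqtl, outcome, ld)
    assert list(res["method"]) == ["wald_ratio"]
    assert res["estimate"].iloc[0] == pytest.approx(0.5)
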