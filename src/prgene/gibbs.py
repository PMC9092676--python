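"""Locus-wise Gibbs sampler for risk-gene prioritization.

Each GWAS locus contributes one risk gene; the joint assignment over loci is
sampled one locus at a time.  Conditional on the genes currently selected at
all other loci, the probability of candidate g at the current locus is

    P(g) ∝ prior(g) * BF(g)

where prior(g) is the RWR proximity of g to the other loci's selections
(normalized within the locus) and BF(g) = exp(log_bf(g)) is the
Fisher's-product evidence surrogate, stabilized by subtracting the locus
maximum of log_bf before exponentiation.  Sampling frequencies after
burn-in are the reported posterior probabilities; the run stops when the
sum of squared frequency differences between consecutive checks drops below
a preset threshold (0.01 by default).

A brute-force oracle (`exact_stationary_oracle`) builds the full
systematic-scan transition matrix over joint configurations and extracts
per-locus marginals from its stationary eigenvector, for instances with at
most a few thousand configurations.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .network import RWRSolver, default_epsilon, locus_prior

logger = logging.getLogger(__name__)


def _candidate_map(candidates: pd.DataFrame) -> Dict[str, List[str]]:
    """locus_id -> sorted candidate gene list."""
    return {
        locus: sorted(sub["gene_id"].unique())
        for locus, sub in candidates.groupby("locus_id", sort=True)
    }


class GibbsSampler:
    """Systematic-scan Gibbs sampler over per-locus candidate genes.

    Parameters
    ----------
    candidates
        CandidateTable frame with locus_id and gene_id columns.
    evidence
        EvidenceTable frame with gene_id and log_bf columns.
    network
        Weighted undirected gene graph, or None for uniform priors.
    restart_prob
        RWR restart probability (default 0.5).
    epsilon
        Prior floor; defaults to 1e-6 / |network nodes|.
    seed
        RNG seed; the run is fully reproducible given the seed.
    """

    def __init__(
        self,
        candidates: pd.DataFrame,
        evidence: pd.DataFrame,
        network: Optional[nx.Graph] = None,
        restart_prob: float = 0.5,
        epsilon: Optional[float] = None,
        seed: int = 0,
        random_scan: bool = False,
    ):
        self.candidates = _candidate_map(candidates)
        if not self.candidates:
            raise ValueError("no loci in the candidate table")
        self.loci = sorted(self.candidates)
        lbf = evidence.set_index("gene_id")["log_bf"]
        if lbf.index.duplicated().any():
            raise ValueError("duplicate gene_id in the evidence table")
        self.log_bf: Dict[str, float] = {}
        for locus, genes in self.candidates.items():
            missing = [g for g in genes if g not in lbf.index or not np.isfinite(lbf[g])]
            if len(missing) == len(genes):
                raise ValueError(f"locus {locus} has no candidate with finite evidence")
            for g in genes:
                v = float(lbf.get(g, np.nan))
                self.log_bf[g] = v if np.isfinite(v) else 0.0
        self.network = network
        self.restart_prob = restart_prob
        if network is not None and network.number_of_edges() > 0:
            self._solver: Optional[RWRSolver] = RWRSolver(network, restart_prob)
            self.epsilon = default_epsilon(network) if epsilon is None else epsilon
        else:
            self._solver = None
            self.epsilon = 0.0 if epsilon is None else epsilon
        self.seed = seed
        self.random_scan = random_scan
        self._rng = np.random.default_rng(seed)
        self._cond_cache: Dict[Tuple[str, frozenset], np.ndarray] = {}
        # snp lookup for the output table
        if "snp_id" in candidates.columns:
            self._snp_by_locus = (
                candidates.drop_duplicates("locus_id").set_index("locus_id")["snp_id"].to_dict()
            )
        else:
            self._snp_by_locus = {l: l for l in self.loci}
        self.reset()

    # ------------------------------------------------------------------ state

    def reset(self) -> None:
        """Deterministic initial state: argmax log_bf per locus (ties -> smallest id)."""
        self.selection: Dict[str, str] = {}
        for locus, genes in self.candidates.items():
            best = min(genes, key=lambda g: (-self.log_bf[g], g))
            self.selection[locus] = best
        self.counts: Dict[str, np.ndarray] = {
            locus: np.zeros(len(genes), dtype=np.int64) for locus, genes in self.candidates.items()
        }
        self.sweep_index = 0
        self._recorded = 0
        self._rng = np.random.default_rng(self.seed)
        self._cond_cache.clear()

    # ------------------------------------------------------------ conditionals

    def conditional_probs(self, locus: str, other_selection: Mapping[str, str]) -> np.ndarray:
        """P(candidate | selections at the other loci), in candidate-list order."""
        genes = self.candidates[locus]
        seeds = frozenset(g for l, g in other_selection.items() if l != locus)
        key = (locus, seeds)
        cached = self._cond_cache.get(key)
        if cached is not None:
            return cached
        if self._solver is not None and seeds:
            scores = self._solver.score_of(genes, seeds)
            prior = locus_prior(dict(zip(genes, scores)), genes, self.epsilon)
            log_prior = np.log(np.array([prior[g] for g in genes]))
        else:
            log_prior = np.zeros(len(genes))  # uniform prior, constant cancels
        lbf = np.array([self.log_bf[g] for g in genes])
        logw = log_prior + lbf
        logw -= logw.max()  # log-sum-exp stabilization
        w = np.exp(logw)
        probs = w / w.sum()
        if not np.all(np.isfinite(probs)):
            raise FloatingPointError(f"non-finite conditional probabilities at locus {locus}")
        self._cond_cache[key] = probs
        return probs

    def sweep(self) -> None:
        """One full pass over the loci; counts update after the complete sweep."""
        order = list(self.loci)
        if self.random_scan:
            order = [self.loci[i] for i in self._rng.permutation(len(self.loci))]
        for locus in order:
            probs = self.conditional_probs(locus, self.selection)
            genes = self.candidates[locus]
            u = self._rng.random()
            idx = int(np.searchsorted(np.cumsum(probs), u, side="right"))
            idx = min(idx, len(genes) - 1)
            self.selection[locus] = genes[idx]
        self.sweep_index += 1

    def _record(self) -> None:
        for locus, genes in self.candidates.items():
            self.counts[locus][genes.index(self.selection[locus])] += 1
        self._recorded += 1

    def frequencies(self) -> Dict[str, np.ndarray]:
        """Per-locus sampling frequencies from post-burn-in counts."""
        if self._recorded == 0:
            return {l: np.zeros(len(g)) for l, g in self.candidates.items()}
        return {l: c / self._recorded for l, c in self.counts.items()}

    def _freq_vector(self) -> np.ndarray:
        f = self.frequencies()
        return np.concatenate([f[l] for l in self.loci])

    # -------------------------------------------------------------------- run

    def run(
        self,
        threshold: float = 0.01,
        check_every: int = 100,
        burn_in: int = 500,
        max_sweeps: int = 20_000,
    ) -> pd.DataFrame:
        """Run to convergence and return the posterior table.

        After ``burn_in`` sweeps, counts accumulate; every ``check_every``
        sweeps the full frequency vector over (locus, candidate) pairs is
        compared with the previous check and the run stops when the sum of
        squared differences falls below ``threshold`` (or at ``max_sweeps``
        with a warning and converged = False).
        """
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        for _ in range(burn_in):
            self.sweep()
            if self.sweep_index >= max_sweeps:
                break
        prev = np.zeros(sum(len(self.candidates[l]) for l in self.loci))
        converged = False
        while self.sweep_index < max_sweeps:
            for _ in range(check_every):
                self.sweep()
                self._record()
                if self.sweep_index >= max_sweeps:
                    break
            cur = self._freq_vector()
            if float(np.sum((cur - prev) ** 2)) < threshold:
                converged = True
                break
            prev = cur
        if not converged:
            logger.warning("max_sweeps=%d reached before convergence", max_sweeps)
        return self._posterior_table(converged)

    def run_fixed(self, n_sweeps: int, burn_in: int = 500) -> pd.DataFrame:
        """Run exactly ``n_sweeps`` recorded sweeps after ``burn_in`` (no stop rule)."""
        for _ in range(burn_in):
            self.sweep()
        for _ in range(n_sweeps):
            self.sweep()
            self._record()
        return self._posterior_table(True)

    def _posterior_table(self, converged: bool) -> pd.DataFrame:
        freqs = self.frequencies()
        rows = []
        for locus in self.loci:
            genes = self.candidates[locus]
            f = freqs[locus]
            best = min(range(len(genes)), key=lambda i: (-f[i], genes[i]))
            for i, g in enumerate(genes):
                rows.append(
                    {
                        "locus_id": locus,
                        "snp_id": self._snp_by_locus.get(locus, locus),
                        "gene_id": g,
                        "frequency": float(f[i]),
                        "selected": i == best,
                        "converged": converged,
                        "sweeps": self._recorded,
                        "seed": self.seed,
                    }
                )
        return pd.DataFrame(rows)


def select_prgenes(posterior: pd.DataFrame) -> pd.DataFrame:
    """Unique prioritized genes with their loci and peak frequencies.

    Per locus the maximum-frequency candidate (ties to the smallest gene_id,
    logged); a gene topping several loci appears once with all loci listed.
    """
    picks = []
    for locus, sub in posterior.groupby("locus_id", sort=True):
        sub = sub.sort_values(["frequency", "gene_id"], ascending=[False, True], kind="mergesort")
        top = sub.iloc[0]
        ties = sub[np.isclose(sub["frequency"], top["frequency"])]
        if len(ties) > 1:
            logger.info(
                "locus %s: frequency tie among %s; selected %s",
                locus, sorted(ties["gene_id"]), top["gene_id"],
            )
        picks.append({"locus_id": locus, "gene_id": top["gene_id"], "frequency": top["frequency"]})
    df = pd.DataFrame(picks)
    agg = (
        df.groupby("gene_id", sort=True)
        .agg(loci=("locus_id", lambda s: ",".join(sorted(s))), n_loci=("locus_id", "size"),
             max_frequency=("frequency", "max"))
        .reset_index()
    )
    return agg


def exact_stationary_oracle(
    candidates: pd.DataFrame,
    evidence: pd.DataFrame,
    network: Optional[nx.Graph] = None,
    restart_prob: float = 0.5,
    epsilon: Optional[float] = None,
    max_configs: int = 4096,
) -> Dict[str, Dict[str, float]]:
    """Exact per-locus stationary marginals of the systematic-scan chain.

    Enumerates all joint configurations (one candidate per locus), builds the
    one-sweep transition matrix as the product of per-locus update kernels,
    extracts the eigenvector for eigenvalue 1, and marginalizes per locus.
    Refuses instances with more than ``max_configs`` configurations.
    """
    sampler = GibbsSampler(candidates, evidence, network, restart_prob, epsilon, seed=0)
    loci = sampler.loci
    cand = sampler.candidates
    sizes = [len(cand[l]) for l in loci]
    n_cfg = int(np.prod(sizes))
    if n_cfg > max_configs:
        raise ValueError(f"{n_cfg} joint configurations exceed the oracle limit {max_configs}")

    configs = list(np.ndindex(*sizes))
    cfg_index = {c: i for i, c in enumerate(configs)}

    T = np.eye(n_cfg)
    for li, locus in enumerate(loci):
        K = np.zeros((n_cfg, n_cfg))  # kernel updating locus li
        for c in configs:
            sel = {loci[j]: cand[loci[j]][c[j]] for j in range(len(loci))}
            probs = sampler.conditional_probs(locus, {l: g for l, g in sel.items() if l != locus})
            for gi, p in enumerate(probs):
                c2 = list(c)
                c2[li] = gi
                K[cfg_index[tuple(c2)], cfg_index[c]] += p
        T = K @ T

    eigval, eigvec = np.linalg.eig(T)
    k = int(np.argmin(np.abs(eigval - 1.0)))
    pi = np.real(eigvec[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()

    marginals: Dict[str, Dict[str, float]] = {}
    for li, locus in enumerate(loci):
        m = np.zeros(sizes[li])
        for c, p in zip(configs, pi):
            m[c[li]] += p
        marginals[locus] = {g: float(v) for g, v in zip(cand[locus], m)}
    return marginals
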