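"""Network prior via random walk with restart (RWR) on a weighted gene graph.

The sampler's prior for a candidate gene at one locus is its RWR proximity
to the genes currently selected at all other loci, normalized within the
locus (with a small epsilon floor so candidates disconnected from every seed
remain reachable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)


def network_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected weighted graph from an edge list (gene_a, gene_b, weight)."""
    g = nx.Graph()
    for a, b, w in edges[["gene_a", "gene_b", "weight"]].itertuples(index=False):
        if a == b:
            continue  # no self-loops
        if g.has_edge(a, b):
            continue  # duplicate listing: keep the first weight
        g.add_edge(a, b, weight=float(w))
    return g


def column_normalize(network: nx.Graph) -> Tuple[np.ndarray, list]:
    """Column-stochastic transition matrix of the weighted adjacency.

    Returns (W, nodes) with nodes sorted for determinism; column j holds the
    probabilities of moving from node j to each node, so every column sums
    to 1.  Isolated nodes get a self-transition of 1.  Negative weights are
    rejected.
    """
    nodes = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for a, b, data in network.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({a}, {b}): {w}")
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    col_sums = W.sum(axis=0)
    isolated = col_sums == 0
    W[np.ix_(isolated, isolated)] = np.eye(int(isolated.sum()))
    col_sums = W.sum(axis=0)
    return W / col_sums, nodes


@dataclass
class RWRResult:
    """Stationary RWR scores over all network nodes (they sum to 1)."""

    scores: Dict[str, float]
    restart_prob: float


def _seed_vector(nodes: Sequence[str], seed_genes: Iterable[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    present = sorted({g for g in seed_genes if g in idx})
    missing = sorted({g for g in seed_genes if g not in idx})
    if missing:
        logger.warning("seed genes absent from the network were dropped: %s", missing[:5])
    e = np.zeros(len(nodes))
    if not present:
        logger.warning("no seed gene present in the network; restart vector set uniform")
        e[:] = 1.0 / len(nodes)
    else:
        e[[idx[g] for g in present]] = 1.0 / len(present)
    return e


def rwr(
    transition: np.ndarray,
    nodes: Sequence[str],
    seed_genes: Iterable[str],
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> RWRResult:
    """Random walk with restart by power iteration.

    Solves s = r*e + (1-r)*W*s (e uniform over the seed genes) to an L1
    tolerance of ``tol``.  With r = 1 the scores equal the seed vector.
    """
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart_prob must lie in (0, 1]")
    e = _seed_vector(nodes, seed_genes)
    s = e.copy()
    r = restart_prob
    for _ in range(max_iter):
        s_next = r * e + (1.0 - r) * (transition @ s)
        if np.abs(s_next - s).sum() < tol:
            s = s_next
            break
        s = s_next
    s = s / s.sum()
    return RWRResult(scores={n: float(v) for n, v in zip(nodes, s)}, restart_prob=r)


def locus_prior(
    scores: Mapping[str, float], candidate_genes: Sequence[str], epsilon: float
) -> Dict[str, float]:
    """Locus-normalized prior: (score + eps) / sum over the locus's candidates.

    Candidates absent from the network contribute score 0; a positive eps
    keeps them reachable by the sampler.
    """
    if len(candidate_genes) == 0:
        raise ValueError("candidate gene list is empty")
    raw = np.array([scores.get(g, 0.0) + epsilon for g in candidate_genes], dtype=float)
    total = raw.sum()
    if total <= 0:  # epsilon = 0 and every candidate off the network
        raw = np.ones(len(raw))
        total = float(len(raw))
    return {g: float(v) for g, v in zip(candidate_genes, raw / total)}


class RWRSolver:
    """Exact RWR via the precomputed fundamental matrix F = r (I - (1-r)W)^-1.

    The RWR fixed point is linear in the restart vector, s = F e, so scores
    for any seed set are the mean of the corresponding columns of F.  This
    is algebraically identical to the power-iteration fixed point and makes
    per-step prior updates inside the Gibbs sweep cheap.
    """

    def __init__(self, network: nx.Graph, restart_prob: float = 0.5):
        if not 0.0 < restart_prob <= 1.0:
            raise ValueError("restart_prob must lie in (0, 1]")
        self.restart_prob = restart_prob
        W, nodes = column_normalize(network)
        self.nodes = nodes
        self._index = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        A = np.eye(n) - (1.0 - restart_prob) * W
        self._F = restart_prob * linalg.solve(A, np.eye(n), assume_a="gen")

    def scores_vector(self, seed_genes: Iterable[str]) -> np.ndarray:
        seed_idx = sorted({self._index[g] for g in seed_genes if g in self._index})
        if not seed_idx:
            logger.warning("no seed gene present in the network; uniform restart")
            return self._F.mean(axis=1)
        return self._F[:, seed_idx].mean(axis=1)

    def scores(self, seed_genes: Iterable[str]) -> Dict[str, float]:
        v = self.scores_vector(seed_genes)
        return {n: float(x) for n, x in zip(self.nodes, v)}

    def score_of(self, genes: Sequence[str], seed_genes: Iterable[str]) -> np.ndarray:
        """RWR scores of ``genes`` (0 for genes absent from the network)."""
        v = self.scores_vector(seed_genes)
        return np.array([v[self._index[g]] if g in self._index else 0.0 for g in genes])


def default_epsilon(network: nx.Graph) -> float:
    """Prior floor 1e-6 / |nodes| (candidates off the network stay reachable)."""
    n = max(1, network.number_of_nodes())
    return 1e-6 / n
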