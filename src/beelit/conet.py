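"""Keyword co-occurrence networks against an independence null.

For keywords i and j, the observed co-occurrence probability is
O_ij = n_ij / N (fraction of publications carrying both) and the expected
probability under independence is E_ij = p_i * p_j with p_i = n_i / N.
An edge is drawn iff O_ij > E_ij strictly, weighted by the excess O - E.
Network cohesion is summarized by the global transitivity (clustering
coefficient), with percentile bootstrap confidence intervals obtained by
resampling publications.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .normalize import NormalizedCorpus

log = logging.getLogger(__name__)


@dataclass
class CooccurrenceStats:
    """Per-keyword and pairwise publication counts with O/E probabilities."""

    N: int
    keywords: list[str]
    n_i: np.ndarray          # publications containing keyword i
    n_ij: np.ndarray         # publications containing both i and j (symmetric)

    @property
    def p_i(self) -> np.ndarray:
        return self.n_i / self.N

    @property
    def O(self) -> np.ndarray:
        return self.n_ij / self.N

    @property
    def E(self) -> np.ndarray:
        p = self.p_i
        return np.outer(p, p)


def _indicator_matrix(corpus: NormalizedCorpus, keywords: list[str]) -> np.ndarray:
    idx = {kw: i for i, kw in enumerate(keywords)}
    M = np.zeros((len(corpus.records), len(keywords)), dtype=np.int64)
    for r_i, rec in enumerate(corpus.records):
        for kw in set(rec.keywords):
            j = idx.get(kw)
            if j is not None:
                M[r_i, j] = 1
    return M


def _stats_from_indicator(M: np.ndarray, keywords: list[str]) -> CooccurrenceStats:
    n_ij = M.T @ M
    return CooccurrenceStats(N=M.shape[0], keywords=list(keywords),
                             n_i=np.diag(n_ij).copy(), n_ij=n_ij)


def compute_cooccurrence(corpus: NormalizedCorpus, keywords: list[str]) -> CooccurrenceStats:
    """Whole-publication co-occurrence counts for a fixed keyword panel."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    if len(corpus.records) < 1:
        raise ValueError("corpus must contain at least one publication")
    return _stats_from_indicator(_indicator_matrix(corpus, keywords), keywords)


def build_network(stats: CooccurrenceStats) -> nx.Graph:
    """Graph with an edge wherever O > E strictly; weight = O - E.

    Isolated keywords stay in the node set.  Edges also carry the O and E
    probabilities for export.
    """
    G = nx.Graph()
    G.add_nodes_from(stats.keywords)
    O, E = stats.O, stats.E
    k = len(stats.keywords)
    for i in range(k):
        for j in range(i + 1, k):
            if O[i, j] > E[i, j]:
                G.add_edge(
                    stats.keywords[i], stats.keywords[j],
                    weight=float(O[i, j] - E[i, j]),
                    O=float(O[i, j]), E=float(E[i, j]),
                )
    nx.set_node_attributes(G, dict(G.degree()), "degree")
    return G


def global_transitivity(net: nx.Graph) -> float:
    """3 x triangles / connected triplets; 0 for triplet-free graphs."""
    return float(nx.transitivity(net))


def bootstrap_transitivity_ci(
    corpus: NormalizedCorpus,
    keywords: list[str],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the keyword-network transitivity.

    Publications (the sampling units) are resampled with replacement; the
    keyword panel is held fixed so selection noise is not conflated with
    network noise.
    """
    if n_boot < 100:
        log.warning("n_boot=%d is low for percentile intervals", n_boot)
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    M = _indicator_matrix(corpus, keywords)
    N = M.shape[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        Mb = M[rng.integers(0, N, size=N)]
        stats = _stats_from_indicator(Mb, keywords)
        reps[b] = global_transitivity(build_network(stats))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# export

def write_network(net: nx.Graph, path, fmt: str | None = None) -> None:
    """Write a network as GraphML, GEXF or a plain edge-list TSV.

    The TSV columns are source, target, O, E, weight (O/E blank for
    networks without stored probabilities, e.g. topic-word networks).
    """
    path = str(path)
    fmt = fmt or path.rsplit(".", 1)[-1].lower()
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "gexf":
        nx.write_gexf(net, path)
    elif fmt in ("tsv", "edgelist"):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "target", "O", "E", "weight"])
            for u, v, data in sorted(net.edges(data=True)):
                w.writerow([u, v, data.get("O", ""), data.get("E", ""),
                            data.get("weight", "")])
    else:
        raise ValueError(f"unknown network format {fmt!r}")
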