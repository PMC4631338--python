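"""Prior-gene enrichment among PPI partners, and the shared-partner network.

For each candidate gene the 2x2 table [partners that are prior genes,
partners that are not; non-partner prior genes, remaining universe genes]
is tested with a one-sided Fisher exact test (enrichment direction), over
the universe excluding the tested gene itself.  Edges enter the graph only
when their confidence score is strictly above the threshold (default 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

DEFAULT_SCORE_THRESHOLD = 0.4

_ADJUST_METHODS = {"fdr_bh": "fdr_bh", "bh": "fdr_bh", "bonferroni": "bonferroni",
                   "holm": "holm"}


def build_ppi_graph(
    edges: pd.DataFrame, score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> nx.Graph:
    """Undirected PPI graph from a (gene_a, gene_b, score) edge list.

    Edges scoring exactly the threshold are excluded (strict cut);
    self-loops are dropped.
    """
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        if row.gene_a == row.gene_b:
            continue
        if float(row.score) > score_threshold:
            graph.add_edge(row.gene_a, row.gene_b, score=float(row.score))
    return graph


@dataclass
class EnrichmentResult:
    """Fisher-test outcome for one gene's partner set."""

    gene: str
    k: int  # partners that are prior genes
    n: int  # total partners
    K: int  # prior genes in the universe
    N: int  # universe size
    p_value: float
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("k cannot exceed min(n, K)")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "gene": self.gene, "k": self.k, "n": self.n, "K": self.K,
            "N": self.N, "p_value": self.p_value, "adjusted_p": self.adjusted_p,
        }


def default_universe(graph: nx.Graph, prior_set: set[str]) -> set[str]:
    """Genes incident to at least one post-threshold edge, plus the priors."""
    return set(graph.nodes) | set(prior_set)


def partner_enrichment(
    graph: nx.Graph, gene: str, prior_set: set[str], universe: set[str]
) -> EnrichmentResult:
    """One-sided Fisher enrichment of prior genes among a gene's partners.

    The universe excludes the tested gene; a gene with no partners gets
    p = 1 rather than an error.
    """
    univ = set(universe) - {gene}
    partners = (set(graph.neighbors(gene)) if gene in graph else set()) & univ
    priors = set(prior_set) & univ
    k = len(partners & priors)
    n = len(partners)
    K = len(priors)
    N = len(univ)
    if n == 0:
        p = 1.0
    else:
        table = [[k, n - k], [K - k, (N - K) - (n - k)]]
        p = float(fisher_exact(table, alternative="greater").pvalue)
    return EnrichmentResult(gene=gene, k=k, n=n, K=K, N=N, p_value=p)


def adjust_pvalues(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini–Hochberg by default)."""
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def enrich_genes(
    graph: nx.Graph,
    genes: list[str],
    prior_set: set[str],
    universe: set[str] | None = None,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Test every gene in `genes` and attach adjusted p-values."""
    if universe is None:
        universe = default_universe(graph, prior_set)
    results = [partner_enrichment(graph, g, prior_set, universe) for g in genes]
    adjusted = adjust_pvalues([r.p_value for r in results], method=method)
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return results


def shared_partner_network(
    graph: nx.Graph, gene_set: list[str]
) -> list[tuple[str, str, int]]:
    """Weighted edges between genes sharing PPI partners.

    Weight = number of shared partners; zero-weight pairs are omitted.
    Genes absent from the graph contribute no edges (isolated nodes).
    Output is sorted by gene-pair for determinism.
    """
    partner_sets = {
        g: (set(graph.neighbors(g)) if g in graph else set()) for g in gene_set
    }
    ordered = sorted(set(gene_set))
    edges: list[tuple[str, str, int]] = []
    for i, g1 in enumerate(ordered):
        for g2 in ordered[i + 1 :]:
            w = len(partner_sets[g1] & partner_sets[g2])
            if w > 0:
                edges.append((g1, g2, w))
    return edges
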