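"""Gene-set over-representation analysis, combined scores, top-pathway
selection, Jaccard similarity networks, and control-trait comparison.

The over-representation p-value is the upper hypergeometric tail
P(X >= observed overlap) with the background as population, the term as the
success class, and the query list as the draw — enrichment is one-sided by
construction. The combined score c = -ln(p) * z follows the familiar
enrichment-service convention, with z a rank-deviation score calibrated by
Monte Carlo: random gene lists of the query size are ranked by p, and z
measures how many SDs better than its expected rank the term lands.
Because the published scores came from an external service and library
version, this score is a documented reconstruction, not a reproduction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .association import AssocResult, filter_significant
from .io_formats import GeneSetLibrary


@dataclass
class EnrichmentResult:
    term: str
    overlap: frozenset[str]
    list_size: int
    term_size: int
    background_size: int
    p: float
    odds_ratio: float
    z: float = 0.0
    combined: float = 0.0


@dataclass
class PathwayNetwork:
    """Jaccard-similarity graph over pathway gene sets."""

    graph: nx.Graph
    threshold: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def density(self) -> float:
        return nx.density(self.graph)

    def connected_components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def map_snps_to_genes(
    snp_ids: list[str], annotation: dict[str, str]
) -> tuple[list[str], list[str]]:
    """Map SNP ids to gene symbols through the annotation table.

    Returns (genes, unmapped snp ids); genes are de-duplicated preserving
    first-appearance order.
    """
    genes: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for snp in snp_ids:
        gene = annotation.get(snp)
        if gene is None:
            unmapped.append(snp)
        elif gene not in seen:
            seen.add(gene)
            genes.append(gene)
    return genes, unmapped


def ora_test(
    gene_list: set[str] | list[str],
    term: set[str] | frozenset[str],
    background: set[str] | frozenset[str],
) -> tuple[float, float]:
    """Hypergeometric over-representation test of a gene list against a term.

    p = P(X >= k) with population N = |background|, successes K = |term|,
    draws n = |list|, observed overlap k. The odds ratio comes from the 2x2
    table with a Haldane 0.5 correction when any cell is zero.
    """
    gene_list = set(gene_list)
    term = set(term)
    background = set(background)
    if not gene_list:
        raise ValueError("gene list is empty")
    if not gene_list <= background or not term <= background:
        raise ValueError("gene list and term must be subsets of the background")
    N, K, n = len(background), len(term), len(gene_list)
    k = len(gene_list & term)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b = k, n - k
    c, d = K - k, N - K - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return min(p, 1.0), float(odds)


def enrich(
    gene_list: list[str] | set[str],
    library: GeneSetLibrary,
    R: int = 1000,
    seed: int = 0,
    with_combined: bool = True,
) -> list[EnrichmentResult]:
    """Over-representation of a gene list against every term in the library,
    with Monte-Carlo-calibrated combined scores.

    Genes absent from the background are dropped from the query before
    testing. Results are sorted by p ascending (ties: larger combined score,
    then term name).
    """
    background = library.effective_background()
    query = frozenset(g for g in gene_list if g in background)
    if not query:
        raise ValueError("no query genes are present in the background")
    results = []
    for term, genes in library.terms.items():
        p, odds = ora_test(query, genes, background)
        results.append(
            EnrichmentResult(
                term=term,
                overlap=query & genes,
                list_size=len(query),
                term_size=len(genes),
                background_size=len(background),
                p=p,
                odds_ratio=odds,
            )
        )
    if with_combined and results:
        _add_combined_scores(results, library, len(query), R=R, seed=seed)
    results.sort(key=lambda r: (r.p, -r.combined, r.term))
    return results


def _term_pvals(
    query_idx: np.ndarray, membership: np.ndarray, N: int, term_sizes: np.ndarray
) -> np.ndarray:
    n = query_idx.size
    k = membership[:, query_idx].sum(axis=1)
    return stats.hypergeom.sf(k - 1, N, term_sizes, n)


def _add_combined_scores(
    results: list[EnrichmentResult],
    library: GeneSetLibrary,
    list_size: int,
    R: int,
    seed: int,
) -> None:
    """Attach z (rank deviation vs random lists) and c = -ln(p) * z."""
    if R < 1:
        raise ValueError("R must be >= 1")
    background = sorted(library.effective_background())
    gene_idx = {g: i for i, g in enumerate(background)}
    terms = [r.term for r in results]
    membership = np.zeros((len(terms), len(background)), dtype=bool)
    for ti, term in enumerate(terms):
        for g in library.terms[term]:
            membership[ti, gene_idx[g]] = True
    term_sizes = membership.sum(axis=1)
    N = len(background)

    rng = np.random.default_rng(seed)
    ranks = np.empty((R, len(terms)))
    for r in range(R):
        sample = rng.choice(N, size=list_size, replace=False)
        ranks[r] = stats.rankdata(_term_pvals(sample, membership, N, term_sizes))
    expected = ranks.mean(axis=0)
    sd = ranks.std(axis=0, ddof=1) if R > 1 else np.zeros(len(terms))

    observed_rank = stats.rankdata([r.p for r in results])
    for i, res in enumerate(results):
        z = 0.0 if sd[i] == 0 else float((expected[i] - observed_rank[i]) / sd[i])
        res.z = z
        res.combined = -math.log(res.p) * z if res.p < 1.0 else 0.0


def top_pathways(results: list[EnrichmentResult], k: int = 5) -> list[EnrichmentResult]:
    """The k most enriched pathways: ascending p, ties broken by larger
    combined score then term name."""
    ordered = sorted(results, key=lambda r: (r.p, -r.combined, r.term))
    return ordered[:k]


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """Jaccard coefficient |A & B| / |A | B|."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def similarity_network(
    pathways: dict[str, set[str] | frozenset[str]], threshold: float = 0.3
) -> PathwayNetwork:
    """Build the pathway-similarity graph: an edge wherever the Jaccard
    coefficient of two gene sets reaches the threshold."""
    graph = nx.Graph()
    for name, genes in pathways.items():
        graph.add_node(name, genes=frozenset(genes))
    for (na, ga), (nb, gb) in itertools.combinations(sorted(pathways.items()), 2):
        j = jaccard(ga, gb) if (ga or gb) else 0.0
        if j >= threshold:
            graph.add_edge(na, nb, jaccard=j)
    return PathwayNetwork(graph=graph, threshold=threshold)


def control_comparison(
    assoc_by_trait: dict[str, list[AssocResult]],
    annotation: dict[str, str],
    library: GeneSetLibrary,
    alpha: float = 0.05,
    k: int = 5,
    jaccard_threshold: float = 0.3,
    R: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Side-by-side specificity table across case and control traits.

    For each trait: number of SNPs tested, number significant at the
    permutation-p cutoff, their ratio, the top-k enriched pathways of the
    mapped genes, and the density of the pathway similarity network. Traits
    with no significant SNPs get an empty pathway list and density 0.
    """
    rows = []
    for trait, results in assoc_by_trait.items():
        sig = filter_significant(results, alpha)
        genes, _ = map_snps_to_genes([r.snp for r in sig], annotation)
        usable = [g for g in genes if g in library.effective_background()]
        if usable:
            enr = enrich(usable, library, R=R, seed=seed)
            top = top_pathways(enr, k)
            net = similarity_network(
                {r.term: library.terms[r.term] for r in top}, jaccard_threshold
            )
            density = net.density
            top_names = [r.term for r in top]
        else:
            top_names, density = [], 0.0
        rows.append(
            {
                "trait": trait,
                "tested": len(results),
                "significant": len(sig),
                "ratio": len(sig) / len(results) if results else 0.0,
                "n_genes": len(genes),
                "top_pathways": ";".join(top_names),
                "network_density": density,
            }
        )
    return pd.DataFrame(rows)
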