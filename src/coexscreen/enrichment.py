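"""Hypergeometric over-representation and redundant-term clustering.

Each catalog term is tested for over-representation in a query gene
list against a finite background (upper-tail hypergeometric); p-values
are Benjamini-Hochberg adjusted across the tested terms.  Because
ontology catalogs carry many near-duplicate terms, enriched terms are
then greedily clustered by Cohen's kappa of their membership indicator
vectors: the most significant unclustered term seeds a cluster and
absorbs every term with kappa at or above the threshold (default 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCatalog
from .screen import bh_adjust

DEFAULT_KAPPA_THRESHOLD = 0.3


@dataclass
class TermCluster:
    """A group of mutually redundant enriched terms.

    The representative is the most significant member (minimal p,
    ties broken by term id).
    """

    representative: str
    members: list[str]
    kappas: dict[str, float] = field(default_factory=dict)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` = overlap, ``n`` = query size, ``K`` = term size, ``N`` =
    background size.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    if not (k <= min(n, K) <= N and n <= N and K <= N):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the log-pmf internally
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_gene_sets(
    query_genes: list[str],
    catalog: GeneSetCatalog,
    background: list[str],
) -> pd.DataFrame:
    """Over-representation table: one row per term overlapping the query.

    Term members are intersected with the background before testing;
    terms with zero overlap are excluded.  Columns:
    ``term_id, term_name, k, n, K, N, p_value, q_value, log10_p``
    (``log10_p`` is negative), sorted by p then term id.
    """
    background_set = set(background)
    if not background_set:
        raise ValueError("empty background")
    query = set(query_genes)
    if not query:
        raise ValueError("empty query")
    stray = query - background_set
    if stray:
        raise ValueError(f"query genes not in background: {sorted(stray)[:5]}")
    n = len(query)
    N = len(background_set)
    rows = []
    for gene_set in catalog:
        members = set(gene_set.genes) & background_set
        K = len(members)
        k = len(members & query)
        if k == 0:
            continue
        p = hypergeom_tail(k, n, K, N)
        rows.append((gene_set.term_id, gene_set.term_name, k, n, K, N, p))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_value"]
    )
    if len(table) == 0:
        table["q_value"] = []
        table["log10_p"] = []
        return table
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["log10_p"] = np.log10(table["p_value"].to_numpy())
    table = table.sort_values(
        by=["p_value", "term_id"], ascending=[True, True], kind="stable"
    ).reset_index(drop=True)
    return table


def kappa_similarity(
    set_a: set[str] | list[str], set_b: set[str] | list[str], background_size: int
) -> float:
    """Cohen's kappa of two set-membership indicators over a background."""
    a = set(set_a)
    b = set(set_b)
    union = a | b
    if background_size < len(union):
        raise ValueError("background smaller than the union of the sets")
    N = background_size
    both = len(a & b)
    neither = N - len(union)
    po = (both + neither) / N
    pa = len(a) / N
    pb = len(b) / N
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0  # both sets empty or both equal to the background
    return float((po - pe) / (1.0 - pe))


def cluster_terms(
    results: pd.DataFrame,
    catalog: GeneSetCatalog,
    background: list[str],
    kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> list[TermCluster]:
    """Greedy redundancy clustering of enriched terms.

    Repeatedly seed with the most significant unclustered term and
    absorb all unclustered terms whose kappa to the seed is at or above
    the threshold; the seed is the cluster representative, so
    representatives' p-values are non-increasing in discovery order.
    """
    if len(results) == 0:
        raise ValueError("no enrichment results to cluster")
    if not 0.0 < kappa_threshold < 1.0:
        raise ValueError("kappa_threshold must be in (0, 1)")
    background_set = set(background)
    N = len(background_set)
    member_sets = {
        term_id: set(catalog.sets[term_id].genes) & background_set
        for term_id in results["term_id"]
    }
    ordered = results.sort_values(
        by=["p_value", "term_id"], ascending=[True, True], kind="stable"
    )["term_id"].tolist()
    unclustered = list(ordered)
    clusters: list[TermCluster] = []
    while unclustered:
        seed = unclustered.pop(0)
        members = [seed]
        kappas = {seed: 1.0}
        remaining = []
        for term in unclustered:
            kap = kappa_similarity(member_sets[seed], member_sets[term], N)
            if kap >= kappa_threshold:
                members.append(term)
                kappas[term] = kap
            else:
                remaining.append(term)
        unclustered = remaining
        clusters.append(TermCluster(seed, members, kappas))
    return clusters
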