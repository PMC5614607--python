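"""Hypergeometric term over-representation with Benjamini-Hochberg FDR.

Gene sets (subnetworks, meta-subnetworks, or a pooled gene list) are
tested for functional enrichment against a gene universe — by default the
scored genes that mapped onto the analyzed network. Terms are tested as
annotated; no ontology-graph propagation is performed (pre-propagated
annotation tables are accepted as-is).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "AnnotationTable",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_gene_set",
]


@dataclass
class AnnotationTable:
    """Gene -> term annotations plus human-readable term names."""

    gene_terms: Dict[str, Set[str]]
    term_names: Dict[str, str]

    def __post_init__(self) -> None:
        for terms in self.gene_terms.values():
            for t in terms:
                self.term_names.setdefault(t, t)

    def term_genes(self, universe: Set[str]) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for g, terms in self.gene_terms.items():
            if g not in universe:
                continue
            for t in terms:
                out.setdefault(t, set()).add(g)
        return out


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # annotated genes in the tested set
    K: int  # annotated genes in the universe
    n: int  # tested set size
    N: int  # universe size
    p: float
    q: float = 1.0
    significant: bool = False


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the annotated genes in the universe, n the
    drawn set size, k the annotated genes observed in the set.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k), computed exactly in scipy from log-binomials
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def enrich_gene_set(
    genes: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationTable,
    fdr: float = 0.05,
) -> List[EnrichmentResult]:
    """Test every term with at least one annotated gene in the set.

    Returns results sorted by ascending p; ``significant`` marks terms with
    BH-adjusted q <= fdr.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    gene_set = set(genes) & uni
    if set(genes) - uni:
        raise ValueError("tested gene set must be a subset of the universe")
    term2genes = annotations.term_genes(uni)
    results: List[EnrichmentResult] = []
    N, n = len(uni), len(gene_set)
    for term, annotated in sorted(term2genes.items()):
        K = len(annotated)
        k = len(annotated & gene_set)
        if k == 0:
            continue
        p = hypergeom_upper_tail(k, K, n, N)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=annotations.term_names.get(term, term),
                k=k, K=K, n=n, N=N, p=p,
            )
        )
    if results:
        qvals = bh_adjust([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = q
            r.significant = q <= fdr
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
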