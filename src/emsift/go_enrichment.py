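"""Gene Ontology over-representation analysis (ORA).

The classical one-sided test: given a universe of N annotated genes of
which K carry a term, and a selection of n genes of which k carry it, the
enrichment p-value is the upper hypergeometric tail

    p = sum_{i >= k} C(K,i) C(N-K, n-i) / C(N,n)

computed in log space for numerical range. Raw p-values are adjusted per
run with Benjamini-Hochberg. Both the tail sum and the adjustment are
implemented here directly (no GO-analysis package is called); GO-DAG
propagation is deliberately out of scope - terms are tested exactly as
annotated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentRow", "hypergeom_upper", "bh_adjust", "enrich"]


def _log_comb(n: int, r: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact in log space.

    Parameters: ``k`` selected genes carrying the term, ``n`` selected
    genes, ``K`` universe genes carrying the term, ``N`` universe size.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    lower = max(k, n - (N - K))  # below this C(N-K, n-i) is zero
    if lower > upper:
        return 0.0
    log_terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
        for i in range(lower, upper + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    adj_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped
    at 1, returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out.tolist()


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term: overlap counts, raw and adjusted p."""

    term: str
    k: int       # selected genes with the term
    n: int       # selected genes that are annotated
    K: int       # universe genes with the term
    N: int       # universe size
    p: float
    p_adjusted: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adjusted < alpha


def enrich(
    selected: Iterable[str],
    gene2go: Mapping[str, set[str]],
    min_term_size: int = 3,
    alpha: float = 0.05,  # noqa: ARG001 - conventional default carried in reports
) -> list[EnrichmentRow]:
    """Test every sufficiently large term for over-representation.

    The universe is every gene with at least one annotation in
    ``gene2go``; selected genes without annotation are dropped from ``n``
    with a logged count. Rows are sorted by raw p (ties by term id).
    """
    universe = set(gene2go)
    selected_set = set(selected)
    annotated_sel = selected_set & universe
    dropped = len(selected_set) - len(annotated_sel)
    if dropped:
        logger.info("enrich: dropped %d unannotated selected genes", dropped)
    if not annotated_sel:
        logger.warning("enrich: empty (annotated) selection; no terms tested")
        return []

    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene2go.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    N, n = len(universe), len(annotated_sel)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(genes & annotated_sel)
        rows.append((term, k, K, hypergeom_upper(k, n, K, N)))
    adjusted = bh_adjust([r[3] for r in rows])
    result = [
        EnrichmentRow(term=t, k=k, n=n, K=K, N=N, p=p, p_adjusted=padj)
        for (t, k, K, p), padj in zip(rows, adjusted)
    ]
    result.sort(key=lambda r: (r.p, r.term))
    return result
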