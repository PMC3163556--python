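"""Hypergeometric over-representation analysis (ORA).

Given a query protein/gene set and an ontology, each category is scored by
the one-sided upper-tail hypergeometric probability of drawing at least the
observed overlap: with universe size N, category size K, query size n and
overlap k,

    p = P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n).

Query and categories are restricted to the universe before counting.  Results
are ranked by raw p (ascending, ties by larger overlap then name); a
Benjamini-Hochberg adjusted p accompanies every raw p.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EnrichmentError
from .knowledgebase import Ontology


@dataclass(frozen=True)
class EnrichmentResult:
    """One ontology category's over-representation score."""

    category: str
    ontology: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    p_adjusted: float
    rank: int


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Computed in log space (scipy survival function), numerically stable for
    universes up to ~1e5.  Bounds: 0 <= k <= n <= N and 0 <= K <= N; k cannot
    exceed min(K, n).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise EnrichmentError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k > min(K, n):
        raise EnrichmentError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def enrich_set(
    query: Iterable[str],
    ont: Ontology,
    universe_override: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Score every ontology category against a query set.

    The query is intersected with the universe first; a query disjoint from
    the universe is an error (reporting how many ids were dropped).
    """
    universe = frozenset(universe_override) if universe_override is not None else ont.universe
    query = set(query)
    restricted = query & universe
    if not restricted:
        raise EnrichmentError(
            f"query disjoint from the universe ({len(query)} id(s) dropped)"
        )

    N, n = len(universe), len(restricted)
    rows = []
    for cat, members in ont.categories.items():
        cat_u = members & universe
        k = len(restricted & cat_u)
        rows.append((cat, len(cat_u), k, hypergeometric_upper_tail(N, len(cat_u), n, k)))

    adjusted = adjust_bh([r[3] for r in rows])
    order = sorted(range(len(rows)), key=lambda i: (rows[i][3], -rows[i][2], rows[i][0]))
    results = []
    for rank, i in enumerate(order, start=1):
        cat, K, k, p = rows[i]
        results.append(
            EnrichmentResult(
                category=cat, ontology=ont.name, N=N, K=K, n=n, k=k,
                p_value=p, p_adjusted=adjusted[i], rank=rank,
            )
        )
    return results


def write_enrichment(path, results: Sequence[EnrichmentResult]) -> None:
    """TSV: category, N, K, n, k, p_value, p_adjusted, rank."""
    with open(path, "w") as fh:
        fh.write("category\tN\tK\tn\tk\tp_value\tp_adjusted\trank\n")
        for r in results:
            fh.write(
                f"{r.category}\t{r.N}\t{r.K}\t{r.n}\t{r.k}"
                f"\t{r.p_value:.6e}\t{r.p_adjusted:.6e}\t{r.rank}\n"
            )
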