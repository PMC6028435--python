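"""Gene-set over-representation testing.

Hypergeometric upper-tail test of a query gene list against each term of a
gene-set collection, with optional EASE variant (the conservative score that
removes one overlapping gene before taking the tail) and Benjamini–Hochberg
adjustment. KEGG-style screening thresholds on the raw p-value; GO-style
screening thresholds on the adjusted one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_tail", "bh_adjust", "enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap counts and p-values for one term.

    N: universe size; K: term members in the universe; n: query genes in the
    universe; k: overlap of query and term.
    """

    term_id: str
    term_name: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adjusted: float
    overlap: tuple[str, ...]
    significant: bool = False


def hypergeom_tail(N: int, K: int, n: int, k: int, ease: bool = False) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    With ``ease=True`` the tail is taken from k-1 (floored at 0) — the
    conservative over-representation score used by annotation tools.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K,n); got k={k}, K={K}, n={n}")
    if ease:
        k = max(k - 1, 0)
    # sf(k-1) = P(X >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def enrich(
    query,
    collection,
    universe,
    alpha: float = 0.05,
    adjust: str = "bh",
    significance_on: str = "raw",
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test a query gene list for over-representation in every term.

    Terms with no member in the universe are skipped. Query genes outside the
    universe are dropped with a warning. ``significance_on`` selects whether
    the ``significant`` flag thresholds the raw p (KEGG-style) or the
    BH-adjusted p (GO-style). Results are sorted by raw p ascending.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("enrich: dropped %d query gene(s) outside the universe", len(outside))
        query &= universe
    if significance_on not in ("raw", "adjusted"):
        raise ValueError("significance_on must be 'raw' or 'adjusted'")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")

    N, n = len(universe), len(query)
    rows: list[tuple[str, str, int, int, tuple[str, ...], float]] = []
    for term_id, term_name, members in collection:
        members_u = set(members) & universe
        if not members_u:
            continue
        overlap = tuple(sorted(members_u & query))
        K, k = len(members_u), len(overlap)
        p = hypergeom_tail(N, K, n, k, ease=ease)
        rows.append((term_id, term_name, K, k, overlap, p))

    p_raw = [r[5] for r in rows]
    p_adj = bh_adjust(p_raw) if adjust == "bh" else np.asarray(p_raw, dtype=float)
    results = []
    for (term_id, term_name, K, k, overlap, p), padj in zip(rows, p_adj):
        basis = p if significance_on == "raw" else float(padj)
        results.append(EnrichmentResult(
            term_id=term_id, term_name=term_name, N=N, K=K, n=n, k=k,
            p_raw=p, p_adjusted=float(max(padj, p)), overlap=overlap,
            significant=bool(basis < alpha),
        ))
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name, "N": r.N, "K": r.K,
                "n": r.n, "k": r.k, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                "significant": r.significant, "overlap": ",".join(r.overlap),
            }
            for r in results
        ]
    ).set_index("term_id") if results else pd.DataFrame(
        columns=["term_name", "N", "K", "n", "k", "p_raw", "p_adjusted", "significant", "overlap"]
    )
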