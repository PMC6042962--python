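"""Hypergeometric term enrichment, BH adjustment and correlation utilities.

The over-representation test asks: drawing ``n`` genes (the significant
list) without replacement from a universe of ``N`` genes of which ``K``
carry a term, what is the probability of seeing at least the observed ``k``
carriers? The upper tail P(X >= k) is accumulated in log-space from the
hypergeometric pmf (log-binomials via ``gammaln``), which keeps tiny
p-values accurate. Fold enrichment is the term's frequency in the list
divided by its frequency in the universe, (k/n)/(K/N).

A term is *included* in the reported enrichment when its raw p-value is
below the cutoff (default 0.05) and at least ``min_k`` (default 2) list
genes are annotated to it. Raw p-values are the default — matching the
inclusion rule above — with Benjamini–Hochberg adjustment available behind
a flag as the safer option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Accumulated in log-space over the upper support; exact to floating
    point for any feasible (k, K, n, N).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    support_min = max(0, n - (N - K))
    if k <= support_min:
        return 1.0  # the tail covers the whole support
    i = np.arange(k, min(n, K) + 1)
    log_pmf = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(np.exp(logsumexp(log_pmf)))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): list frequency of a term over universe frequency."""
    if n <= 0:
        raise ValueError("significant list is empty (n = 0)")
    if K <= 0:
        return float("nan")  # term absent from the universe: undefined
    return (k / n) / (K / N)


@dataclass
class TermEnrichmentResult:
    term: str
    k: int  # list genes annotated to the term
    n: int  # list size
    K: int  # universe genes annotated to the term
    N: int  # universe size
    p_value: float
    fold_enrichment: float
    included: bool
    p_adjusted: float | None = None


def term_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, set[str] | Sequence[str]],
    p_cutoff: float = 0.05,
    min_k: int = 2,
    bh: bool = False,
) -> list[TermEnrichmentResult]:
    """Hypergeometric enrichment of every term against the gene list.

    Results are sorted by fold enrichment, descending (bar-plot order),
    ties broken by p-value then term name. With ``bh=True`` the inclusion
    rule uses BH-adjusted p-values instead of raw ones.
    """
    universe_set = set(universe)
    list_set = set(gene_list)
    offenders = sorted(list_set - universe_set)
    if offenders:
        raise ValueError(f"genes not in universe: {offenders}")
    n, N = len(list_set), len(universe_set)
    results: list[TermEnrichmentResult] = []
    for term in sorted(term_map):
        members = set(term_map[term]) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & list_set)
        p = hypergeom_upper_tail(k, K, n, N) if n > 0 else 1.0
        fe = fold_enrichment(k, n, K, N) if n > 0 else float("nan")
        results.append(TermEnrichmentResult(term, k, n, K, N, p, fe, included=False))
    if bh and results:
        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    for r in results:
        p_for_rule = r.p_adjusted if bh else r.p_value
        r.included = (p_for_rule < p_cutoff) and (r.k >= min_k)
    results.sort(key=lambda r: (-r.fold_enrichment, r.p_value, r.term))
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adj for the i-th smallest p is ``min_{j >= i} (N * p_(j) / j)``,
    capped at 1; ranks are preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation with pairwise NaN dropping.

    Returns NaN (reported as missing) when fewer than two complete pairs
    remain or either argument has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
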