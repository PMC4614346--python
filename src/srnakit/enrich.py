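"""Hypergeometric term enrichment with Bonferroni or BH-FDR control."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Set

import numpy as np
from scipy.special import gammaln


@dataclass
class EnrichmentTerm:
    term: str
    N: int  # annotated universe size
    n: int  # candidate genes inside the universe
    M: int  # genes annotated to the term
    m: int  # candidate genes annotated to the term
    p_raw: float
    p_adjusted: float
    enriched: bool


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, n: int, M: int, m: int) -> float:
    """Upper tail P(X >= m) for X ~ Hypergeometric(N, M, n), in log-space."""
    if min(N, n, M, m) < 0 or n > N or M > N:
        raise ValueError("invalid hypergeometric configuration")
    if m > min(n, M):
        raise ValueError("m cannot exceed min(n, M)")
    if m == 0:
        return 1.0
    ks = np.arange(m, min(n, M) + 1)
    log_terms = _log_comb(M, ks) + _log_comb(N - M, n - ks) - _log_comb(N, n)
    top = float(np.max(log_terms))
    total = top + math.log(float(np.sum(np.exp(log_terms - top))))
    return float(min(1.0, math.exp(total)))


def bh_fdr(p_values: list) -> list:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    k = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(k)
    running = 1.0
    for rank_idx in range(k - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * k / (rank_idx + 1))
        adjusted[i] = running
    return adjusted.tolist()


def enrich_terms(candidates: Set[str], gene2term: dict,
                 method: str = "bonferroni", alpha: float = 0.05):
    """One EnrichmentTerm per term with m >= 1, tested against the universe
    of annotated genes.  Returns (terms, n_dropped_candidates)."""
    if method not in ("bonferroni", "bh_fdr"):
        raise ValueError(f"unknown correction method {method!r}")
    if not gene2term:
        raise ValueError("empty annotation map")
    universe = set(gene2term)
    inside = set(candidates) & universe
    dropped = len(set(candidates)) - len(inside)
    if not inside:
        return [], dropped
    term_genes: dict = {}
    for gene, terms in gene2term.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N, n = len(universe), len(inside)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        m = len(genes & inside)
        if m < 1:
            continue
        M = len(genes)
        rows.append((term, N, n, M, m, hypergeom_tail(N, n, M, m)))
    raw = [r[5] for r in rows]
    if method == "bonferroni":
        adjusted = [min(1.0, p * len(rows)) for p in raw]
    else:
        adjusted = bh_fdr(raw)
    out = []
    for (term, N_, n_, M, m, p), padj in zip(rows, adjusted):
        out.append(EnrichmentTerm(term, N_, n_, M, m, p, padj, padj <= alpha))
    out.sort(key=lambda t: (t.p_adjusted, t.p_raw, t.term))
    return out, dropped
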