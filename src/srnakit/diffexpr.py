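"""Normalization, replicate QC, fold-change, and the count-based test.

Raw counts are pooled per strain, normalized to a per-million scale
against the strain's summed clean-read total, zero-substituted with 0.01,
and compared with a two-library exact count statistic evaluated in
log-space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import pearsonr

ZERO_SUBSTITUTE = 0.01


@dataclass
class DEResult:
    name: str
    count_treated: int
    count_control: int
    norm_treated: float
    norm_control: float
    fold_change: float
    p_value: float
    significant: bool


def normalize(count: int, total_clean_reads: int) -> float:
    """count / total * 1e6, with exact zeros replaced by 0.01."""
    if total_clean_reads <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("negative count")
    value = count / total_clean_reads * 1e6
    return ZERO_SUBSTITUTE if value == 0 else value


def fold_change(norm_treated: float, norm_control: float) -> float:
    """log2(treated / control); inputs must be positive."""
    if norm_treated <= 0 or norm_control <= 0:
        raise ValueError("normalized expressions must be positive")
    return math.log2(norm_treated / norm_control)


def _log_terms(x: int, r: float, ks: np.ndarray) -> np.ndarray:
    # log p(k|x) = k log r + lgamma(x+k+1) - lgamma(x+1) - lgamma(k+1)
    #              - (x+k+1) log(1+r)
    return (ks * math.log(r) + gammaln(x + ks + 1) - gammaln(x + 1)
            - gammaln(ks + 1) - (x + ks + 1) * math.log1p(r))


def count_p_value(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact tail probability for observing counts (x, y) from
    libraries of size (n1, n2) under a common underlying rate.

    With r = n2/n1 the conditional law of y given x has
    p(k|x) = r^k (x+k)! / (x! k! (1+r)^(x+k+1)); both tails are summed
    directly in log-space and the smaller one doubled (capped at 1).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    lower_ks = np.arange(0, y + 1)
    log_lower = logsumexp(_log_terms(x, r, lower_ks))
    # upper tail: sum from y until the running terms are negligible
    block, start = 256, y
    parts = []
    while True:
        ks = np.arange(start, start + block)
        terms = _log_terms(x, r, ks)
        parts.append(logsumexp(terms))
        if terms[-1] < max(parts) - 60 and terms[-1] < terms[0]:
            break
        start += block
        block = min(block * 2, 1 << 16)
    log_upper = logsumexp(parts)
    log_p = min(log_lower, log_upper) + math.log(2.0)
    return float(min(1.0, math.exp(min(0.0, log_p))))


def replicate_pearson(counts_a: Sequence[float], counts_b: Sequence[float]) -> float:
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("correlation undefined for constant vector")
    return float(pearsonr(a, b)[0])


def de_table(counts: dict, totals_treated: int, totals_control: int,
             library_totals: dict | None = None,
             treated_libs: Sequence[str] = (), control_libs: Sequence[str] = (),
             alpha: float = 0.05) -> list:
    """Build the differential-expression table from pooled strain counts.

    ``counts`` maps name -> {library: count}.  miRNAs whose normalized
    expression is below 1 in every individual library are dropped; the
    remaining rows carry the pooled fold-change and count test, sorted by
    p-value.
    """
    results = []
    for name, libs in counts.items():
        treated = sum(libs.get(l, 0) for l in treated_libs)
        control = sum(libs.get(l, 0) for l in control_libs)
        if library_totals is not None:
            per_lib = [normalize(libs.get(l, 0), library_totals[l])
                       for l in list(treated_libs) + list(control_libs)]
            if all(v < 1 for v in per_lib):
                continue
        nt = normalize(treated, totals_treated)
        nc = normalize(control, totals_control)
        if library_totals is None and nt < 1 and nc < 1:
            continue
        p = count_p_value(control, treated, totals_control, totals_treated)
        lfc = fold_change(nt, nc)
        results.append(DEResult(name, treated, control, nt, nc, lfc, p,
                                p < alpha))
    results.sort(key=lambda r: (r.p_value, r.name))
    return results
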