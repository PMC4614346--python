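"""Independent brute-force oracles used by the test suite only."""

from fractions import Fraction
from functools import lru_cache
from math import comb

from srnakit.fold import MIN_LOOP, can_pair, stack_energy_centi, to_rna


def enumerate_structures(seq):
    """All nested structures (tuples of (i, j) pairs) with min loop 3."""
    s = to_rna(seq)
    n = len(s)

    @lru_cache(maxsize=None)
    def rec(i, j):  # structures over s[i:j]
        if j - i <= MIN_LOOP:
            return [()]
        out = list(rec(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j):
            if can_pair(s[i], s[k]):
                for inner in rec(i + 1, k):
                    for rest in rec(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return out

    return rec(0, n)


def structure_energy_centi(seq, pairs):
    s = to_rna(seq)
    bp = dict(pairs)
    total = 0
    for i, j in pairs:
        if bp.get(i + 1) == j - 1:
            total += stack_energy_centi(s[i], s[j], s[i + 1], s[j - 1])
    return total


def brute_force_mfe(seq):
    """Exhaustive minimum energy (kcal/mol) over all nested structures."""
    best = 0
    for pairs in enumerate_structures(seq):
        best = min(best, structure_energy_centi(seq, pairs))
    return best / 100.0


def brute_force_duplex(seq_a, seq_b):
    """Min energy over all antiparallel monotone intermolecular pairings."""
    a = to_rna(seq_a)
    b = to_rna(seq_b)
    na, nb = len(a), len(b)

    best = [0]

    def extend(i, j, chain_energy, last):
        # last = (i_prev, j_prev) or None
        for ii in range(i, na):
            for jj in range(j, -1, -1):
                if not can_pair(a[ii], b[jj]):
                    continue
                e = chain_energy
                if last is not None and ii == last[0] + 1 and jj == last[1] - 1:
                    e += stack_energy_centi(a[last[0]], b[last[1]], a[ii], b[jj])
                best[0] = min(best[0], e)
                extend(ii + 1, jj - 1, e, (ii, jj))

    extend(0, nb - 1, 0, None)
    return best[0] / 100.0


def ac_p_value_exact(x, y, n1, n2):
    """Exact-rational two-sided count-test p-value (direct summation)."""
    r = Fraction(n2, n1)
    one_plus = 1 + r

    def term(k):
        return (r ** k * comb(x + k, k)) / (one_plus ** (x + k + 1))

    lower = sum(term(k) for k in range(0, y + 1))
    upper = 1 - sum(term(k) for k in range(0, y))
    p = 2 * min(lower, upper)
    return float(min(Fraction(1), p))


def hypergeom_tail_exact(N, n, M, m):
    """P(X >= m) by exact binomial-coefficient summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for k in range(m, min(n, M) + 1):
        total += Fraction(comb(M, k) * comb(N - M, n - k), denom)
    return float(min(Fraction(1), total))
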