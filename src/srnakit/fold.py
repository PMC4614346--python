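"""Nested secondary-structure folding with a nearest-neighbor stacking model.

Energies come from a Turner-style stacking table (Watson-Crick and G·U
pairs, no dangles, no loop penalties).  The total energy of a structure is
the sum of the stacking terms of every pair stacked directly on another
pair; isolated pairs and loops contribute nothing.  All arithmetic is done
in integer centi-kcal/mol so dynamic programming ties are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

MIN_LOOP = 3  # minimum number of unpaired bases enclosed by a pair

_PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}

# Stacking free energies (kcal/mol, 37 C) keyed by ((i, j), (i+1, j-1))
# where (i, j) is the outer closing pair.  Entries are completed below via
# the strand-reversal symmetry E[(a,b),(c,d)] == E[(d,c),(b,a)].
_STACK_SEED = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("U", "A"), ("G", "U")): -1.00,
    (("U", "A"), ("U", "G")): -1.27,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("G", "U"), ("G", "U")): -0.50,
    (("U", "G"), ("U", "G")): -0.50,
    (("G", "U"), ("U", "G")): -0.50,
    (("U", "G"), ("G", "U")): -0.30,
}


def _build_stack_table() -> dict:
    table = {}
    for (p1, p2), e in _STACK_SEED.items():
        mirrored = ((p2[1], p2[0]), (p1[1], p1[0]))
        cents = round(e * 100)
        for key in (p1, p2), mirrored:
            if key in table and table[key] != cents:
                raise AssertionError(f"inconsistent stack symmetry for {key}")
            table[key] = cents
    for p1 in _PAIRABLE:
        for p2 in _PAIRABLE:
            if (p1, p2) not in table:
                raise AssertionError(f"missing stack entry {(p1, p2)}")
    return table


STACK_CENTI = _build_stack_table()


def to_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - {"A", "C", "G", "U", "N"}
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def stack_energy_centi(a: str, b: str, c: str, d: str) -> int:
    """Energy of pair (c,d) stacked inside closing pair (a,b), centi-kcal."""
    return STACK_CENTI[((a, b), (c, d))]


def structure_energy(seq: str, pairs: dict[int, int]) -> float:
    """Recompute the energy of an explicit structure (pairs: i -> j, i < j)."""
    s = to_rna(seq)
    cents = 0
    for i, j in pairs.items():
        if i > j:
            continue
        k = pairs.get(i + 1)
        if k is not None and k == j - 1 and k > i + 1:
            cents += stack_energy_centi(s[i], s[j], s[i + 1], s[j - 1])
    return cents / 100.0


@dataclass(frozen=True)
class FoldResult:
    structure: str  # dot-bracket, same length as the input
    mfe: float      # kcal/mol, <= 0

    @property
    def pairs(self) -> dict[int, int]:
        """Base pairs as a symmetric index map."""
        stack, out = [], {}
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                out[j] = i
                out[i] = j
        return out


_INF = (10 ** 9, 10 ** 9)


def fold_mfe(seq: str, max_len: int = 200) -> FoldResult:
    """Minimum-free-energy nested structure by dynamic programming.

    Ties are broken toward fewer pairs and then toward 5'-most pairing, so
    the traceback is deterministic.  The DP state is a (centi-kcal, number
    of pairs) tuple compared lexicographically.
    """
    s = to_rna(seq)
    n = len(s)
    if n < 1:
        raise ValueError("empty sequence")
    if n > max_len:
        raise ValueError(f"sequence longer than {max_len} nt")
    if n <= MIN_LOOP + 1:
        return FoldResult("." * n, 0.0)

    pairable = [[can_pair(s[i], s[j]) for j in range(n)] for i in range(n)]

    # V[i][j]: best (energy, pairs) given i pairs j; W[i][j]: best overall.
    V = [[_INF] * n for _ in range(n)]
    W = [[(0, 0)] * n for _ in range(n)]

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i][j]:
                # interior folds freely (pair itself contributes 0)
                wi = W[i + 1][j - 1] if j - 1 > i + 1 else (0, 0)
                best = (wi[0], wi[1] + 1)
                if j - 1 - (i + 1) > MIN_LOOP and pairable[i + 1][j - 1]:
                    v = V[i + 1][j - 1]
                    if v is not _INF:
                        cand = (v[0] + stack_energy_centi(s[i], s[j], s[i + 1], s[j - 1]),
                                v[1] + 1)
                        if cand < best:
                            best = cand
                V[i][j] = best
            # W recursion: option order fixes the tie-break
            best = W[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if pairable[i][k]:
                    v = V[i][k]
                    rest = W[k + 1][j] if k + 1 <= j else (0, 0)
                    cand = (v[0] + rest[0], v[1] + rest[1])
                    if cand < best:
                        best = cand
            W[i][j] = best

    pairs: dict[int, int] = {}

    def trace_v(i: int, j: int) -> None:
        pairs[i] = j
        pairs[j] = i
        target = V[i][j]
        if j - 1 - (i + 1) > MIN_LOOP and pairable[i + 1][j - 1]:
            v = V[i + 1][j - 1]
            cand = (v[0] + stack_energy_centi(s[i], s[j], s[i + 1], s[j - 1]), v[1] + 1)
            if cand == target:
                trace_v(i + 1, j - 1)
                return
        if j - 1 > i + 1:
            trace_w(i + 1, j - 1)

    def trace_w(i: int, j: int) -> None:
        while i < j:
            target = W[i][j]
            if target == (0, 0):
                return
            if W[i + 1][j] == target:
                i += 1
                continue
            done = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if pairable[i][k]:
                    v = V[i][k]
                    rest = W[k + 1][j] if k + 1 <= j else (0, 0)
                    if (v[0] + rest[0], v[1] + rest[1]) == target:
                        trace_v(i, k)
                        i = k + 1
                        done = True
                        break
            if not done:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed")

    trace_w(0, n - 1)
    db = ["."] * n
    for i, j in pairs.items():
        if i < j:
            db[i] = "("
            db[j] = ")"
    return FoldResult("".join(db), W[0][n - 1][0] / 100.0)


def duplex_mfe(seq_a: str, seq_b: str, max_len: int = 30) -> float:
    """Minimum stacking energy of an antiparallel intermolecular duplex.

    seq_a 5'->3' is paired against seq_b 5'->3' with no intramolecular
    structure; bulges are allowed but contribute no energy, so only runs of
    stacked pairs score.  Returns kcal/mol <= 0.
    """
    a = to_rna(seq_a)
    b = to_rna(seq_b)
    if len(a) > max_len or len(b) > max_len:
        raise ValueError(f"duplex sequences longer than {max_len} nt")
    if not a or not b:
        raise ValueError("empty sequence")
    na, nb = len(a), len(b)
    # D[i][j]: best energy (centi) of a duplex whose last pair is (a[i], b[j]);
    # pairing is monotone: i increases while j decreases (antiparallel).
    D = [[None] * nb for _ in range(na)]
    best_overall = 0
    # prefix_min[i][j] = min over i' <= i, j' >= j of D[i'][j'] (for bulged joins)
    pmin = [[10 ** 9] * nb for _ in range(na)]
    for i in range(na):
        for j in range(nb - 1, -1, -1):
            if can_pair(a[i], b[j]):
                e = 0
                if i > 0 and j < nb - 1:
                    d_adj = D[i - 1][j + 1]
                    if d_adj is not None:
                        e = min(e, d_adj + stack_energy_centi(a[i - 1], b[j + 1], a[i], b[j]))
                    # join across a bulge: no stack term
                    if i > 1 or j < nb - 2:
                        gap = 10 ** 9
                        if i > 1:
                            gap = min(gap, pmin[i - 2][j + 1])
                        if j < nb - 2:
                            gap = min(gap, pmin[i - 1][j + 2])
                        if gap < 10 ** 9:
                            e = min(e, gap)
                D[i][j] = e
                best_overall = min(best_overall, e)
            v = D[i][j] if D[i][j] is not None else 10 ** 9
            up = pmin[i - 1][j] if i > 0 else 10 ** 9
            right = pmin[i][j + 1] if j < nb - 1 else 10 ** 9
            pmin[i][j] = min(v, up, right)
    return best_overall / 100.0
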