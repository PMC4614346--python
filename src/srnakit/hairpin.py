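"""Novel miRNA discovery: genome placement, precursor excision, folding,
and hairpin/Dicer/MFE acceptance.

A candidate is accepted iff its precursor folds into a single stem-loop
with MFE <= the threshold, the mature tag is 20-24 nt, mostly paired,
does not span the terminal loop, and a star region with the 2-nt 3'
overhang duplex geometry fits inside the precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .fold import FoldResult, fold_mfe
from .tagio import TagCount

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class HairpinCriteria:
    max_mfe: float = -18.0
    min_mature_len: int = 20
    max_mature_len: int = 24
    min_paired_fraction: float = 0.75
    min_read_support: int = 3
    min_precursor_len: int = 60
    max_precursor_len: int = 100
    flank_5p: int = 15
    flank_3p: int = 85


@dataclass
class Placement:
    tag: str
    contig: str
    strand: str
    start: int  # forward-genomic, 0-based half-open
    end: int


@dataclass
class HairpinCandidate:
    name: str
    mature: str
    star: str
    precursor: str
    structure: str
    mfe: float
    arm: str  # 5p or 3p
    contig: str
    strand: str
    start: int  # precursor genomic span, 0-based half-open
    end: int
    mature_offset: int = 0
    counts: dict = field(default_factory=dict)


def map_unannotated(tags: Iterable[TagCount], genome: dict) -> list:
    """All exact occurrences of each tag on either genome strand."""
    placements = []
    for tag in tags:
        seq = tag.sequence
        rc = revcomp(seq)
        for contig, ref in genome.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                pos = ref.find(query)
                while pos >= 0:
                    placements.append(Placement(seq, contig, strand,
                                                pos, pos + len(seq)))
                    pos = ref.find(query, pos + 1)
    return placements


def extract_precursors(placement: Placement, genome: dict,
                       criteria: HairpinCriteria = HairpinCriteria()) -> list:
    """Up to two candidate precursor windows around a placement.

    Returns (precursor sequence, mature offset, genomic start, genomic end)
    tuples oriented 5'->3' on the placement strand; windows running off the
    contig are clipped, and clipped windows shorter than the minimum
    precursor length are dropped.
    """
    ref = genome[placement.contig]
    n = len(ref)
    if placement.strand == "+":
        t0, t1 = placement.start, placement.end
        oriented = ref
    else:
        oriented = revcomp(ref)
        t0, t1 = n - placement.end, n - placement.start
    length = t1 - t0
    out = []
    windows = (
        (t0 - criteria.flank_5p, t0 - criteria.flank_5p + criteria.max_precursor_len),
        (t1 + criteria.flank_5p - criteria.max_precursor_len, t1 + criteria.flank_5p),
    )
    seen = set()
    for a, b in windows:
        a, b = max(0, a), min(n, b)
        if a > t0 or b < t1:  # window must still contain the tag
            a, b = min(a, t0), max(b, t1)
        if b - a < criteria.min_precursor_len:
            continue
        if (a, b) in seen:
            continue
        seen.add((a, b))
        seq = oriented[a:b]
        offset = t0 - a
        if placement.strand == "+":
            g0, g1 = a, b
        else:
            g0, g1 = n - b, n - a
        out.append((seq, offset, g0, g1))
    return out


def _hairpin_loops(structure: str) -> list:
    """Spans of terminal (hairpin) loops in a dot-bracket string."""
    loops = []
    last_open = None
    for i, c in enumerate(structure):
        if c == "(":
            last_open = i
        elif c == ")":
            if last_open is not None:
                loops.append((last_open + 1, i))
                last_open = None
    return loops


def evaluate_hairpin(precursor: str, mature_offset: int, mature_len: int,
                     fold: FoldResult,
                     criteria: HairpinCriteria = HairpinCriteria()):
    """(accepted-candidate-fields, None) or (None, rejection reason)."""
    if not (criteria.min_mature_len <= mature_len <= criteria.max_mature_len):
        return None, "length"
    if fold.mfe > criteria.max_mfe:
        return None, "mfe"
    loops = _hairpin_loops(fold.structure)
    if len(loops) != 1:
        return None, "multiloop" if loops else "unstructured"
    loop_lo, loop_hi = loops[0]
    m0, m1 = mature_offset, mature_offset + mature_len
    if not (m1 <= loop_lo or m0 >= loop_hi):
        return None, "loop"
    arm = "5p" if m1 <= loop_lo else "3p"
    pairs = fold.pairs
    paired = [p for p in range(m0, m1) if p in pairs]
    if len(paired) / mature_len < criteria.min_paired_fraction:
        return None, "pairing"

    def project(pos: int) -> Optional[int]:
        # nearest paired mature base within 4 nt, extended antiparallel
        for d in range(0, 5):
            for q in (pos - d, pos + d):
                if m0 <= q < m1 and q in pairs:
                    return pairs[q] + (q - pos)
        return None

    p0 = project(m0)
    p2 = project(m1 - 3)
    if p0 is None or p2 is None:
        return None, "dicer"
    s_lo, s_hi = min(p2, p0 + 3), max(p2, p0 + 3)
    if s_lo < 0 or s_hi > len(precursor):
        return None, "dicer"
    if not (s_hi <= m0 or s_lo >= m1):
        return None, "dicer"
    star = precursor[s_lo:s_hi]
    return {"arm": arm, "star": star, "star_span": (s_lo, s_hi)}, None


def _top_level_components(structure: str) -> list:
    """Spans of outermost pairs (0-based half-open) in a dot-bracket string."""
    depth = 0
    comps = []
    start = None
    for i, c in enumerate(structure):
        if c == "(":
            if depth == 0:
                start = i
            depth += 1
        elif c == ")":
            depth -= 1
            if depth == 0:
                comps.append((start, i + 1))
    return comps


def refine_window(window: str, mature_offset: int, mature_len: int,
                  fold: FoldResult,
                  criteria: HairpinCriteria = HairpinCriteria()):
    """Excise the stem-loop component that holds the mature tag.

    A wide excision window often folds into the real hairpin plus small
    side stems; this keeps only the component overlapping the mature,
    padded within the window up to the minimum precursor length.  Returns
    (start, end) of the trimmed span in window coordinates, or None.
    """
    m0, m1 = mature_offset, mature_offset + mature_len
    span = None
    for a, b in _top_level_components(fold.structure):
        if a < m1 and m0 < b:
            if span is not None:
                return None  # mature touches two components: not a hairpin
            span = (a, b)
    if span is None:
        return None
    a, b = min(span[0], m0), max(span[1], m1)
    while b - a < criteria.min_precursor_len and (a > 0 or b < len(window)):
        if a > 0:
            a -= 1
        if b < len(window) and b - a < criteria.min_precursor_len:
            b += 1
    if b - a < criteria.min_precursor_len:
        return None
    return a, b


def name_candidates(accepted: list, prefix: str = "Ofu") -> list:
    """Assign sequential zero-padded names; keep same-sequence loci apart."""
    ordered = sorted(accepted, key=lambda c: (c.contig, c.start, c.strand, c.arm))
    seen = set()
    out = []
    for c in ordered:
        key = (c.contig, c.strand, c.start, c.end, c.mature)
        if key in seen:
            continue
        seen.add(key)
        c.name = f"{prefix}-m{len(out) + 1:04d}_{c.arm}"
        out.append(c)
    return out


def discover_novel(tags: Iterable[TagCount], genome: dict,
                   criteria: HairpinCriteria = HairpinCriteria(),
                   prefix: str = "Ofu") -> list:
    """Full novel-miRNA pass over unannotated tags."""
    tags = [t for t in tags
            if t.total >= criteria.min_read_support
            and criteria.min_mature_len <= len(t.sequence) <= criteria.max_mature_len]
    counts = {t.sequence: t.counts for t in tags}
    fold_cache: dict = {}
    accepted = []
    for placement in map_unannotated(tags, genome):
        best = None
        for window, w_offset, w_g0, w_g1 in extract_precursors(placement, genome,
                                                               criteria):
            fold = fold_cache.get(window)
            if fold is None:
                fold = fold_cache[window] = fold_mfe(window)
            mature_len = len(placement.tag)
            seq, offset, g0, g1 = window, w_offset, w_g0, w_g1
            verdict, reason = evaluate_hairpin(seq, offset, mature_len,
                                               fold, criteria)
            for _ in range(3):  # iteratively excise side stems
                if verdict is not None or reason != "multiloop":
                    break
                trimmed = refine_window(seq, offset, mature_len, fold, criteria)
                if trimmed is None or trimmed == (0, len(seq)):
                    break
                a, b = trimmed
                seq = seq[a:b]
                offset -= a
                if placement.strand == "+":
                    g0, g1 = g0 + a, g0 + b
                else:
                    g0, g1 = g1 - b, g1 - a
                fold = fold_cache.get(seq)
                if fold is None:
                    fold = fold_cache[seq] = fold_mfe(seq)
                verdict, reason = evaluate_hairpin(seq, offset, mature_len,
                                                   fold, criteria)
            if verdict is None:
                continue
            cand = HairpinCandidate(
                name="", mature=placement.tag, star=verdict["star"],
                precursor=seq, structure=fold.structure, mfe=fold.mfe,
                arm=verdict["arm"], contig=placement.contig,
                strand=placement.strand, start=g0, end=g1,
                mature_offset=offset,
                counts=dict(counts[placement.tag]),
            )
            if best is None or cand.mfe < best.mfe:
                best = cand
        if best is not None:
            accepted.append(best)
    return name_candidates(accepted, prefix)
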