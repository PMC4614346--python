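"""Tag annotation: one category per unique tag plus known-miRNA naming.

The category priority is rRNAetc (GenBank before Rfam) > known miRNA >
repeat > exon > intron > unannotated, so a tag matching several references
is assigned to the highest-priority one only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .tagio import TagCount, normalize_tag

PRIORITY = ("rRNAetc_genbank", "rRNAetc_rfam", "known_miRNA",
            "repeat", "exon", "intron", "unann")


@dataclass
class CategoryAssignment:
    sequence: str
    category: str
    reference: Optional[str] = None


@dataclass
class KnownMiRNAHit:
    """All tag variants of one reference mature miRNA, pooled."""

    name: str
    reference: str
    representative: str  # the variant with the most reads
    counts: dict = field(default_factory=dict)
    variants: list = field(default_factory=list)
    note: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _substring_index(refs: dict) -> str:
    # concatenate with separators so a tag can be located by plain find()
    return "#" + "#".join(refs.values()) + "#"


class SequenceSet:
    """Reference sequences queried for exact substring membership of a tag."""

    def __init__(self, refs: dict):
        self.refs = {k: normalize_tag(v) for k, v in refs.items()}
        self._blob = _substring_index(self.refs)

    def lookup(self, tag: str) -> Optional[str]:
        if self._blob.find(tag) < 0:
            return None
        for name, seq in self.refs.items():
            if tag in seq:
                return name
        return None


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class MatureLocus:
    name: str
    sequence: str
    precursor: str
    start: int  # position of the mature within its precursor


def index_mirna_db(mature: dict, precursors: dict) -> list:
    """Locate each mature sequence inside its precursor(s).

    Mature entries whose id has no precursor counterpart are matched
    against every precursor; a mature with no precursor hit is kept as a
    free-standing locus (start -1) and matched directly.
    """
    loci = []
    for name, mseq in mature.items():
        mseq = normalize_tag(mseq)
        placed = False
        for pname, pseq in precursors.items():
            pos = pseq.find(mseq)
            if pos >= 0 and (pname in name or name in pname
                             or _stem(pname) == _stem(name)):
                loci.append(MatureLocus(name, mseq, pseq, pos))
                placed = True
        if not placed:
            for pname, pseq in precursors.items():
                pos = pseq.find(mseq)
                if pos >= 0:
                    loci.append(MatureLocus(name, mseq, pseq, pos))
                    placed = True
                    break
        if not placed:
            loci.append(MatureLocus(name, mseq, mseq, 0))
    return loci


def _stem(name: str) -> str:
    base = name.split()[0]
    for suffix in ("-5p", "-3p", "_5p", "_3p"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base


def match_tag_to_locus(tag: str, locus: MatureLocus, end_shift: int = 2,
                       max_mismatch: int = 2) -> Optional[str]:
    """Alignment description if the tag sits within +/-end_shift of the
    mature ends on the precursor with <= max_mismatch substitutions."""
    m0 = locus.start
    m1 = locus.start + len(locus.sequence)
    prec = locus.precursor
    best = None
    for start in range(m0 - end_shift, m0 + end_shift + 1):
        if start < 0 or start + len(tag) > len(prec):
            continue
        end = start + len(tag)
        if abs(end - m1) > end_shift:
            continue
        mism = _hamming(tag, prec[start:end])
        if mism <= max_mismatch and (best is None or mism < best[0]):
            best = (mism, start - m0)
    if best is None:
        return None
    return f"shift={best[1]:+d},mm={best[0]}"


def assign_name(reference: str, prefix: str = "Ofu") -> str:
    """Species-prefix the reference id (dme-miR-1-3p -> Ofu-miR-1-3p)."""
    parts = reference.split("-")
    if len(parts) > 1 and parts[0].islower() and len(parts[0]) <= 4:
        parts = parts[1:]
    return f"{prefix}-" + "-".join(parts)


def match_known_mirnas(tags: Iterable[TagCount], mature: dict, precursors: dict,
                       end_shift: int = 2, max_mismatch: int = 2,
                       prefix: str = "Ofu") -> list:
    """Pool tag variants under named known-miRNA hits.

    The best-scoring reference wins per tag (fewest mismatches, ties broken
    by lexicographic reference id); variants of one reference are pooled
    and the representative is the variant with the most reads.
    """
    if not mature:
        raise ValueError("empty miRNA database")
    loci = index_mirna_db(mature, precursors)
    hits: dict = {}
    for tag in tags:
        best = None
        for locus in sorted(loci, key=lambda l: l.name):
            desc = match_tag_to_locus(tag.sequence, locus, end_shift, max_mismatch)
            if desc is None:
                continue
            mism = int(desc.split("mm=")[1])
            if best is None or mism < best[0]:
                best = (mism, locus.name, desc)
        if best is None:
            continue
        _, ref, desc = best
        hit = hits.get(ref)
        if hit is None:
            hit = hits[ref] = KnownMiRNAHit(assign_name(ref, prefix), ref,
                                            tag.sequence, {}, [])
        hit.variants.append((tag.sequence, tag.total, desc))
        for lib, c in tag.counts.items():
            hit.counts[lib] = hit.counts.get(lib, 0) + c
    for hit in hits.values():
        hit.representative = max(hit.variants, key=lambda v: (v[1], v[0]))[0]
        hit.note = ";".join(v[2] for v in hit.variants)
    return sorted(hits.values(), key=lambda h: (-h.total, h.name))


class GenomeIntervals:
    """BED-like category intervals over genome contigs (0-based half-open)."""

    def __init__(self, genome: dict, rows: list):
        self.genome = genome
        self.rows = rows

    def lookup(self, tag: str, category: str) -> Optional[str]:
        for contig, start, end, cat in self.rows:
            if cat != category:
                continue
            seq = self.genome.get(contig)
            if seq is None:
                continue
            pos = seq.find(tag, start)
            if 0 <= pos and pos + len(tag) <= end:
                return f"{contig}:{start}-{end}"
        return None


def classify_tags(tags: Iterable[TagCount], genbank: Optional[SequenceSet] = None,
                  rfam: Optional[SequenceSet] = None,
                  mature: Optional[dict] = None, precursors: Optional[dict] = None,
                  intervals: Optional[GenomeIntervals] = None,
                  end_shift: int = 2, max_mismatch: int = 2,
                  prefix: str = "Ofu"):
    """(assignments, known-miRNA hits, composition table).

    The composition table reports unique and total counts per category;
    unique counts partition the input tags.
    """
    tags = list(tags)
    assignments = []
    mirna_hits: list = []
    mirna_tag_names: dict = {}
    if mature:
        candidates = [t for t in tags]
        hits = match_known_mirnas(candidates, mature, precursors or {},
                                  end_shift, max_mismatch, prefix)
        for hit in hits:
            for variant, _, _ in hit.variants:
                mirna_tag_names[variant] = hit.reference
        mirna_hits = hits

    claimed_by_rna = set()
    for tag in tags:
        seq = tag.sequence
        category, ref = "unann", None
        if genbank is not None and (ref := genbank.lookup(seq)) is not None:
            category = "rRNAetc_genbank"
        elif rfam is not None and (ref := rfam.lookup(seq)) is not None:
            category = "rRNAetc_rfam"
        elif seq in mirna_tag_names:
            category, ref = "known_miRNA", mirna_tag_names[seq]
        elif intervals is not None:
            for cat in ("repeat", "exon", "intron"):
                if (ref := intervals.lookup(seq, cat)) is not None:
                    category = cat
                    break
        if category in ("rRNAetc_genbank", "rRNAetc_rfam") and seq in mirna_tag_names:
            claimed_by_rna.add(seq)
        assignments.append(CategoryAssignment(seq, category, ref))

    if claimed_by_rna:  # priority rule: rRNAetc beats known miRNA
        pruned = []
        for hit in mirna_hits:
            keep = [v for v in hit.variants if v[0] not in claimed_by_rna]
            if not keep:
                continue
            hit.variants = keep
            hit.counts = {}
            for tag in tags:
                if any(tag.sequence == v[0] for v in keep):
                    for lib, c in tag.counts.items():
                        hit.counts[lib] = hit.counts.get(lib, 0) + c
            hit.representative = max(keep, key=lambda v: (v[1], v[0]))[0]
            pruned.append(hit)
        mirna_hits = pruned

    totals = {t.sequence: t.total for t in tags}
    composition: dict = {}
    for a in assignments:
        row = composition.setdefault(a.category, {"unique": 0, "total": 0})
        row["unique"] += 1
        row["total"] += totals[a.sequence]
    return assignments, mirna_hits, composition
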