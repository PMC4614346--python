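"""Read-cleaning cascade, per-library accounting, length histogram, overlaps.

Each high-quality read is assigned to exactly one category, tested in a
fixed priority order so the accounting identity

    high_quality = adapter3_null + insert_null + adapter5_contaminant
                   + shorter_than_18 + polyA + clean_reads

always holds.  Low-quality reads are excluded before the accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .tagio import ReadRecord, TagCount

CATEGORIES = ("adapter3_null", "insert_null", "adapter5_contaminant",
              "shorter_than_18", "polyA", "clean")

# standard Illumina small-RNA adapters, used when a config omits them
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass
class CleanParams:
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    min_len: int = 18
    max_len: int = 30
    min_quality: int = 5
    max_n_fraction: float = 0.10
    polyA_fraction: float = 0.8
    adapter_min_overlap: int = 6
    adapter_max_mismatch: int = 1

    def __post_init__(self):
        if not self.adapter_3p or not self.adapter_5p:
            raise ValueError("adapter sequences must be non-empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0 < self.polyA_fraction <= 1:
            raise ValueError("polyA_fraction must be in (0, 1]")


@dataclass
class LibrarySummary:
    """Per-library cleaning accounting (the five filters plus clean reads)."""

    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminant: int = 0
    shorter_than_18: int = 0
    polyA: int = 0
    clean_reads: int = 0
    low_quality: int = 0  # excluded from high_quality

    def check_identity(self) -> bool:
        return self.high_quality == (self.adapter3_null + self.insert_null
                                     + self.adapter5_contaminant
                                     + self.shorter_than_18 + self.polyA
                                     + self.clean_reads)

    def percentages(self) -> dict:
        if self.high_quality == 0:
            return {}
        return {k: 100.0 * getattr(self, k) / self.high_quality
                for k in ("adapter3_null", "insert_null", "adapter5_contaminant",
                          "shorter_than_18", "polyA", "clean_reads")}

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("high_quality", "adapter3_null", "insert_null",
                 "adapter5_contaminant", "shorter_than_18", "polyA",
                 "clean_reads", "low_quality")}


def clean_reads_identity(high_quality: int, adapter3_null: int, insert_null: int,
                         adapter5_contaminant: int, shorter_than_18: int,
                         polyA: int) -> int:
    """Clean-read count implied by the accounting identity."""
    return (high_quality - adapter3_null - insert_null - adapter5_contaminant
            - shorter_than_18 - polyA)


def find_adapter(seq: str, adapter: str, min_overlap: int, max_mismatch: int) -> int:
    """Leftmost start of a 3'-adapter match, or -1.

    A match at position p uses the first min(len(adapter), len(seq)-p)
    adapter bases; it requires at least ``min_overlap`` overlapping bases
    and at most ``max_mismatch`` mismatches.
    """
    n, m = len(seq), len(adapter)
    for p in range(0, n - min_overlap + 1):
        span = min(m, n - p)
        mism = 0
        ok = True
        for k in range(span):
            if seq[p + k] != adapter[k]:
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            return p
    return -1


def _matches_prefix(seq: str, adapter: str, max_mismatch: int) -> bool:
    if len(seq) < len(adapter):
        return False
    mism = sum(1 for a, b in zip(seq, adapter) if a != b)
    return mism <= max_mismatch


def is_low_quality(read: ReadRecord, params: CleanParams) -> bool:
    if read.quality and min(read.quality) < params.min_quality:
        return True
    n = len(read.sequence)
    return n > 0 and read.sequence.count("N") / n > params.max_n_fraction


def categorize(read: ReadRecord, params: CleanParams):
    """(category, insert-or-None); category 'low_quality' precedes the rest."""
    seq = read.sequence
    if is_low_quality(read, params):
        return "low_quality", None
    if _matches_prefix(seq, params.adapter_5p, params.adapter_max_mismatch):
        return "adapter5_contaminant", None
    pos = find_adapter(seq, params.adapter_3p, params.adapter_min_overlap,
                       params.adapter_max_mismatch)
    if pos < 0:
        return "adapter3_null", None
    if pos == 0:
        return "insert_null", None
    insert = seq[:pos]
    if insert.count("A") / len(insert) >= params.polyA_fraction:
        return "polyA", None
    if len(insert) < params.min_len:
        return "shorter_than_18", None
    return "clean", insert


def trim_and_filter(reads: Iterable[ReadRecord], params: CleanParams):
    """Clean inserts plus the per-library accounting summary."""
    summary = LibrarySummary()
    inserts = []
    for read in reads:
        category, insert = categorize(read, params)
        if category == "low_quality":
            summary.low_quality += 1
            continue
        summary.high_quality += 1
        if category == "clean":
            summary.clean_reads += 1
            inserts.append(insert)
        else:
            setattr(summary, category, getattr(summary, category) + 1)
    return inserts, summary


def length_distribution(tags: Iterable[TagCount], min_len: int = 18,
                        max_len: int = 30) -> dict:
    """Histogram of total reads by insert length over [min_len, max_len]."""
    hist = {n: 0 for n in range(min_len, max_len + 1)}
    for tag in tags:
        n = len(tag.sequence)
        if min_len <= n <= max_len:
            hist[n] += tag.total
    return hist


def common_specific(tags_a: Iterable[TagCount], tags_b: Iterable[TagCount]) -> dict:
    """Unique/total tag overlap between two libraries (Venn summary)."""
    ca = {t.sequence: t.total for t in tags_a}
    cb = {t.sequence: t.total for t in tags_b}
    common = set(ca) & set(cb)
    only_a = set(ca) - common
    only_b = set(cb) - common
    return {
        "common_unique": len(common),
        "A_specific_unique": len(only_a),
        "B_specific_unique": len(only_b),
        "common_total": sum(ca[s] for s in common) + sum(cb[s] for s in common),
        "A_specific_total": sum(ca[s] for s in only_a),
        "B_specific_total": sum(cb[s] for s in only_b),
    }
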