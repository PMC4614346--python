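"""Readers/writers for the on-disk formats and the shared tag-collapsing step.

Coordinates are 0-based half-open internally; GFF3 output converts to
1-based closed.  Tag sequences are normalized to uppercase DNA (U -> T).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

_VALID = set("ACGTN")


class ParseError(ValueError):
    pass


def normalize_tag(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: tuple  # per-base Phred scores

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence/quality length mismatch")


@dataclass
class TagCount:
    """A unique insert sequence with per-library raw counts."""

    sequence: str
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream Phred+33 FASTQ records; raises ParseError with a line number."""
    with _open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"line {lineno}: expected '@' header")
            block = [fh.readline() for _ in range(3)]
            if any(not l for l in block):
                raise ParseError(f"line {lineno}: truncated FASTQ record")
            seq = block[0].strip().upper()
            plus = block[1].strip()
            qual = block[2].strip()
            if not plus.startswith("+"):
                raise ParseError(f"line {lineno + 2}: expected '+' separator")
            if set(seq) - _VALID:
                raise ParseError(f"line {lineno + 1}: non-IUPAC character in sequence")
            if len(seq) != len(qual):
                raise ParseError(f"line {lineno + 3}: sequence/quality length mismatch")
            lineno += 3
            yield ReadRecord(header[1:].strip().split()[0], seq,
                             tuple(ord(c) - 33 for c in qual))


def write_fastq(records: Iterable[tuple], path) -> None:
    """Write (id, sequence, quality-string) triples."""
    with _open(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fasta(path) -> dict:
    """Ordered {id: sequence}; sequences uppercased with U -> T."""
    out: dict = {}
    name = None
    chunks: list = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = normalize_tag("".join(chunks))
                name = line[1:].split()[0]
                chunks = []
            elif name is None:
                raise ParseError(f"line {lineno}: sequence before FASTA header")
            else:
                chunks.append(line)
        if name is not None:
            out[name] = normalize_tag("".join(chunks))
    return out


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def collapse_tags(reads: Iterable[tuple]) -> list:
    """Collapse (library-id, insert) pairs into per-sequence TagCounts.

    One entry per distinct sequence, counts partitioned by library; the
    grand total is conserved.  Output ordered by first appearance.
    """
    tags: dict = {}
    for lib, seq in reads:
        seq = normalize_tag(seq)
        tc = tags.get(seq)
        if tc is None:
            tc = tags[seq] = TagCount(seq, {})
        tc.counts[lib] = tc.counts.get(lib, 0) + 1
    return list(tags.values())


def write_counts(tags: Iterable[TagCount], libraries: list, path) -> None:
    rows = [[t.sequence] + [t.counts.get(lib, 0) for lib in libraries] for t in tags]
    df = pd.DataFrame(rows, columns=["sequence"] + list(libraries))
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple:
    """Return (list of TagCount, library ids) from a TSV count matrix."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"malformed count matrix {path}: {exc}") from exc
    if df.columns[0] != "sequence":
        raise ParseError("count matrix must start with a 'sequence' column")
    libs = list(df.columns[1:])
    tags = []
    for _, row in df.iterrows():
        counts = {lib: int(row[lib]) for lib in libs if int(row[lib]) != 0}
        tags.append(TagCount(str(row["sequence"]), counts))
    return tags, libs


def write_gff(candidates: Iterable, path, source: str = "srnakit") -> None:
    """Write hairpin candidates as GFF3 (converting to 1-based closed)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            contig, start, end = c.contig, c.start, c.end
            attrs = f"ID={c.name};mature={c.mature};energy={c.mfe:.2f}"
            fh.write("\t".join([
                contig, source, "pre_miRNA", str(start + 1), str(end),
                f"{c.mfe:.2f}", c.strand, ".", attrs,
            ]) + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_map(path) -> dict:
    """2-column TSV gene -> term (one pair per line) into {gene: set(terms)}."""
    mapping: dict = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 2 columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def write_gene_map(mapping: dict, path) -> None:
    with _open(path, "wt") as fh:
        for gene in mapping:
            for term in sorted(mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_bed(path) -> list:
    """BED-like rows (contig, start, end, category) with 0-based half-open spans."""
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"line {lineno}: expected 4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return rows


def write_bed(rows: Iterable[tuple], path) -> None:
    with _open(path, "wt") as fh:
        for contig, start, end, category in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{category}\n")
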