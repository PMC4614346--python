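"""miRNA target prediction by complementarity penalty and duplex energy.

A site is scored antiparallel against the miRNA: mismatches and gaps cost
1, G·U wobbles 0.5, doubled inside the 5' core (miRNA positions 2-13).
Sites passing both the penalty cutoff and the duplex-energy cutoff are
reported, keeping the best site per (miRNA, transcript) overlap group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .fold import can_pair, duplex_mfe

CORE_START = 2   # 1-based miRNA positions with doubled penalties
CORE_END = 13


@dataclass(frozen=True)
class TargetPrediction:
    mirna: str
    transcript: str
    start: int  # site span on the transcript, 0-based half-open
    end: int
    penalty: float
    duplex_mfe: float
    site: str


@dataclass
class TargetThresholds:
    max_penalty: float = 4.0
    max_energy: float = -20.0


def penalty_score(mirna: str, site: str) -> float:
    """Allen/Schwab-style penalty of an antiparallel miRNA:site alignment.

    Both sequences are 5'->3' and must have equal length after gapping
    ('-' allowed).  Position numbering follows miRNA bases from its 5'
    end; a gap column inherits the current position.
    """
    if not mirna or not site:
        raise ValueError("empty sequence")
    if len(mirna) != len(site):
        raise ValueError("aligned sequences must have equal length")
    m = mirna.upper().replace("T", "U")
    s = site.upper().replace("T", "U")
    if (set(m) | set(s)) - set("ACGUN-"):
        raise ValueError("non-nucleotide characters in alignment")
    s = s[::-1]  # antiparallel: miRNA 5' aligns to site 3'
    penalty = 0.0
    pos = 0
    for a, b in zip(m, s):
        if a != "-":
            pos += 1
        if a == "-" or b == "-":
            cost = 1.0
        elif can_pair(a, b):
            cost = 0.5 if (a, b) in (("G", "U"), ("U", "G")) else 0.0
        else:
            cost = 1.0
        if CORE_START <= pos <= CORE_END:
            cost *= 2
        penalty += cost
    return penalty


def scan_targets(mirnas: dict, transcripts: dict,
                 thresholds: TargetThresholds = TargetThresholds()) -> list:
    """Score every gapless window of every transcript against each miRNA.

    Overlapping passing windows for one (miRNA, transcript) pair are merged
    to the best-scoring one (lowest penalty, then lowest energy, then
    5'-most).  Output is sorted and independent of input order.
    """
    predictions = []
    for mname in sorted(mirnas):
        mseq = mirnas[mname]
        L = len(mseq)
        for tname in sorted(transcripts):
            tseq = transcripts[tname]
            hits = []
            for start in range(0, len(tseq) - L + 1):
                site = tseq[start:start + L]
                pen = penalty_score(mseq, site)
                if pen > thresholds.max_penalty:
                    continue
                e = duplex_mfe(mseq, site)
                if e > thresholds.max_energy:
                    continue
                hits.append(TargetPrediction(mname, tname, start, start + L,
                                             pen, e, site))
            predictions.extend(_merge_overlaps(hits))
    predictions.sort(key=lambda p: (p.mirna, p.transcript, p.start))
    return predictions


def _merge_overlaps(hits: list) -> list:
    hits = sorted(hits, key=lambda h: h.start)
    merged = []
    group: list = []
    for h in hits:
        if group and h.start < group[-1].end:
            group.append(h)
        else:
            if group:
                merged.append(_best(group))
            group = [h]
    if group:
        merged.append(_best(group))
    return merged


def _best(group: list) -> TargetPrediction:
    return min(group, key=lambda h: (h.penalty, h.duplex_mfe, h.start))
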