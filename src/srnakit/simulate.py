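"""Ground-truth synthetic corpus generator.

Produces every input the pipeline consumes: genome-like contigs with
planted hairpin loci, a known-miRNA database, transcripts carrying planted
complementary target sites, category reference sets, annotation maps, and
raw FASTQ libraries with adapters and the five contaminant classes.  The
contaminant constructions mirror the cleaning module's detectors exactly,
so the expected per-library accounting is known a priori.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import tagio
from .cleaning import (CleanParams, DEFAULT_ADAPTER_3P, DEFAULT_ADAPTER_5P,
                       LibrarySummary, categorize, find_adapter)
from .fold import fold_mfe
from .hairpin import HairpinCriteria, evaluate_hairpin, revcomp
from .tagio import ReadRecord

_BASES = np.array(list("ACGT"))

CONTAMINANT_KEYS = ("adapter3_null", "insert_null", "adapter5_contaminant",
                    "shorter_than_18", "polyA")


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_known_mirnas: int = 30
    n_novel_loci: int = 4
    n_transcripts: int = 20
    n_contigs: int = 2
    contig_length: int = 4000
    transcript_length: int = 600
    read_length: int = 50
    library_depths: dict = field(default_factory=lambda: {
        "control-1": 5000, "control-2": 5000,
        "treated-1": 5000, "treated-2": 5000,
    })
    contamination_rates: dict = field(default_factory=lambda: {
        "adapter3_null": 0.002, "insert_null": 0.001,
        "adapter5_contaminant": 0.002, "shorter_than_18": 0.02,
        "polyA": 0.001,
    })
    low_quality_rate: float = 0.0
    de_effects: dict = field(default_factory=dict)
    n_de: int = 4          # auto-planted DE miRNAs when de_effects is empty
    de_lfc: float = 4.0
    dispersion: float = 0.0
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    mirna_fraction: float = 0.35   # of clean reads
    novel_fraction: float = 0.05
    background_fractions: dict = field(default_factory=lambda: {
        "rRNAetc_genbank": 0.35, "rRNAetc_rfam": 0.25, "genome": 0.40,
    })
    n_background_fragments: int = 24
    n_genbank_refs: int = 4
    n_rfam_refs: int = 6
    n_target_sites: int = 1        # planted sites per known miRNA
    n_go_terms: int = 15
    n_kegg_terms: int = 8
    mfe_threshold: float = -18.0

    def __post_init__(self):
        for lib, depth in self.library_depths.items():
            if depth <= 0:
                raise SimConfigError(f"library_depths[{lib}] must be > 0")
        total = 0.0
        for key, rate in self.contamination_rates.items():
            if not 0 <= rate < 1:
                raise SimConfigError(
                    f"contamination_rates[{key}] must be in [0, 1)")
            total += rate
        if total + self.low_quality_rate >= 1:
            raise SimConfigError("contamination_rates must sum to < 1")
        if self.n_known_mirnas < 0:
            raise SimConfigError("n_known_mirnas must be >= 0")
        if self.n_novel_loci < 0:
            raise SimConfigError("n_novel_loci must be >= 0")
        if not self.adapter_3p or not self.adapter_5p:
            raise SimConfigError("adapter_3p/adapter_5p must be non-empty")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be non-negative")

    def clean_params(self) -> CleanParams:
        return CleanParams(adapter_3p=self.adapter_3p, adapter_5p=self.adapter_5p)

    @property
    def libraries(self) -> list:
        return list(self.library_depths)

    def condition(self, library: str) -> str:
        return "treated" if library.startswith("treated") else "control"


@dataclass
class NovelLocus:
    name: str
    contig: str
    strand: str
    start: int
    end: int
    arm: str
    mature: str
    star: str
    precursor: str
    mfe: float
    mean_control: float = 0.0
    mean_treated: float = 0.0


@dataclass
class TruthTable:
    known: dict = field(default_factory=dict)   # name -> truth record
    novel: list = field(default_factory=list)   # NovelLocus
    targets: list = field(default_factory=list)  # (mirna, transcript, start, end)
    de_set: dict = field(default_factory=dict)  # name -> true lfc

    def to_json(self) -> str:
        return json.dumps({
            "known": self.known,
            "novel": [asdict(n) for n in self.novel],
            "targets": self.targets,
            "de_set": self.de_set,
        }, indent=1)


@dataclass
class ReferenceBundle:
    genome: dict
    mature_db: dict
    precursor_db: dict
    transcripts: dict
    genbank_refs: dict
    rfam_refs: dict
    intervals: list
    gene2go: dict
    gene2kegg: dict
    truth: TruthTable
    background_pool: dict = field(default_factory=dict)  # class -> [fragments]

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, data in [("genome", self.genome), ("mature", self.mature_db),
                           ("hairpin", self.precursor_db),
                           ("transcripts", self.transcripts),
                           ("genbank", self.genbank_refs),
                           ("rfam", self.rfam_refs)]:
            paths[name] = str(outdir / f"{name}.fa")
            tagio.write_fasta(data, paths[name])
        paths["intervals"] = str(outdir / "intervals.bed")
        tagio.write_bed(self.intervals, paths["intervals"])
        paths["gene2go"] = str(outdir / "gene2go.tsv")
        tagio.write_gene_map(self.gene2go, paths["gene2go"])
        paths["gene2kegg"] = str(outdir / "gene2kegg.tsv")
        tagio.write_gene_map(self.gene2kegg, paths["gene2kegg"])
        paths["truth"] = str(outdir / "truth.json")
        Path(paths["truth"]).write_text(self.truth.to_json())
        return paths


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


class _CharStream:
    """Batched random nucleotide source (much faster than per-read draws)."""

    def __init__(self, rng, chunk: int = 1 << 16):
        self._rng = rng
        self._chunk = chunk
        self._buf = ""
        self._pos = 0

    def take(self, n: int) -> str:
        if self._pos + n > len(self._buf):
            size = max(self._chunk, n)
            self._buf = "".join(self._rng.choice(_BASES, size=size))
            self._pos = 0
        out = self._buf[self._pos:self._pos + n]
        self._pos += n
        return out


def _insert_ok(seq: str, config: SimConfig) -> bool:
    """Screen an insert with the cleaning module's own detectors."""
    if not seq or "N" in seq:
        return False
    if seq.count("A") / len(seq) >= 0.8:
        return False
    probe = seq + config.adapter_3p
    return find_adapter(probe, config.adapter_3p, 6, 1) == len(seq)


def _draw_insert(rng, config: SimConfig, length: int, max_tries: int = 100) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if _insert_ok(seq, config):
            return seq
    raise RuntimeError("could not draw a screened insert")  # pragma: no cover


def _build_hairpin(rng, config: SimConfig, mature_len: int, arm: str,
                   criteria: HairpinCriteria, max_tries: int = 60):
    """(precursor, mature, star, offset, mfe) passing the hairpin criteria."""
    for _ in range(max_tries):
        mature = _draw_insert(rng, config, mature_len)
        loop = _random_seq(rng, 15)
        f5 = _random_seq(rng, 8)
        f3 = _random_seq(rng, 8)
        partner = revcomp(mature)
        if arm == "5p":
            precursor = f5 + mature + loop + partner + f3
            offset = len(f5)
        else:
            precursor = f5 + partner + loop + mature + f3
            offset = len(f5) + len(partner) + len(loop)
        fold = fold_mfe(precursor)
        verdict, _ = evaluate_hairpin(precursor, offset, mature_len, fold, criteria)
        if verdict is None or verdict["arm"] != arm:
            continue
        if fold.mfe > config.mfe_threshold:
            continue
        if precursor.count(mature) != 1:
            continue
        return precursor, mature, verdict["star"], offset, fold.mfe
    raise RuntimeError("could not build an acceptable hairpin")  # pragma: no cover


def simulate_reference(config: SimConfig) -> ReferenceBundle:
    """Generate references, annotation maps, and the ground-truth table."""
    rng = np.random.default_rng(config.seed)
    criteria = HairpinCriteria(max_mfe=config.mfe_threshold)
    truth = TruthTable()

    # --- known miRNA database (mature + precursor, foreign species ids)
    mature_db: dict = {}
    precursor_db: dict = {}
    seen = set()
    for i in range(config.n_known_mirnas):
        arm = "5p" if rng.random() < 0.5 else "3p"
        mature_len = int(rng.integers(20, 25))
        ref = f"dme-miR-{1001 + i}-{arm}"
        precursor, mature, star, offset, mfe = _build_hairpin(
            rng, config, mature_len, arm, criteria)
        if mature in seen:
            continue
        seen.add(mature)
        mature_db[ref] = mature
        precursor_db[f"dme-mir-{1001 + i}"] = precursor
        truth.known[ref] = {"mature": mature, "arm": arm,
                            "mean_control": 0.0, "mean_treated": 0.0}

    # --- DE assignment
    de_effects = dict(config.de_effects)
    names = list(mature_db)
    if not de_effects and config.n_de > 0:
        for k, name in enumerate(names[: config.n_de]):
            de_effects[name] = config.de_lfc * (1 if k % 2 == 0 else -1)
    stems = {_name_stem(n) for n in names}
    valid = set(names) | stems | {f"novel-{i + 1}" for i in range(config.n_novel_loci)}
    unknown = set(de_effects) - valid
    if unknown:
        raise SimConfigError(f"de_effects names unknown: {sorted(unknown)}")

    # --- genome contigs with planted hairpin loci and category intervals
    genome = {f"contig{c + 1}": list(_random_seq(rng, config.contig_length))
              for c in range(max(1, config.n_contigs))}
    contig_names = list(genome)
    intervals = []
    if config.contig_length >= 900:
        c0 = contig_names[0]
        intervals = [(c0, 100, 300, "repeat"), (c0, 400, 600, "exon"),
                     (c0, 700, 900, "intron")]
    novel: list = []
    pad = 20
    slot = 1000 if config.contig_length >= 1000 else 0
    for i in range(config.n_novel_loci):
        arm = "5p" if rng.random() < 0.5 else "3p"
        mature_len = int(rng.integers(20, 25))
        precursor, mature, star, offset, mfe = _build_hairpin(
            rng, config, mature_len, arm, criteria)
        contig = contig_names[i % len(contig_names)]
        base = slot + (i // len(contig_names)) * (len(precursor) + 2 * pad + 60)
        start = base + pad
        end = start + len(precursor)
        if end + pad > config.contig_length:
            raise SimConfigError("contig_length too small for n_novel_loci")
        seq = genome[contig]
        seq[base:start] = list("A" * pad)
        seq[start:end] = list(precursor)
        seq[end:end + pad] = list("A" * pad)
        novel.append(NovelLocus(f"novel-{i + 1}", contig, "+", start, end, arm,
                                mature, star, precursor, mfe))
    genome = {k: "".join(v) for k, v in genome.items()}
    for locus in novel:
        # the planted mature occurs once forward; its reverse complement is
        # the partner arm inside the same precursor, so exactly once too
        fwd = sum(g.count(locus.mature) for g in genome.values())
        rev = sum(g.count(revcomp(locus.mature)) for g in genome.values())
        if (fwd, rev) != (1, 1):
            raise RuntimeError("planted mature not unique; re-seed the config")
    truth.novel = novel

    # --- rRNA-etc reference sets
    genbank_refs = {f"gb|rRNA-{i + 1}": _random_seq(rng, 200)
                    for i in range(config.n_genbank_refs)}
    rfam_classes = ["tRNA", "snRNA", "snoRNA"]
    rfam_refs = {}
    for i in range(config.n_rfam_refs):
        cls = rfam_classes[i % len(rfam_classes)]
        rfam_refs[f"RF{i + 1:05d}_{cls}"] = _random_seq(rng, 120)

    # --- background tag pools (screened fragments)
    def _fragments(source_seqs: list, n: int) -> list:
        frags = []
        tries = 0
        while len(frags) < n and tries < n * 50:
            tries += 1
            src = source_seqs[int(rng.integers(0, len(source_seqs)))]
            flen = int(rng.integers(18, 31))
            if len(src) <= flen:
                continue
            p = int(rng.integers(0, len(src) - flen))
            frag = src[p:p + flen]
            if _insert_ok(frag, config) and frag not in frags:
                frags.append(frag)
        return frags

    n_frag = config.n_background_fragments
    pool = {
        "rRNAetc_genbank": _fragments(list(genbank_refs.values()), n_frag),
        "rRNAetc_rfam": _fragments(list(rfam_refs.values()), n_frag),
    }
    # unannotated genome fragments: drawn clear of planted loci and intervals
    tail_regions = [g[-1000:] if len(g) > 1000 else g for g in genome.values()]
    genome_frags = []
    for frag in _fragments(tail_regions, n_frag * 2):
        if any(frag in r.precursor for r in novel):
            continue
        if all(frag not in m for m in (list(genbank_refs.values())
                                       + list(rfam_refs.values()))):
            genome_frags.append(frag)
        if len(genome_frags) >= n_frag:
            break
    pool["genome"] = genome_frags

    # --- transcripts with planted complementary target sites
    transcripts = {f"tx{i + 1:03d}": _random_seq(rng, config.transcript_length)
                   for i in range(config.n_transcripts)}
    tx_names = list(transcripts)
    if tx_names:
        for k, (ref, mature) in enumerate(mature_db.items()):
            for s in range(config.n_target_sites):
                tx = tx_names[(k * config.n_target_sites + s) % len(tx_names)]
                site = revcomp(mature)
                seq = transcripts[tx]
                if len(seq) < len(site) + 20:
                    continue
                p = int(rng.integers(10, len(seq) - len(site) - 10))
                transcripts[tx] = seq[:p] + site + seq[p + len(site):]
                truth.targets.append([ref, tx, p, p + len(site)])

    # --- flat annotation maps
    go_terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    kegg_terms = [f"ko{i + 1:05d}" for i in range(config.n_kegg_terms)]
    gene2go, gene2kegg = {}, {}
    for tx in tx_names:
        gene2go[tx] = set(rng.choice(go_terms,
                                     size=int(rng.integers(1, 4)), replace=False))
        gene2kegg[tx] = set(rng.choice(kegg_terms,
                                       size=int(rng.integers(1, 3)), replace=False))

    # --- per-condition true means
    _assign_means(rng, config, truth, de_effects)
    truth.de_set = {name: rec["lfc"] for name, rec in truth.known.items()
                    if rec.get("lfc")}
    truth.de_set.update({n.name: _lookup_lfc(de_effects, n.name)
                         for n in truth.novel
                         if _lookup_lfc(de_effects, n.name)})

    return ReferenceBundle(genome, mature_db, precursor_db, transcripts,
                           genbank_refs, rfam_refs, intervals, gene2go,
                           gene2kegg, truth, pool)


def _name_stem(name: str) -> str:
    for suffix in ("-5p", "-3p"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def _lookup_lfc(de_effects: dict, name: str) -> float:
    # exact name first, then the arm-less stem (miR-1001 covers miR-1001-5p)
    if name in de_effects:
        return de_effects[name]
    return de_effects.get(_name_stem(name), 0.0)


def _assign_means(rng, config: SimConfig, truth: TruthTable, de_effects: dict):
    """True per-condition mean fractions (of library depth) per miRNA."""
    names = list(truth.known)
    contam = sum(config.contamination_rates.values()) + config.low_quality_rate
    clean_frac = 1.0 - contam
    if names:
        weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(names))
        weights /= weights.sum()
        for name, w in zip(names, weights):
            base = clean_frac * config.mirna_fraction * w
            lfc = _lookup_lfc(de_effects, name)
            truth.known[name]["mean_control"] = base
            truth.known[name]["mean_treated"] = base * 2.0 ** lfc
            truth.known[name]["lfc"] = lfc
    if truth.novel:
        weights = rng.lognormal(mean=0.0, sigma=0.5, size=len(truth.novel))
        weights /= weights.sum()
        for locus, w in zip(truth.novel, weights):
            base = clean_frac * config.novel_fraction * w
            lfc = _lookup_lfc(de_effects, locus.name)
            locus.mean_control = base
            locus.mean_treated = base * 2.0 ** lfc


def _nb_counts(rng, means: np.ndarray, dispersion: float) -> np.ndarray:
    means = np.asarray(means, dtype=float)
    if dispersion == 0:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def _build_read(rng, config: SimConfig, category: str):
    """(sequence, quality) for one read of the requested category; the
    result is re-checked with the cleaning detectors (rejection sampling)."""
    L = config.read_length
    params = config.clean_params()
    for _ in range(200):
        if category == "low_quality":
            seq = _random_seq(rng, L)
            qual = "#" * L  # Phred 2 < min_quality
        else:
            qual = "I" * L
            if category == "adapter3_null":
                seq = _random_seq(rng, L)
            elif category == "insert_null":
                seq = config.adapter_3p + _random_seq(rng, L)
            elif category == "adapter5_contaminant":
                seq = (config.adapter_5p + _draw_insert(rng, config, 21)
                       + config.adapter_3p + _random_seq(rng, L))
            elif category == "shorter_than_18":
                n = int(rng.integers(6, 18))
                seq = (_draw_insert(rng, config, n) + config.adapter_3p
                       + _random_seq(rng, L))
            elif category == "polyA":
                n = int(rng.integers(18, 31))
                seq = "A" * n + config.adapter_3p + _random_seq(rng, L)
            else:  # pragma: no cover
                raise ValueError(category)
            seq = seq[:L]
        got, _ = categorize(ReadRecord("x", seq, tuple(ord(c) - 33 for c in qual)),
                            params)
        if got == category:
            return seq, qual
    raise RuntimeError(f"failed to construct a {category} read")  # pragma: no cover


def _clean_read(config: SimConfig, insert: str, pad: str) -> str:
    return (insert + config.adapter_3p + pad)[: config.read_length]


def simulate_libraries(reference: ReferenceBundle, config: SimConfig,
                       outdir=None):
    """FASTQ libraries plus the expected per-library cleaning summary.

    Returns (reads, summaries, true_counts) where ``reads`` maps library ->
    list of (id, sequence, quality) and ``true_counts`` maps library ->
    {tag-source-name: count} for planted miRNA/novel sequences.  When
    ``outdir`` is given the FASTQ files are also written there.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = reference.truth
    params = config.clean_params()
    reads: dict = {}
    summaries: dict = {}
    true_counts: dict = {}

    bg_classes = [c for c in config.background_fractions if reference.background_pool.get(c)]
    bg_weights = np.array([config.background_fractions[c] for c in bg_classes],
                          dtype=float)
    if bg_weights.sum() > 0:
        bg_weights /= bg_weights.sum()

    for lib in config.libraries:
        depth = config.library_depths[lib]
        cond = config.condition(lib)
        lib_reads: list = []
        summary = LibrarySummary()
        counts_out: dict = {}

        n_lowq = rng.binomial(depth, config.low_quality_rate) \
            if config.low_quality_rate else 0
        contam_counts = {k: int(rng.binomial(depth, config.contamination_rates.get(k, 0.0)))
                         for k in CONTAMINANT_KEYS}

        mean_key = "mean_treated" if cond == "treated" else "mean_control"
        known_names = list(truth.known)
        known_means = np.array([truth.known[n][mean_key] * depth
                                for n in known_names])
        known_counts = _nb_counts(rng, known_means, config.dispersion) \
            if known_names else np.array([], dtype=int)
        novel_means = np.array([getattr(n, mean_key) * depth for n in truth.novel])
        novel_counts = _nb_counts(rng, novel_means, config.dispersion) \
            if truth.novel else np.array([], dtype=int)

        used = (n_lowq + sum(contam_counts.values())
                + int(known_counts.sum()) + int(novel_counts.sum()))
        n_background = max(0, depth - used)

        inserts: list = []  # (insert sequence, source-name)
        for name, c in zip(known_names, known_counts):
            if c > 0:
                inserts.extend([(truth.known[name]["mature"], name)] * int(c))
                counts_out[name] = int(c)
        for locus, c in zip(truth.novel, novel_counts):
            if c > 0:
                inserts.extend([(locus.mature, locus.name)] * int(c))
                counts_out[locus.name] = int(c)
        if n_background and bg_classes:
            cls_draw = rng.multinomial(n_background, bg_weights)
            for cls, n_cls in zip(bg_classes, cls_draw):
                pool = reference.background_pool[cls]
                idx = rng.integers(0, len(pool), size=n_cls)
                for i in idx:
                    inserts.append((pool[int(i)], cls))

        rid = 0
        for category in ("low_quality",) if n_lowq else ():
            for _ in range(n_lowq):
                seq, qual = _build_read(rng, config, "low_quality")
                rid += 1
                lib_reads.append((f"{lib}_r{rid}", seq, qual))
                summary.low_quality += 1
        for category, n_cat in contam_counts.items():
            for _ in range(n_cat):
                seq, qual = _build_read(rng, config, category)
                rid += 1
                lib_reads.append((f"{lib}_r{rid}", seq, qual))
                summary.high_quality += 1
                setattr(summary, category, getattr(summary, category) + 1)
        pads = _CharStream(rng)
        qual_cache: dict = {}
        for k, (insert, _source) in enumerate(inserts):
            pad = pads.take(max(0, config.read_length - len(insert)
                                - len(config.adapter_3p)))
            seq = _clean_read(config, insert, pad)
            if k % 101 == 0:  # sampled contract check against the cleaner
                qual = qual_cache.get(len(seq))
                if qual is None:
                    qual = qual_cache[len(seq)] = tuple([40] * len(seq))
                got, got_insert = categorize(ReadRecord("x", seq, qual), params)
                assert got == "clean" and got_insert == insert, \
                    "generator/cleaner contract violation"
            rid += 1
            lib_reads.append((f"{lib}_r{rid}", seq, "I" * len(seq)))
            summary.high_quality += 1
            summary.clean_reads += 1

        order = rng.permutation(len(lib_reads))
        lib_reads = [(f"{lib}_r{i + 1}",) + lib_reads[j][1:]
                     for i, j in enumerate(order)]
        reads[lib] = lib_reads
        summaries[lib] = summary
        true_counts[lib] = counts_out

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib, lib_reads in reads.items():
            tagio.write_fastq(lib_reads, outdir / f"{lib}.fastq")
    return reads, summaries, true_counts
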