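"""End-to-end orchestration: clean -> annotate -> novel -> de -> targets -> enrich.

Each stage consumes the previous stage's declared outputs; a rerun with the
same config and seed reproduces identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, cleaning, diffexpr, enrich, hairpin, tagio, targets

log = logging.getLogger("srnakit.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    fastq: dict                  # library -> path
    output: str
    groups: dict                 # {"treated": [...], "control": [...]}
    genome: str | None = None
    mature: str | None = None
    hairpins: str | None = None
    genbank: str | None = None
    rfam: str | None = None
    intervals: str | None = None
    transcripts: str | None = None
    gene2go: str | None = None
    gene2kegg: str | None = None
    seed: int = 0
    clean_params: dict = field(default_factory=dict)
    hairpin_params: dict = field(default_factory=dict)
    de_params: dict = field(default_factory=dict)
    target_params: dict = field(default_factory=dict)
    scan_scope: str = "significant"  # or "all"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        cfg = cls(
            fastq=inputs["fastq"],
            output=raw["output"],
            groups=raw["groups"],
            genome=inputs.get("genome"),
            mature=inputs.get("mature"),
            hairpins=inputs.get("hairpins"),
            genbank=inputs.get("genbank"),
            rfam=inputs.get("rfam"),
            intervals=inputs.get("intervals"),
            transcripts=inputs.get("transcripts"),
            gene2go=inputs.get("gene2go"),
            gene2kegg=inputs.get("gene2kegg"),
            seed=raw.get("seed", 0),
            clean_params=params.get("clean", {}),
            hairpin_params=params.get("hairpin", {}),
            de_params=params.get("de", {}),
            target_params=params.get("targets", {}),
            scan_scope=params.get("scan_scope", "significant"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for lib, path in self.fastq.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"fastq[{lib}]: {path} does not exist")
        for name in ("genome", "mature", "hairpins", "genbank", "rfam",
                     "intervals", "transcripts", "gene2go", "gene2kegg"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        for side in ("treated", "control"):
            for lib in self.groups.get(side, ()):
                if lib not in self.fastq:
                    raise ValueError(f"group {side} references unknown library {lib}")


def run_all(config: RunConfig) -> dict:
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}
    libraries = list(config.fastq)

    # --- stage 1: clean
    stage = "clean"
    try:
        params = cleaning.CleanParams(**config.clean_params)
        per_lib_inserts: dict = {}
        summaries: dict = {}
        for lib in libraries:
            reads = tagio.read_fastq(config.fastq[lib])
            inserts, summary = cleaning.trim_and_filter(reads, params)
            per_lib_inserts[lib] = inserts
            summaries[lib] = summary
            log.info("clean %s: %d clean of %d high-quality", lib,
                     summary.clean_reads, summary.high_quality)
        tags = tagio.collapse_tags((lib, ins) for lib in libraries
                                   for ins in per_lib_inserts[lib])
        summary_rows = [{"library": lib, **summaries[lib].as_dict()}
                        for lib in libraries]
        summary_path = outdir / "clean_summary.tsv"
        tagio.write_tsv(pd.DataFrame(summary_rows), summary_path)
        counts_path = outdir / "tags.tsv"
        tagio.write_counts(tags, libraries, counts_path)
        manifest["stages"][stage] = {"summary": str(summary_path),
                                     "tags": str(counts_path)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 2: annotate
    stage = "annotate"
    try:
        genbank = (annotate.SequenceSet(tagio.read_fasta(config.genbank))
                   if config.genbank else None)
        rfam = (annotate.SequenceSet(tagio.read_fasta(config.rfam))
                if config.rfam else None)
        mature = tagio.read_fasta(config.mature) if config.mature else {}
        precursors = tagio.read_fasta(config.hairpins) if config.hairpins else {}
        genome = tagio.read_fasta(config.genome) if config.genome else {}
        intervals = None
        if config.intervals and genome:
            intervals = annotate.GenomeIntervals(genome,
                                                 tagio.read_bed(config.intervals))
        assignments, known_hits, composition = annotate.classify_tags(
            tags, genbank=genbank, rfam=rfam, mature=mature,
            precursors=precursors, intervals=intervals)
        comp_path = outdir / "composition.tsv"
        tagio.write_tsv(pd.DataFrame(
            [{"category": c, **v} for c, v in sorted(composition.items())]),
            comp_path)
        known_path = outdir / "known_mirnas.tsv"
        tagio.write_tsv(pd.DataFrame(
            [{"name": h.name, "reference": h.reference,
              "representative": h.representative,
              **{lib: h.counts.get(lib, 0) for lib in libraries}}
             for h in known_hits]), known_path)
        manifest["stages"][stage] = {"composition": str(comp_path),
                                     "known": str(known_path)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 3: novel hairpin discovery
    stage = "novel"
    try:
        unann = {a.sequence for a in assignments if a.category == "unann"}
        unann_tags = [t for t in tags if t.sequence in unann]
        criteria = hairpin.HairpinCriteria(**config.hairpin_params)
        candidates = (hairpin.discover_novel(unann_tags, genome, criteria)
                      if genome else [])
        novel_path = outdir / "novel_mirnas.tsv"
        tagio.write_tsv(pd.DataFrame(
            [{"name": c.name, "sequence": c.mature, "length": len(c.mature),
              "location": f"{c.contig}:{c.start}-{c.end}({c.strand})",
              "precursor_length": len(c.precursor), "energy": c.mfe,
              **{lib: c.counts.get(lib, 0) for lib in libraries}}
             for c in candidates]), novel_path)
        gff_path = outdir / "novel_mirnas.gff3"
        tagio.write_gff(candidates, gff_path)
        manifest["stages"][stage] = {"table": str(novel_path),
                                     "gff": str(gff_path)}
        log.info("novel: %d candidates accepted", len(candidates))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 4: differential expression (known + novel together)
    stage = "de"
    try:
        treated_libs = config.groups["treated"]
        control_libs = config.groups["control"]
        counts: dict = {}
        seqs: dict = {}
        for h in known_hits:
            counts[h.name] = dict(h.counts)
            seqs[h.name] = h.representative
        for c in candidates:
            counts[c.name] = dict(c.counts)
            seqs[c.name] = c.mature
        totals = {lib: summaries[lib].clean_reads for lib in libraries}
        totals_treated = sum(totals[l] for l in treated_libs)
        totals_control = sum(totals[l] for l in control_libs)
        results = diffexpr.de_table(counts, totals_treated, totals_control,
                                    library_totals=totals,
                                    treated_libs=treated_libs,
                                    control_libs=control_libs,
                                    **config.de_params)
        de_path = outdir / "de.tsv"
        tagio.write_tsv(pd.DataFrame(
            [{"name": r.name, "treated_count": r.count_treated,
              "control_count": r.count_control,
              "treated_std": round(r.norm_treated, 4),
              "control_std": round(r.norm_control, 4),
              "fold_change": round(r.fold_change, 4), "p_value": r.p_value,
              "significant": r.significant} for r in results]), de_path)
        manifest["stages"][stage] = {"table": str(de_path)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 5: target prediction
    stage = "targets"
    try:
        predictions = []
        transcripts = (tagio.read_fasta(config.transcripts)
                       if config.transcripts else {})
        if transcripts:
            if config.scan_scope == "all":
                query = dict(seqs)
            else:
                query = {r.name: seqs[r.name] for r in results if r.significant}
            thresholds = targets.TargetThresholds(**config.target_params)
            predictions = targets.scan_targets(query, transcripts, thresholds)
        targets_path = outdir / "targets.tsv"
        tagio.write_tsv(pd.DataFrame(
            [{"mirna": p.mirna, "transcript": p.transcript, "start": p.start,
              "end": p.end, "penalty": p.penalty, "duplex_mfe": p.duplex_mfe}
             for p in predictions]), targets_path)
        manifest["stages"][stage] = {"table": str(targets_path)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 6: enrichment
    stage = "enrich"
    try:
        candidate_genes = {p.transcript for p in predictions}
        enrich_outputs = {}
        for label, map_path, method in (
                ("go", config.gene2go, "bonferroni"),
                ("kegg", config.gene2kegg, "bh_fdr")):
            path = outdir / f"enrich_{label}.tsv"
            if map_path and candidate_genes:
                gene2term = tagio.read_gene_map(map_path)
                terms, dropped = enrich.enrich_terms(candidate_genes, gene2term,
                                                     method=method)
                tagio.write_tsv(pd.DataFrame(
                    [{"term": t.term, "N": t.N, "n": t.n, "M": t.M, "m": t.m,
                      "p_raw": t.p_raw, "p_adjusted": t.p_adjusted,
                      "enriched": t.enriched} for t in terms]), path)
            else:
                tagio.write_tsv(pd.DataFrame(
                    columns=["term", "N", "n", "M", "m", "p_raw",
                             "p_adjusted", "enriched"]), path)
            enrich_outputs[label] = str(path)
        manifest["stages"][stage] = enrich_outputs
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest["libraries"] = libraries
    manifest["clean_totals"] = {lib: summaries[lib].clean_reads
                                for lib in libraries}
    return manifest
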