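# srnakit

Small RNA-seq miRNA analysis toolkit: read cleaning and accounting, tag
annotation, known/novel miRNA identification (with an in-repo hairpin MFE
folder), count-based differential expression, miRNA target prediction,
hypergeometric GO/KEGG enrichment, and qPCR validation arithmetic — plus a
ground-truth synthetic-data generator that produces every input the
pipeline consumes.

## Modules

| module              | role |
|---------------------|------|
| `srnakit.simulate`  | synthetic corpus generator (references, annotation maps, FASTQ libraries with planted ground truth) |
| `srnakit.tagio`     | FASTA/FASTQ/GFF3/TSV readers and writers, tag collapsing |
| `srnakit.cleaning`  | adapter/contaminant cleaning cascade and per-library accounting |
| `srnakit.annotate`  | category assignment (rRNAetc > known miRNA > repeat > exon > intron) and known-miRNA naming |
| `srnakit.hairpin`   | novel miRNA discovery: genome placement, precursor excision, folding, hairpin/Dicer/MFE criteria |
| `srnakit.fold`      | nearest-neighbor stacking MFE folding (intramolecular and duplex) |
| `srnakit.diffexpr`  | per-million normalization, fold-change, exact two-library count test, replicate QC |
| `srnakit.targets`   | complementarity-penalty + duplex-energy target-site scanning |
| `srnakit.enrich`    | hypergeometric term enrichment with Bonferroni / BH-FDR control |
| `srnakit.qpcr`      | relative expression vs. U6 and two-sample t-test |
| `srnakit.pipeline`  | end-to-end orchestration from a YAML config |

## CLI

```bash
srnakit simulate --seed 1 --out corpus/            # synthetic corpus
srnakit clean --fastq lib.fq --adapter3 SEQ --adapter5 SEQ \
       --out tags.tsv --summary summary.tsv
srnakit annotate --tags tags.tsv --mirbase mature.fa --hairpins hairpin.fa \
       --out known.tsv --composition comp.tsv
srnakit novel --tags unann.tsv --genome genome.fa --out novel.tsv --gff novel.gff3
srnakit de --counts counts.tsv --totals totals.tsv --groups design.tsv --out de.tsv
srnakit targets --mirnas mirnas.fa --transcripts tx.fa --out targets.tsv
srnakit enrich --candidates genes.txt --map gene2go.tsv --method bonferroni --out enrich.tsv
srnakit qpcr --ct ct_table.tsv --out qpcr.tsv
srnakit pipeline run --config run.yaml              # full pipeline
```

See `tests/test_pipeline.py::TestRunAll::test_yaml_roundtrip` for the YAML
config layout.

## Tests

```bash
python -m pytest -q tests/
```

Unit tests per module, hypothesis property tests for the invariants, and
`tests/test_acceptance.py` implementing the acceptance criteria (golden
accounting/normalization values, brute-force oracles for the folding
energies and the exact count/hypergeometric tests, null-calibration checks,
and parameter-recovery runs on synthetic corpora).

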