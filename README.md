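# clashpipe

Chimeric-read calling and AGO2-IP local-enrichment analysis for miRNA
target discovery, with a ground-truth simulator.

The package implements two analysis tracks over a shared reference set
(mature miRNA FASTA, transcript FASTA with 3'-UTR annotation, and a
BED-like candidate target-site table; all coordinates 0-based half-open
in transcript space):

* **Chimera track** — overlapping paired-end reads are merged into
  fragments, library adapters are trimmed, reads explainable as one
  contiguous reference match are discarded, and the remainder are
  searched with a word-seeded banded local aligner against the miRNA and
  mRNA classes (E-value cutoffs 10 and 0.1). A read is called chimeric
  when it carries a partial miRNA alignment and a partial mRNA alignment
  on disjoint read intervals; chance co-extension across the ligation
  junction is resolved by exact alignment-path trimming.

* **IP-enrichment track** — each candidate site is widened from its 5'
  end to a 100-nt extended target region (TAR) inside the 3'-UTR; the
  remaining UTR is the non-target region (NT3UTR). IP reads are placed
  end-to-end on transcripts and counted into TAR/NT3UTR, counts are
  TMM-normalized, per-sample local enrichment `log2(TAR/NT3UTR)` is
  computed (pseudocount 0.5 by default), and sites are ranked by the
  drop in local enrichment from wild-type to knockout IP samples.

The `synthetic_data` module generates references with planted
seed-complementary target sites, WT/KO IP libraries with configurable
TAR enrichment folds, and adapter-flanked chimeric libraries — all
byte-deterministic under a seed — so both tracks can be validated
against known ground truth.

## CLI

```
clashpipe simulate --seed 1 --out simdata/         # synthetic dataset + config
clashpipe run --config simdata/pipeline.yaml --mode all
```

Subcommands: `simulate | prep | align | chimera | enrich | run | report`.
`run` executes the configured tracks (`clash`, `ip-enrich`, or `all`),
writing merged reads, blast-style arm hits, the chimera table, per-pair
hybrid counts, the region count matrix, TMM factors, the ranked
enrichment table, a combined report cross-referencing chimera support
with enrichment ranks, and a `manifest.json` (config hash, seed,
version, row counts). Exit codes: 0 success, 2 validation error,
3 stage failure. All outputs are single-header TSVs; every writer has a
matching reader.

Individual stages can be run standalone, e.g.

```
clashpipe prep --r1 R1.fastq --r2 R2.fastq --out merged.fastq
clashpipe chimera --reads merged.fastq --mirna-fasta m.fa \
    --transcript-fasta t.fa --utr-table utr.tsv --site-table sites.tsv \
    --out chimeras.tsv
```

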