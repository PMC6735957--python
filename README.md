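# lncforge

A toolkit for building and characterizing a long noncoding RNA (lncRNA)
catalog from transcript models and expression evidence:

- **`genome_model_io`** — domain types (genomic intervals, transcript models,
  expression matrices, sample metadata) and readers/writers for GTF, BED,
  bedGraph-style score tracks and TSV matrices. Coordinates are 1-based
  inclusive throughout; BED inputs are converted on read.
- **`reference_merge`** — merges reference catalogs by redundancy rules
  (identical intron chains for multi-exon transcripts; >80% overlap of the
  shorter transcript for single-exon ones, source priority deciding the
  survivor) and relates query transcripts to a reference via one-character
  class codes (`=`, `c`, `u`, `x`, `o`, `i`, `other`) with a novelty flag.
- **`confidence_filter`** — a transcript confidence score in [0, 100]
  combining junction-read support in the maximally expressed sample, the
  95th-percentile FPKM and sample recurrence, each normalized over one
  scoring universe; shuffled intergenic decoys preserving exon/intron
  structure; ROC analysis with the cutoff minimizing distance to the
  (sensitivity=1, specificity=1) corner; mean-coverage verification (>2x).
- **`lncrna_classify`** — length (>200 nt) and noncoding filters over
  precomputed predictor evidence, genomic-context classification
  (intergenic / sense / antisense / others) and 1-bp exon overlap catalog
  comparison.
- **`expression_metrics`** — quantile normalization, Jensen–Shannon
  tissue-specificity score (entropy in bits), splicing efficiency against a
  locus-spanning isoform, per-base conservation averaging, inter-individual
  coefficient of variation, the Q3 + 1.5·IQR moderate-expression filter,
  recurrence summaries and half-up-rounded catalog percentages.
- **`trait_association`** — per-transcript linear mixed models (individual
  random intercept) for sex/age/race traits, tumor/normal differential
  expression (FDR < 0.05 and fold change > 1.5), clinical-outcome
  association, multivariate Cox survival with proportional-hazards checking
  and age stratification, Kaplan–Meier median splits, one-tailed Fisher
  tissue enrichment, GWAS SNP overlap counting and Benjamini–Hochberg FDR.
- **`synthetic_fixtures`** — seeded generators for every input above with
  ground-truth labels, so the whole pipeline is testable offline.

## Command line

The `lncforge` entry point exposes one subcommand per pipeline stage:

```bash
lncforge simulate --preset full --seed 7 -o fixtures/     # synthetic inputs
lncforge validate --gtf fixtures/annotation.gtf
lncforge merge --gtf ref1.gtf --gtf ref2.gtf -o merged.gtf
lncforge compare --query assembled.gtf --ref merged.gtf -o codes.tsv
lncforge decoys --gtf templates.gtf --genome chrom.sizes --seed 1 -o decoys.gtf
lncforge tcs --evidence fixtures/evidence.tsv -o tcs.tsv
lncforge cutoff --pos pos.tsv --neg neg.tsv
lncforge identify --gtf candidates.gtf --evidence coding_evidence.tsv -o lnc.gtf
lncforge classify --lnc lnc.gtf --coding coding.gtf -o classes.tsv
lncforge normalize --expr expr.tsv -o norm.tsv
lncforge metrics --expr expr.tsv --meta samples.tsv -o metrics.tsv
lncforge assoc --expr expr.tsv --meta samples.tsv --mode de --tissue liver -o de.tsv
lncforge gwas --gtf lnc.gtf --snps snps.bed -o overlaps.tsv
```

All commands are deterministic for a fixed seed and fixed inputs.

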