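# spliceneo

Splice-junction neoantigen evaluation: from tumor splice-junction events,
per-sample aligned reads, and patient HLA genotypes, `spliceneo` produces
junction-spanning candidate neoantigen peptides scored by patient
harmonic-mean best-rank (PHBR) aggregation across HLA alleles, matched
wild-type junction baselines, principal-candidate filtering, and
responder/nonresponder differential-binding analysis.

## Pipeline stages

1. **Wild-type junction identification** (`junction_io`) — parses STAR
   `SJ.out.tab` catalogs from normal samples and finds, for each tumor
   event, the most commonly expressed normal junction sharing its donor
   or acceptor site. Coordinates follow the STAR convention (1-based
   first/last intron base) throughout.
2. **Read extraction** (`read_ops`) — pulls junction-spanning reads
   (exact skipped-region CIGAR match) or region-overlapping reads plus
   their mates from SAM/BAM; an optional read boost duplicates reads
   (default 10× in low-coverage runs) to aid assembly.
3. **Assembly** (`assembly`) — a built-in de Bruijn assembler (canonical
   k-mers, unitig compaction, maximal simple-path enumeration) plus an
   adapter for any external FASTA-in/FASTA-out assembler.
4. **Frame selection and k-mers** (`peptides`) — translates contigs in
   all six frames, keeps the frame with the best local alignment to the
   wild-type protein (match +2, mismatch −5, gap open −1, gap extend
   −0.5), locates the junction breakpoint by flank anchoring, and
   enumerates breakpoint-spanning peptide k-mers (8–11 for MHC-I, 15
   for MHC-II).
5. **PHBR scoring** (`phbr`) — a pluggable binding-rank predictor
   (deterministic mock or external-command adapter) scores every
   (k-mer, allele) pair; the harmonic mean of per-allele best ranks is
   the patient's PHBR. Binder classes: MHC-I strong < 0.5, weak < 2;
   MHC-II strong < 1, relevant < 5.
6. **Candidates and reports** (`candidates_report`) — principal
   candidates bind MHC, have a WT alternative with a strictly larger
   PHBR, occur in a majority of tumors, and show outlier
   overexpression; responder/nonresponder comparisons, Fisher exact +
   Benjamini–Hochberg loss-association tests, and TSV report writers.
7. **Synthetic cohorts** (`synthetic`) — seed-deterministic toy genomes
   with planted exon-skip events, spliced SAM reads, SJ catalogs, HLA
   tables, and ground-truth peptide registries; also packages the
   published candidate/comparison PHBR value tables.
8. **Orchestration** (`pipeline`, `cli`) — per-event, per-sample
   execution with exclusion bookkeeping (premature stop, short peptide,
   assembly failure), summaries, and a JSON run manifest.

## CLI

```sh
# generate a deterministic toy cohort
spliceneo --seed 7 simulate --out-dir cohort --n-tumor 4 --n-normal 3

# wild-type junction scan only
spliceneo wt-scan --events cohort/events.tsv --normal-sj-dir cohort/sj/normals

# full run from a YAML config (see RunConfig fields in spliceneo/pipeline.py)
spliceneo run --config config.yaml

# score an ad-hoc peptide list against patient genotypes
spliceneo score --peptides peps.txt --genotypes cohort/genotypes.tsv

# re-render the candidate TSV from a previous run
spliceneo report --run-dir out --out candidates.tsv
```

A minimal `config.yaml`:

```yaml
events_path: cohort/events.tsv
alignments_dir: cohort/alignments
reference_fasta: cohort/reference.fasta
genotypes_path: cohort/genotypes.tsv
normal_sj_dir: cohort/sj/normals
wt_protein_fasta: cohort/wt_proteins.fasta
output_dir: out
```

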