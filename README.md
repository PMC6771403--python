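# cltkit

Cancer genomes transcribe thousands of long-terminal-repeat (LTR)
retroelement integrations that healthy tissues keep silent. Transcripts
that overlap such elements and are expressed specifically and recurrently
in one or a few cancer types — cancer-specific LTR-overlapping transcripts
(**CLTs**) — are candidate disease markers, prognostic signals and sources
of tumour-specific antigenic peptides. `cltkit` implements the downstream
analysis that turns an assembled transcriptome plus expression and clinical
data into a vetted CLT catalogue, for computational biologists working on
retroelement exonization and cancer immunopeptidomics.

## What the package computes

Given a transcript assembly (GTF), a RepeatMasker-style repeat annotation,
per-sample TPM matrices with a cancer/healthy sample design, ATAC-seq peaks,
clinical tables and transcript sequences, the pipeline:

1. **Classifies transcripts** by exonic repeat overlap (hierarchical
   LTR > LINE > SINE > other), annotation status against a reference, gene
   biotype overlap, and the structural position of the LTR element —
   *stand-alone*, *LTR-initiated*, *terminal (strand unknown)*, *embedded*
   or *spliced* — and scores splice-site recovery against a reference
   annotation.
2. **Selects cancer-specific transcripts.** With cohort expression
   percentiles `Q75^c` (cancer type *c*) and healthy-tissue statistics, a
   transcript is a CLT in *c* iff
   - TPM > 1 in ≥ 6 of the 24 discovery samples and `Q75^c > 1`,
   - TPM < 10 in ≥ 90 % of all healthy samples,
   - `Q75^c ≥ 3 × max_h median_h` over healthy tissues *h*, and
   - `Q75^c ≥ 3 × Q90` of the matched healthy tissue (when defined).
3. **Validates prevalence** in independent cohorts: a sample is positive
   when TPM exceeds 3 × the highest healthy-tissue median (strict), and a
   CLT validates when more than a quarter of cohort samples are positive.
4. **Tests open-chromatin proximity** of CLT transcription start sites
   against nulls built from random same-size sets of LTR-element centres
   (one-sided rank-sum on nearest-peak distances, 10 null sets).
5. **Associates expression with survival**: expression tertiles, log-rank
   tests between the top and bottom tertile, and Cox
   proportional-hazards ratios (Efron ties), with raw and BH-adjusted p.
6. **Screens coding potential and uniqueness**: ORFs ≥ 300 nt whose mean
   in-frame dicodon (hexamer) log-odds score is strictly higher sense than
   antisense; elimination of CLTs with healthy medians ≥ 1 TPM; ≤ 85 %
   protein identity (local alignment, BLOSUM62, gaps 11/1, identity over
   the full candidate length) against all assembly ORFs ≥ 210 nt, with the
   rescue/discard rule driven by the partner transcript's expression; and
   export of all ORFs ≥ 75 nt of the final CLTs as a peptide search
   database.

A first-class synthetic-data module generates seeded, ground-truth-labelled
fixtures for every stage (planted structural categories, planted CLTs and
single-criterion decoys, hexamer-biased coding corpora with planted ORFs,
tertile-linked exponential survival cohorts, TSS-enriched peak sets), so
the whole pipeline is testable end to end without consortium data.

## Worked example

```sh
cltkit simulate --seed 11 --outdir demo --planted-per-category 2 --decoys-per-criterion 3
cltkit run-all --config demo/config.yaml
```

prints

```
fixture bundle written to demo (10 planted CLTs, 12 decoys)
config_hash: 433cef8985bb
seed: 11
stages:
  classify:
    n_ltr_overlapping: 42
    n_repeats: 1400
    n_transcripts: 42
  select:
    n_candidates: 42
    n_selected: 10
  proximity:
    n_tss: 8
    p_value: 2.3044665803926316e-06
  survival:
    n_significant: 1
    n_transcripts: 1
  orf:
    n_candidates: 10
    n_final: 10
    n_universe_orfs: 42
  export:
    n_peptides: 17
```

All 42 generated transcripts are LTR-overlapping and receive their planted
structural category; the selection stage recovers exactly the 10 planted
CLTs while the 12 decoys fail precisely the criterion they were designed to
violate; the planted TSS-peak enrichment is highly significant against the
random-LTR null; the survival screen flags the planted hazard transcript;
and all 10 planted coding ORFs survive the uniqueness filter, yielding a
17-record peptide database. Stage outputs land under `demo/results/<stage>/`
as TSV/JSON, each carrying the config hash.

The same operations are available as a library
(`cltkit.clt_selection.select_cancer_specific`,
`cltkit.survival.prognostic_screen`, ...) for use on real assemblies and
cohort matrices.

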