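# Methods

## Scope and data model

`cltkit` consumes an assembled transcriptome and its quantification; it does
not perform read alignment, transcript assembly, TPM estimation, repeat
masking or peak calling. All genomic coordinates are 0-based half-open
internally; GTF and RepeatMasker `.out` coordinates are converted at the
file boundary. Strand may be `+`, `-` or unknown (`.`); strand-unknown
transcripts are retained as first-class objects because the structural
taxonomy has a dedicated category for them, and they have no defined TSS.

## Transcript classification

**ERE overlap.** A transcript is ERE-overlapping iff any exon overlaps a
repeat integration by at least `min_overlap_nt` (default 1 nt); intronic
overlap never counts. With several repeat classes present the assignment is
hierarchical: LTR > LINE > SINE > other (SVA elements are carried as
`other` in the four-way summary).

**Annotation status.** A transcript is *annotated* iff every exon is
present in the reference, *partially annotated* iff at least one but not
all are, else *unannotated*. "Present" means: internal exons match a
reference exon at both boundaries; terminal exons match at their
splice-side boundary with the outer boundary free (assemblers are noisy at
transcript ends); a monoexonic transcript's exon matches when contained
within a reference exon (it has no splice-side boundary to pin down).

**LTR structural position.** Five mutually exclusive categories, decided in
priority order when several rules fire:

1. *stand_alone* — ≥ 80 % of exonic nucleotides covered by LTR-class
   repeats (configurable `standalone_coverage_fraction`) and no gene
   overlap;
2. *spliced* — a splice boundary lies strictly inside an LTR element
   (the element donates a splice site);
3. *ltr_initiated* — strand known and the TSS lies within
   `[element.start, element.end)`; strand-unknown transcripts can never be
   LTR-initiated;
4. *ltr_terminal_unknown_strand* — strand unknown and an LTR overlaps a
   terminal exon (both ends are treated as terminal, since which end is
   5' is precisely what is unknown);
5. *embedded* — the LTR lies wholly inside one exon containing neither a
   splice boundary nor the TSS (the extended-UTR case).

The five rules are not exhaustive on their own (e.g. a stranded transcript
whose terminal exon partially overlaps an LTR away from the TSS), so
*embedded* also absorbs the residual cases; this keeps the classifier total
and matches the reading of embedded elements as UTR extensions. The
tie-break order itself is a design choice: the spliced call is the most
information-rich chimeric configuration, so it is preferred over
promoter-level calls once stand-alone transcripts are removed.

**Splice-site recovery.** A reference splice boundary is recovered iff an
assembly boundary exists at the identical chromosome and position. The
overall percentage is computed over the union of reference sites;
per-transcript missing counts are summarised by their median. Monoexonic
reference transcripts contribute no sites.

## Cancer-specificity selection

Percentiles everywhere use linear interpolation between closest order
statistics (rank `1 + (n-1)p/100`, numpy's default), fixed so results are
reproducible to the last digit.

The four criteria (defaults in `SelectionCriteria`):

1. recurrence — TPM strictly above `expressed_tpm` (1) in at least
   `min_expressed_samples` (6) of the `discovery_cohort_size` (24) cohort
   samples, **and** cohort 75th percentile above the same threshold. The
   two published formulations of recurrence (sample count vs cohort upper
   quartile) are not equivalent, so both are enforced by default and each
   is exposed as configuration;
2. healthy ceiling — TPM strictly below `healthy_low_tpm` (10) in at least
   `healthy_low_fraction` (90 %) of all healthy samples pooled across
   tissues (pooling matches the wording "all healthy tissue samples");
3. fold over healthy medians — cohort p75 at least `fold` (3) times the
   maximum per-tissue healthy median. Zero-median tissues contribute a
   threshold of zero: no pseudocount is added, because criterion 2 already
   bounds absolute healthy expression;
4. fold over the matched tissue's 90th percentile, skipped (recorded as
   not-applicable) when no matched tissue is defined.

Fold comparisons are inclusive (`≥`, "three or more times");
validation-cohort positivity is strict (`>`, "more than three times the
highest median in any normal tissue"), and a CLT validates when the
positive fraction strictly exceeds 0.25. Cohorts of a size other than the
discovery default are rejected unless `scale_min_samples` is set, in which
case the sample-count minimum scales proportionally (rounded up).

A manual-exclusion hook accepts a list of transcript ids to drop
(mis-assembled contigs are a judgment call outside the package's scope).

Prevalence and validation percentages are reported as whole percents,
truncated (86.4 % prints as 86); element-usage percentages are reported to
one decimal with standard rounding. These are the printing conventions of
the upstream reports this package reproduces.

## Open-chromatin proximity

The observed statistic is the nearest-peak distance of each CLT TSS
(0 inside a peak; positions on peak-less chromosomes are recorded as
missing). The null samples `n_sets` (default 10) sets of exactly
`|TSS set|` LTR elements without replacement and measures the same distance
from their centres (`floor((start+end)/2)`). The primary p-value is a
one-sided Mann–Whitney rank comparison of observed vs pooled null
distances; the fraction of null sets whose median distance is at most the
observed median is reported alongside as an empirical median rank (with 10
sets its resolution is only 0.1, which is why it is not the primary
statistic). Distances are translation invariant and the null is seeded.

## Survival analysis

Overall survival uses `days_to_death` for deceased patients; censored
patients get `365 × (reference_year − year_of_birth) − age_at_diagnosis
(days)`, with `reference_year` a configurable constant (default 2017, the
last annotation update of the source cohort). The formula mixes calendar
years with day counts and is applied literally, as the source annotation
defines it; non-positive times are dropped with a warning.

Patients are stratified at the 33.33rd/66.67th expression percentiles;
values exactly at a cut go to the lower stratum, and assignment is
independent of input order. The log-rank test is the standard
observed-minus-expected tabulation with deaths at equal times counted
simultaneously; with zero events it warns and returns p = 1. Hazard ratios
come from a Cox partial likelihood with Efron tie handling (lifelines) on
a binary high-vs-low covariate; monotone likelihoods (complete separation)
are reported as non-estimable rather than returning a divergent estimate.
The per-transcript screen emits raw and Benjamini–Hochberg-adjusted
log-rank p-values; the `significant` flag uses raw p < 0.05 because the
upstream analysis states no correction — users wanting strict error
control should gate on the adjusted column.

## Coding potential and uniqueness

ORFs are ATG-to-stop spans in the three forward frames, stop codon
included in the span and excluded from the peptide; within one stop-bounded
region only the 5'-most ATG is reported unless `all_starts` is set, and
codons containing N never match. Candidate ORFs must be ≥ 300 nt
(`candidate_min`); the search-database export keeps ORFs ≥ 75 nt
(`peptide_db_min`); the assembly-wide universe uses ≥ 210 nt
(`orf_universe_min`).

The dicodon model is an in-frame hexamer log-odds table: coding and
background frequencies are counted codon-stepped (stride 3, configurable to
1), and `log((f_coding + pc)/(f_background + pc))` with pseudocount
`pc = 1e-5` gives 4096 finite entries. An ORF's score is the **mean**
log-odds over its in-frame hexamers — length-normalised so the
sense/antisense comparison is length-free (the explicit ≥ 300 nt rule
carries the length requirement); the antisense score is the same statistic
on the reverse complement of the ORF, and candidates require sense >
antisense strictly. Adding a constant to the table shifts both scores
equally, leaving the decision invariant.

Uniqueness uses best local protein alignment (BLOSUM62, gap open 11 /
extend 1, no compositional masking) between the candidate's largest ORF
(ties broken 5'-most) and every universe ORF from a different transcript;
percent identity counts identical aligned residues over the **full
candidate length**. A candidate is unique iff no partner exceeds 85 %
identity. Non-unique candidates are discarded iff any high-identity
partner's transcript is healthy-expressed and retained otherwise —
partners that are themselves cancer-specific, or not expressed at all, do
not disqualify. Because identity is computed pairwise and deterministically
the filter is independent of candidate order. This local-alignment screen
stands in for a translated-BLAST search; an E-value cutoff is kept in the
configuration for users who substitute an external aligner, but E-values
are database-size dependent and are not used internally.

## Synthetic data: what it emulates and what it does not

The generators plant known truth inside data with the statistical shape
each stage assumes; all take explicit seeds (no global random state) and
regenerate byte-identically.

- **Virtual genome**: 4 chromosomes × 5 Mb by default, coordinates only —
  interval logic needs no sequence homology, and the repeat annotation
  carries the standard MaLR/HERV family names.
- **Structural fixtures** are noise-free: each planted transcript is built
  around an LTR element with repeat-free flanks so its category is
  unambiguous, including an embedded case whose LTR sits in the last exon
  3' of the planted stop-codon coordinate.
- **Expression**: group means with multiplicative log-normal noise
  (sigma = 0.2 on the log scale), a heavy-tailed surrogate for TPM
  variability. Planted CLTs use mean 30 TPM in their cancer type and exact
  zero elsewhere, giving margins of several fold on every criterion; each
  decoy perturbs exactly one criterion (e.g. the healthy-ceiling decoy
  spreads its high healthy samples thinly across non-matched tissues so no
  tissue median rises and the matched p90 stays clean). The default design
  is 3 cancer types × 24 samples against 10 healthy tissues × 20.
- **Sequences**: coding corpora draw codons from a fixed skewed
  distribution interpolated with uniform by the `hexamer_bias` parameter
  (0 = indistinguishable from the uniform background, stop codons
  suppressed as bias grows); planted ORFs are ATG + biased non-stop codons
  + stop between ATG/stop-free flanks, so their coordinates are exact.
- **Survival**: exponential event times with the hazard multiplied by the
  true ratio in the top expression tertile (proportional hazards by
  construction, matching the fitted model); censoring is an independent
  uniform fraction of the event time, with clinical fields arranged so the
  censoring-time formula reconstructs the intended time.
- **Peaks**: a configurable fraction of TSSs receives a peak displaced by
  Normal(0, `offset_sd`); the rest are uniform background.

Passing tests on these fixtures demonstrates the correctness of the
selection arithmetic, classifiers and statistics — not robustness to
assembly artefacts, batch effects, read-level noise, real repeat-family
homology or tumour purity variation, none of which the generators model.

## Numerical and reporting choices

- Percentile convention fixed package-wide (see above); tertile boundary
  ties go down.
- Duplicate transcript ids across chromosomes are an error; within one
  chromosome the exons are merged into one model and must be disjoint.
- The acceptance script runs the log-rank calibration at 400 replicates of
  n = 100 and the Cox recovery at 50 replicates of n = 300 (the test suite
  runs 1,000 and 100 respectively); fixture sizes for recovery checks are
  50 planted CLTs + 200 decoys.
- The hexamer model's architecture is a deliberate simplification: a
  two-class in-frame hexamer composition comparison, which is what a
  dicodon score measures; no state-transition structure is fitted. The
  antisense score is computed on the reverse complement of the ORF itself,
  not on antisense-frame ORFs of the transcript.

## Known limitations

- Strand assignment is taken from the input GTF; no strand inference from
  LTR directionality or splice motifs is attempted.
- Criterion 2 pools all healthy samples; a per-tissue variant would be
  stricter for tissues with few samples.
- The uniqueness screen is all-pairs local alignment, adequate for
  assembly-scale ORF universes in the tens of thousands but not optimised
  for proteome-scale databases.
- Multivariable Cox models (clinical covariates, competing risks) are out
  of scope; the survival module tests one expression contrast at a time.
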