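# Methods

## Classification model

The cascade assigns every focal gene one of three conservation strata
from a clade-structured panel: a gene is **EC** when any of its isoform
proteins has a similarity hit with e-value strictly below the cutoff
(default 10⁻⁵) in an out-group species, **CTSG** when it has no
out-group hit but a qualifying hit in a non-focal in-group species, and
**ORPHAN** otherwise. The categories are mutually exclusive and
exhaustive by construction, and classification is a pure function of
the hit table: deterministic, independent of row order, and monotone in
the cutoff (relaxing the cutoff can only move genes toward older
strata).

Conventions worth making explicit:

* a hit **at exactly** the cutoff does not count (strict `<`);
* isoforms are aggregated with an any-isoform rule — one hitting
  isoform classifies the whole gene;
* translated-genome (six-frame) searches are used only for species
  without an annotated proteome, mirroring the common practice of
  reserving genome searches for unannotated assemblies; a flag forces
  genome mode for all species;
* hits inside the focal species itself are ignored;
* an optional validation hit table (e.g. from a broader external
  protein database) can promote CTSG/ORPHAN calls to EC. This replaces
  the manual-inspection reassignment a human curator would perform; no
  automatic heuristic is invented for it, and the validation table uses
  the same cutoff by default.

### Built-in search engine

The bundled aligner is an exhaustive Smith–Waterman local aligner
(BLOSUM62, gap open 11, extend 1) — the dynamic program itself comes
from Biopython's `PairwiseAligner`; the search semantics, six-frame
translation and statistics are this package's. Raw scores are converted
to bit scores and e-values with the Karlin–Altschul formula,
`E = m·n·2^(−S′)`, using the published gapped-BLOSUM62 constants
λ = 0.267, K = 0.041, held fixed rather than refit per database so that
results are reproducible across runs and panels. The search space `m·n`
is query length × subject length (protein mode) or query length × total
translated residues (genome mode). Six-frame translation splits at stop
codons and searches stop-free segments of ≥ 20 residues. Because the
search is exhaustive rather than heuristic, sensitivity is exact at the
cost of speed; the intended scale is panels of tens of species with
small proteomes, not genome-wide screens.

## Gene features

* **gene size** — genomic span (end − start + 1), introns included;
  a span-level size is what makes conserved multi-exon genes an order
  of magnitude longer than compact single-exon orphans.
* **protein size** — the longest isoform; **exon number** — the
  transcript with the most exons. Both are per-gene reductions over
  isoforms chosen for determinism; both conventions are configurable in
  principle and recorded in the output header.
* **GC content** — G+C over unambiguous A/C/G/T within the span
  (ambiguous bases excluded from numerator and denominator); a
  CDS-only mode is available (`gc_region="cds"`).

### Group statistics

Stratum contrasts use one-way ANOVA. Levene's test (median-centred) at
α = 0.05 selects the post-hoc family: Duncan's multiple range test when
variances look homogeneous, Dunnett's T3 otherwise. Neither post-hoc
test exists in scipy or statsmodels, so both are implemented here:

* **Duncan** compares the range of each span of *p* ordered means with
  `q(γ_p; p, df_err)·√(MSE/n_h)` where `γ_p = (1−α)^(p−1)` is Duncan's
  protection level, `q` is the studentized-range quantile
  (`scipy.stats.studentized_range`), and `n_h` is the harmonic mean of
  the group sizes; spans nested inside a non-significant span are never
  declared significant, and the whole procedure is protected by the
  omnibus F at α = 0.05.
* **Dunnett's T3** computes Welch-type pairwise statistics with
  Satterthwaite degrees of freedom and refers them to the studentized
  maximum modulus over the k(k−1)/2 comparisons. The SMM tail is
  computed under independence, `P(max|T| ≤ q) = (2·F_t(q; df) − 1)^k` —
  a standard working approximation given that exact SMM tables are not
  available in any dependency; it is slightly conservative for
  positively correlated comparisons. This affects only post-hoc
  p-values, never the omnibus test.

Spearman's rank correlation (average ranks on ties, two-sided p from
the t approximation) relates per-chromosome gene counts to chromosome
lengths; a constant vector yields an explicitly undefined (NaN) rho.
Welch's t-test is used for the paralog similarity contrast — the
equal-variance assumption is not defensible for similarity
distributions split by partner conservation, so the unequal-variance
form is the default.

## Transcript-evidence QC

PSL alignments are filtered with four inclusive thresholds: mapping
length (Σ block sizes) ≥ 100 bp, identity ≥ 96 %, coverage within the
mapping ≥ 97 %, coverage within the whole transcript ≥ 75 %. The ratios
are defined from PSL fields as

* identity = matches / (matches + mismatches) — gap columns excluded,
* coverage within mapping = (matches + mismatches) / mapping length,
* coverage within transcript = mapping length / transcript length;

a failing record lists every violated criterion. Scores are the UCSC
BLAT score (matches + repMatches − misMatches − qNumInsert −
tNumInsert). Among a transcript's passing mappings only the best
survives, unless the runner-up is within 5 % of the best score
(relative to the best), in which case the transcript is discarded as
ambiguous. Assignment to a gene requires > 100 bp overlap (strict) on
the same strand between the mapping's genomic span and the gene span;
PSL's 0-based half-open coordinates are converted to the GTF 1-based
convention in a single routine. The gene with maximal overlap wins;
exact ties leave the transcript unassigned. A gene counts as expressed
in a tissue as soon as one assigned transcript from that tissue's
library supports it. Tissue enrichment is a two-sided Fisher exact test
on (category vs background) × (in-tissue vs elsewhere) over genes
expressed anywhere; the background category defaults to EC.

## Expression

RPKM = count / (exon length / 10³) / (total valid reads / 10⁶), with
the exon length the merged union of all exons over the gene's
transcripts, and total valid reads the per-sample number of uniquely
mapped reads supplied as metadata (it covers the whole transcriptome,
not just the listed genes, so it is never recomputed from the matrix).
Replicates of the same named stage are pooled by summing counts and
totals before normalization. "Expressed" means count ≥ 1 by default; a
configurable floor is available. Peak stages are ranked by RPKM with
ties broken toward the earliest stage (deterministic); all-zero genes
have no peak and are excluded from peak proportions with a recorded
exclusion. The late-stage contrast is a Pearson chi-square (1 df, no
continuity correction) on late-peaking fractions of two categories; a
degenerate margin (both fractions 0 or 1) carries no signal and returns
(0, 1), and expected cells < 1 flag the result. The temporal
specificity score uses raw RPKM shares (no log transform): shares are
already scale-free, which gives the score its exact scale invariance.
The early/late boundary is configurable per sample; the synthetic
default places it at stage index 7 of 15, by analogy with a
mid-series onset of zygotic transcription.

## The synthetic cohort

The generator's defaults define the study conditions: 26 focal genes
(12 EC, 8 CTSG, 6 orphan), 3 in-group and 3 out-group species (one
out-group species has a genome but no proteome), 15 developmental
stages, 5 tissues, negative-binomial dispersion 0.3, homolog divergence
0.10 substitutions/site.

* **Homolog planting** uses per-site substitution with no indels.
  At 10 % divergence a planted pair scores hundreds of bits, so
  classifier behaviour is separated from aligner sensitivity; a
  generation-time self-test re-aligns every planted pair and aborts if
  any fails the cutoff.
* **Orphans** are drawn i.i.d. from a background amino-acid frequency
  and redrawn if the built-in search finds any cross-species hit below
  the cutoff, guaranteeing label purity.
* **Gene architecture** is class-dependent (orphans short and
  exon-poor, ≥ 1 single-exon orphan guaranteed), so structural
  contrasts have a planted direction.
* **Counts** are negative binomial with `var = μ + d·μ²`; `d = 0` is
  the noiseless limit where counts equal rounded means. Stage-restricted
  genes concentrate their mean (400 vs 0.5 baseline) at one planted
  stage; orphans are restricted to a late stage with probability 0.8,
  clade-specific genes 0.5, conserved genes are uniform (mean 40).
  Per-stage library factors are log-uniform over a 4-fold range so RPKM
  normalization is exercised.
* **PSL fixture**: every QC threshold gets one record just above and
  one just below it, plus one transcript with a 4 % score gap
  (ambiguous) and one with 6 % (clear); planted verdicts are recorded.
  Tissue-labelled assignable ESTs skew orphans toward the reproductive
  library and clade-specific genes toward brain, so the Fisher
  enrichment path always has signal; reproductive and brain libraries
  are always generated.
* **Paralogs**: every third pair gets an EC partner with low similarity
  (18–38 %), the rest non-conserved partners with high similarity
  (60–92 %), matching the duplication-divergence expectation.

Identical (config, seed) produces byte-identical outputs.

What the generator does **not** emulate: realistic sequence evolution
(no indels, no rate heterogeneity, no codon bias beyond a two-codon
table), read-level noise (counts are drawn directly, not simulated from
reads), annotation error, or cross-contamination between libraries.
Passing tests therefore demonstrate correctness of the pipeline's
logic and statistics under clean planted signal — not robustness to the
failure modes of real annotations and alignments.

## Numerical choices and degenerate inputs

* e-value comparisons are strict (`<` cutoff); QC thresholds inclusive
  (`≥`).
* ANOVA groups with < 2 members are excluded with a record; all-equal
  observations raise (the test is undefined), as does a specificity
  contrast over constant scores.
* All-zero expression rows have an undefined specificity score (NaN)
  and are excluded from group contrasts.
* Paralog tables are deduplicated on the unordered gene pair after
  restriction to the category under study, so summaries are invariant
  to row order and duplicated rows; partners missing from the call set
  count as non-conserved and are logged.
* Ambiguous bases are excluded from GC numerator and denominator.
* Reported problem sizes: the default cohort (26 genes, 7 species)
  classifies in a few seconds; the Monte-Carlo peak-recovery check uses
  220 stage-restricted genes; the null-calibration simulation uses
  1000 replicates of 3 × 10 observations.

## Known limitations

* The built-in aligner is exhaustive (no seeding/heuristics); use an
  external search tool's 12-column output for anything beyond toy
  panels.
* Dunnett's T3 p-values use the independence form of the SMM tail (see
  above).
* The EST pipeline evaluates alignments, it does not produce them; a
  genome aligner must supply the PSL.
* Duplication-origin inference takes the paralog table as given — no
  de novo paralogy detection — and its "similarity" is whatever percent
  identity the table provides.
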