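# Methods

## Scope and model of the data

The package quantifies a pooled barcode ChIP screen. Each strain in the
pool carries one fixed-length DNA barcode (default 20 bp) at a common
genomic location next to a replication origin; sequencing a barcode
amplicon from an immunoprecipitated (IP) chromatin sample and from the
matched input sample yields per-strain read counts. The IP/input count
ratio, after depth normalization, is taken as a relative measure of
polymerase occupancy at the barcode in that strain. The experimental
design scored here is two replicate screens × two timepoints (40 and 80
minutes after release into S phase under hydroxyurea) × two roles (IP,
input) — eight samples. The scoring chain itself is agnostic to the exact
timepoint values; it requires exactly two distinct timepoints and at least
two replicates, and labels its output columns by the sorted timepoints.

## Barcode counting

Reads are parsed with Biopython's FASTQ iterator (quality strings are read
but ignored: no quality filtering is applied, and none is modelled). A
read is assigned by locating a constant anchor sequence — the leftmost
position within a configurable search window at which the anchor matches
with at most `anchor_max_mismatch` substitutions — and taking the next L
bases as the candidate barcode. Under the default `exact` policy the
candidate must equal a map barcode; under the opt-in `hamming1` policy a
candidate is corrected to the unique map barcode at Hamming distance 1
(a pre-built neighbor index makes this O(1) per read; a candidate with two
or more neighbors is `ambiguous_correction`). Unassignable reads are data,
tallied by reason (`no_anchor`, `short_read`, `unknown_barcode`,
`ambiguous_correction`), never errors. `exact` is the default because
screen barcode libraries are designed well-separated and the cost of a
wrong correction exceeds the gain of ~L·e recovered reads per unit error
rate. The anchor, window and barcode length are configurable because
amplicon layouts differ between primer designs; the defaults (no anchor
constraint beyond what the caller sets, whole-read window, L = 20, zero
anchor mismatches) assume a clean amplicon.

## Scoring chain

* **Absence filter.** A barcode is retained in an input sample iff its
  count is at least `absence_fraction × total_reads`, default
  2.5×10⁻⁵ (0.0025%). The rule excludes what is *below* the cutoff, so a
  count exactly at the cutoff is retained. The filter is defined on input
  samples only; an IP count of zero for a retained barcode is meaningful
  signal (ratio 0), not absence.
* **Median normalization.** Counts are divided by the median count over
  the retained set (midpoint interpolation for even sizes — the
  conventional definition). This makes scores depth-free: multiplying all
  counts of a sample by any positive constant changes nothing downstream.
* **Ratio, averaging, overlap.** Per-barcode IP/input score ratios are
  averaged across replicates as the arithmetic mean of raw ratios
  (`mean_of_ratios`, the default; `mean_of_logs` — a geometric mean — is
  available). A strain enters the final table only if retained in every
  replicate's input at both timepoints: a strict intersection, so every
  reported gene is quantified under identical sample support.
* **Baseline.** The log2 fold-change is taken against a per-timepoint
  baseline B_t. The default `wildtype_median` uses the median mean-ratio
  of the pooled wild-type barcodes — the wild types are carried in the
  pool precisely as a control population, and this choice centers their
  log2FC distribution at 0 by construction. `all_median` and `none`
  (B_t = 1) are available because the centering convention of a published
  screen is often not recoverable from its reports.
* **Zero ratios.** A mean ratio of 0 (no IP reads in any replicate) has no
  finite log2. Such entries are floored to the smallest positive mean
  ratio of the same timepoint column and flagged (`floored_t40/t80`), so
  they sort to the bottom without fabricating a magnitude.
* **Classification.** With threshold τ (default 1.25, log2 units) the four
  hit classes are assigned with strict inequalities (a gene exactly at ±τ
  is unchanged at that timepoint); `down_40_only` requires only
  log2FC(80) ≥ −τ, while `down_80_only` requires |log2FC(40)| ≤ τ, so the
  five classes are mutually exclusive and exhaustive over the plane.
* **Replicate agreement.** Reported as Pearson correlation of log2 ratios
  over the shared strains (zero ratios dropped), with Spearman on raw
  ratios as an option; published screens typically state only "R", so both
  conventions are exposed.

## Overlap enrichment

The 2×2 table is hits/non-hits × annotated/not over a common universe,
with the annotated universe count K taken *inclusive* of hits (published
"genome-wide" rates are typically reported that way), hence K − k
annotated non-hits. Percentages are 100·k/n and 100·K/N. The two-sided p
sums the hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed the observed table's — computed
in exact integer/rational arithmetic (binomial-coefficient weights,
`fractions.Fraction` only at the final division), so ties are handled
exactly and the result is reproducible to the last bit. scipy's
floating-point implementation is used in the test suite as an independent
cross-check, not in the implementation. The odds ratio is the sample odds
ratio k(N−n−K+k) / ((n−k)(K−k)), reported as +inf for a zero denominator
with a nonzero numerator and NA for 0/0. The exact test is an extension:
overlap reports of this kind often print only percentages, and the summary
string says so.

## Suppressor-screen colony scoring

Each plate is normalized to its own median colony size; the per-strain
score is normalized-treated over normalized-control, and a suppressor call
means score strictly greater than the fold-change threshold (default 1.5).
The plate median is taken over all wells including zero-size colonies,
because removal of zeros is defined to happen *after* normalization;
`include_zeros_in_median=False` is available. Replicate plates per
condition, if given, are averaged per strain after normalization. No
spatial (row/column/edge) corrections are applied — scoring is exactly
the stated median-normalize-and-ratio procedure, which keeps it
transparent; screens processed with array-tool spatial corrections may
call a somewhat different set at the same threshold.

## Synthetic screens

The generator is a deliberately simple hierarchical model — the aim is a
ground truth the pipeline must recover, not a sequencer emulator:

* **Library.** Barcodes are drawn uniformly over {A,C,G,T}^L and rejected
  within a minimum pairwise Hamming distance (default 3) of an accepted
  barcode; pool scale defaults to 4500 mutants + 1100 wild types.
* **Truth.** Mutants receive hit classes by configurable proportions
  (defaults ≈15% down_both, 4% up_both, 5% each single-timepoint class,
  echoing the hit structure of a real screen); a class fixes multiplicative
  occupancy effects 2^effect at each timepoint. Wild types always have
  multiplier 1. Strain abundances are log-normal (natural-log SD σ_a,
  default 0.5).
* **Counts.** Input expected proportions ∝ abundance; IP proportions
  additionally carry the occupancy multiplier and a per-replicate,
  per-strain log-normal noise factor (natural-log SD σ_r, default 0.1,
  drawn once per replicate and shared between its timepoints). Read counts
  are multinomial at the configured depth (default 2×10⁶ per sample).
* **Sequencing error.** Reads are anchor + barcode + random filler with
  i.i.d. substitutions at `base_error_rate` (default 0.002) on every base.
  At the counts level the same model enters as binomial thinning with
  survival (1−e)^(|anchor|+L): under exact matching, any substitution in
  the anchor or barcode unassigns the read. The two levels differ only in
  events where ≥3 substitutions convert one library barcode into another
  (probability ~(Le)³ per read at minimum distance 3), which is negligible
  at the default error rate; a test checks their statistical agreement.
  The counts level is used for deep scenarios, the FASTQ level to exercise
  the parsing/counting stage end to end.
* **Not modelled.** PCR duplicates and jackpotting, GC/amplification bias,
  indels, quality-score structure, chimeras, and biological covariation
  between abundance and occupancy. Passing recovery tests therefore shows
  the quantification is correct under multinomial sampling with log-normal
  heterogeneity — not that real screens are free of these artifacts.

Colony plates: control sizes log-normal around 200 area units (log SD
0.3); treated = control × effect for true suppressors × log-normal noise.

Recovery is evaluated as an integer confusion matrix of true class ×
called class over mutant genes, with a `not_scored` column for truth
strains the pipeline filtered out; sensitivity for a class counts those
against it, precision is over calls made.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds; identical
parameters and seed give byte-identical FASTQ output. The standard
recovery scenario used by the tests and the acceptance script is 500
mutants + 100 wild types at 2×10⁶ reads/sample (counts level; ~5 s); the
FASTQ round trip in the acceptance script uses 75 strains at 10⁵
reads/sample, deep enough that per-strain counts (~1300 reads) put the
±2-log2 effects far outside sampling noise. The exhaustive exact-test
verification covers all ~6.3×10⁵ tables with N ≤ 60.

## Known limitations

* The published screen's exact baseline convention, correlation convention
  and counting software are not fully recoverable from its reports;
  reproducing its printed tallies (2905 scored, 423/128/154/202 hits,
  R = 0.90/0.91) requires the deposited raw data and is a reproduction
  study outside the test suite. The configuration surface
  (`baseline_policy`, `replicate_combine`, `correlation_method`) spans the
  plausible conventions.
* Hit calling is purely threshold-based, mirroring the screen design; no
  per-gene variance model or p-values are provided.
* `hamming1` correction assumes the library's minimum pairwise distance is
  ≥3; on a poorly separated library it will refuse corrections as
  ambiguous rather than guess.
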