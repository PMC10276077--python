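# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `barcodekit`.

## Scope and model of the problem

Random DNA barcodes tag cell lineages; deep amplicon sequencing of the
barcode locus yields per-lineage read counts over time.  The package covers
the quantitative layer of that workflow: evaluating a barcode *design*
(a degenerate oligo specification), simulating ground-truthed sequencing
data with a realistic error model, extracting barcodes from reads,
collapsing error-derived sequences back onto true barcodes, and scoring the
result.  Wet-lab steps (synthesis, integration, PCR chemistry) and
downstream fitness inference are out of scope, as is re-implementation of
third-party clustering tools (their outputs can be scored through the
cluster-map adapter in `correction`).

## Design evaluation

**Information.**  A design is an ordered list of per-position base sets
(letters A/C/G/T/N/W/S; full 15-letter IUPAC is deliberately not accepted —
the three degeneracy classes cover the designs used in practice and keep the
grammar unambiguous).  Information is I = Σ log2 |set| bits; 2^I sequences
are producible.  Tracking K lineages needs Imin = log2 K bits
(Lmin = Imin/2 bp at 2 bits per fully random base), in practice several bits
more.

**Library-diversity criterion.**  Transformation delivers each barcode to
Multinomial(K; f) cells, so diversity survives when K·fmax ≪ 1, fmax being
the top library frequency.  For exponentially distributed frequencies,
extreme-value theory gives E[fmax] = 2^−I (γ + I ln 2) with γ ≈ 0.577.  The
formula is asymptotic in N = 2^I; inputs with I < 5 are rejected rather than
silently returning a poor approximation.  "≪ 1" is operationalized as
K·fmax < 0.1 by default; the threshold is a named, configurable parameter
because no canonical quantification of "much less" exists.

**Run statistics.**  `max_run` reports homopolymer length (unit 1) and the
number of complete repeats of a two-letter unit with *distinct* letters
(unit 2), scanned over both phases.  Homopolymers are excluded from the
unit-2 statistic so "AAAA" is a 4-base homopolymer, not two "AA" repeats —
one pathology, one number.  `worst_case_run` computes the exact maximum over
the whole design space by dynamic programming: for unit 1 the state is the
longest feasible run of each base ending at the current position; for unit 2
the number of complete repeats of each ordered pair ending at the current
position, extended two positions at a time (both phases arise from scanning
every end position).  Tests verify the DP against exhaustive enumeration on
small designs.

**GC bounds.**  `worst_case_gc` counts positions whose sets are contained in
{G,C} (guaranteed strong) and positions intersecting {G,C} (potentially
strong).  For the 38-bp N3WS design this gives an exact worst-case GC range
of 18.4–81.6%; the *sampled* range under uniform per-position draws is much
narrower and is reported by `design_profile`.  The package reports both and
does not hard-code any narrower claimed range.

**Collision analysis.**  For a fully degenerate library of K L-mers, the
chance that a random L-mer falls within Hamming distance d of a fixed one is
p_d = Σ_{i≤d} C(L,i) 3^i / 4^L, and the expected fraction of barcodes with
another barcode within d (duplicates included, i.e. d = 0 counts) is
1 − (1 − p_d)^(K−1).  `neighbor_fraction_simulated` checks this by
simulation with an **exact** pigeonhole search: the L positions are split
into d_max+1 blocks; any pair within distance d_max must agree exactly on at
least one block, so grouping by block content and testing pairs within
groups examines every qualifying pair.  No approximate index is used, so no
recall audit is needed; the search is verified against brute-force all-pairs
distances in the tests.  Five replicate libraries give a mean and standard
error per radius.

## Read simulation

**Library.**  The benchmark library mixes three exponential abundance tiers
— 99,895 barcodes with mean 1, 100 with mean 10, and 5 with mean 1000 —
emulating a bulk of ordinary lineages plus rare high-frequency outliers.
Frequencies are abundances normalized to sum 1.  Scaled-down libraries keep
the same proportions (99.895% / 0.1% / 0.005%) via largest-remainder
rounding, with a leftover unit assigned to the highest-mean tier so the
outlier tier is always represented (at 10^4 barcodes: 9989 / 10 / 1).
Barcodes are drawn from the design uniformly per position (hand-mixed
synthesis idealization) and resampled on collision.

**Reads.**  Per-barcode read counts are Poisson with mean f_i × expected
depth (default 25M; the realized total is the Poisson sum).  Errors are
applied in two stages, indels first, then substitutions, so reads can carry
both:

* *Run-dependent indels.*  Only barcodes with a mononucleotide run of ≥ 5 bp
  generate indel reads (dinucleotide-run indels are not simulated by
  default).  The total per-read indel probability for a run of n bases is
  a·e^{bn} capped at 0.5, with a = 1.273×10⁻⁴, b = 0.597 — calibrated so
  rate(10) ≈ 0.05 and rate(13) ≈ 0.30 per read, anchored to the observation
  that up to ~30% of reads of a barcode with a run beyond 10 bp carry an
  indel.  Exact per-length rates in real data are platform- and
  chemistry-dependent, so the model accepts a per-length lookup table
  (`rate_table`) overriding the exponential form.  The total rate is split
  across the four event types (±1, ±2 repeat units) as 45/45/5/5% — single-
  repeat slips dominate replication slippage.  Indel generation is
  *recursive*: an indel product with a qualifying run spawns its own events,
  so multi-step length changes arise with realistic (multiplicative)
  probabilities.
* *Substitutions.*  Every read independently acquires substitutions at
  0.4%/base (the upper bound for Illumina); the per-read count is binomial,
  positions uniform, and the alternative base uniform over the other three.

Every simulation carries a complete provenance table (observed sequence,
parent barcode, error class, reads), so read conservation and truth-map
completeness are asserted on every run, and downstream evaluation never
guesses lineage ancestry.

**UMI regimes.**  `simulate_umi_experiment` tags every template with a
unique UMI, multiplies one focal barcode's amplification by a bias factor,
and samples reads with replacement.  The duplicate fraction
1 − unique templates / reads diagnoses the regime: near 0 when templates ≫
reads (read-limited), near 1 when reads ≫ templates (template-limited).  A
separate `two_per_template` mode sequences every template exactly twice,
the accounting in which duplicates make up exactly 50% of reads; it is kept
distinct from Poisson-depth sampling because "each template sequenced on
average twice" is ambiguous between the two.

**FASTQ rendering** wraps observed sequences in the amplicon layout
(offsets, inline index, UMI, flanks) with constant qualities — sufficient
for end-to-end extraction tests; per-cycle quality profiles are not
modeled.

## Extraction

**Regex ladder.**  Five patterns of increasing leniency, stopping at the
first match: exact 6-bp flank anchors with exact barcode length, then
length ±1, ±2, then one edit allowed in each anchor at exact length, and
finally one edit with length ±2.  The fuzzy levels are compiled as
alternations over all edit-distance-1 variants of the anchor (ordered
exact, substitutions, deletions, insertions), which is tractable at 6-bp
anchors (~50 variants) and gives the same acceptance language as a fuzzy
regex engine.  An optional sixth, length-free pattern with 10-bp anchors
supports barcode-length surveys.  Leniency is nested: anything matched at
level k is matched at every higher level (property-tested).

**Alignment extraction** locates each flank by local alignment
(match +1, mismatch −1, gap −2 — deterministic and self-contained, replacing
an external aligner) and returns the read substring strictly between the
upstream flank's end and the downstream flank's start.  Failures are
statuses, not exceptions: identity < 0.8, aligned span < 6 columns, or
out-of-order coordinates.  Equal-scoring placements resolve leftmost for the
upstream flank and rightmost for the downstream flank, maximizing the
captured region deterministically.  Alignment tolerates grossly abnormal
barcode lengths that the ±2-capped ladder cannot; both methods can
mis-extract when the barcode itself resembles a flank, which is why the
concordance table (`compare_methods`) is part of the toolkit.

**Quality policy.**  A read fails if its mean Phred is below 20, or any base
inside a matched flank anchor is below 10.  The cutoffs are declared
defaults, not measured constants; both are configurable.

**Demultiplexing.**  Each observed index resolves to its nearest declared
index within 1 mismatch (ties unresolved).  A fully resolved but
inadmissible 4-tuple is a *chimera* — in a redundant scheme (each 5' inline
index paired with a unique i7, each 3' inline with a unique i5) every
single-index swap between samples is inadmissible, and the tests verify
100% of synthetic single-swap chimeras are flagged.  Anything else is
*unknown*.

**UMI deduplication** is refused (with a diagnostic, not silently) unless
4^umi_length is at least 100× the highest barcode read count, since an
undersized UMI space makes distinct templates share UMIs and deduplication
would erase real abundance.

## Error correction (Deletion-Correct)

The published record of the original tool is its parameter set
(`min_counts_for_centroid=2, max_edits=3, poisson_error_rate=0.1`); the
algorithm here is this package's own reconstruction of a
deletion-neighborhood, Poisson-thresholded greedy clusterer, with every
choice documented:

* Sequences are processed in descending count order (ties lexicographic).
  Merging requires the parent to have *strictly* more reads, so sequences of
  equal count cannot interact and the within-level order cannot change the
  result.
* Candidate parents are retrieved from a deletion-neighborhood index: each
  centroid is indexed under every subsequence obtained by deleting up to 3
  characters; queries are expanded the same way.  If Lev(s,p) ≤ 3 the two
  share such a subsequence, so retrieval is lossless; candidates are then
  verified with an exact Levenshtein computation (edlib).  Tests prove the
  candidate sets identical to brute-force all-pairs DP distances.
* Attribution test: `poisson_error_rate` is read as the per-read probability
  that a read of the parent is corrupted (consistent with 0.4%/base over
  20–38 bp plus indels), so the expected error-read count of parent p is
  λ = 0.1 × count(p), and a child is mergeable only if its count does not
  exceed the Poisson(λ) quantile at 1 − 10⁻⁶.  The parent count used is the
  centroid's *own* observed count, not its running aggregate, keeping the
  result order-independent.  Among admissible parents the nearest wins
  (then higher count, then lexicographic).
* Unmerged sequences seen at least twice become centroids; singletons that
  match nothing go to an explicit unassigned pool, so Σ aggregated +
  Σ unassigned = Σ input is asserted, never assumed.

Levenshtein distance (not Hamming) is used so indel errors — which the
simulator generates at realistic rates for repetitive barcodes — are
correctable.

**Evaluation.**  True barcodes (those that generated ≥ 1 read) are matched
to centroids: exact sequence match first, otherwise the centroid holding the
plurality of the barcode's descendant reads, larger barcodes claiming
contested clusters first.  Unmatched true barcodes are false negatives,
reported separately as below-threshold (no surviving descendant cluster) vs
merged into another true barcode, since the two have different remedies.
Centroids matched to no true barcode are false positives (fraction of
inferred centroids).  Matched pairs with centroid ≠ truth are
wrong-sequence errors — cheaper than false positives because frequencies are
preserved.  Pearson R is computed on log read counts over matched pairs.

**Indel-rate estimation** mirrors how the rates are measured from real
count tables: for each run length n, the top 50 sequences with a maximal
run of exactly n and > 100 reads are treated as true; their ±1/±2-repeat
variants (rest of the sequence identical, fewer reads) supply the indel
numerator, and parent + indel + single-substitution reads the denominator.
Run lengths with no qualifying parent yield NaN, not zero.  Applied to
simulated data the estimator recovers the generator's rate within binomial
confidence intervals (tested with substitutions disabled, which isolates
the indel channel; with substitutions on, variants carrying an additional
substitution no longer match the "rest identical" template, deflating the
estimate by roughly the per-read substitution fraction).

## Problem sizes and reproducibility

The package's benchmark harness (`barcodekit.benchmark`) defaults to 10^4
barcodes and ~2.5M expected reads — the full study design scaled by 10× with
identical mixture proportions and error model — which completes in a few
minutes on one CPU and reproduces the same metric regime (Pearson R of log
abundances rounding to 1.0, FN and FP below 1%).  The collision analysis
runs 5 replicates of 10^5 15-mers with the exact neighbor search.  Every
stochastic step derives its seed from a single integer via
`derive_seed(seed, label)`, so identical configurations produce identical
output bytes.

## Known limitations

* No PCR-cycle-explicit amplification, GC-dependent efficiency, or
  per-cycle quality model; the simulator's substitution process is uniform
  over positions and reads.  Passing benchmarks therefore demonstrates
  correctness of the pipeline against this error model, not against every
  platform artifact (e.g. jackpot PCR errors are represented only through
  the generic error channel).
* Indels are simulated for mononucleotide runs only; dinucleotide-run
  indel *estimation* is supported, but the generator does not produce them.
* The regex ladder's fuzzy levels allow exactly one edit per flank; deeper
  flank corruption requires the alignment method.
* Extraction does not attempt paired-end merging, reverse-strand layouts
  beyond an explicit declaration, or recovery of reads missing both flanks.
* The exponential fmax formula and the analytic collision fraction assume
  fully degenerate (N×L) libraries; constrained designs need the simulated
  routes.
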