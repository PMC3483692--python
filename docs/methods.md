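# Methods

## The assay and its in-silico model

`tagdge` analyses NlaIII/MmeI tag libraries ("DGE" or SAGE-style
profiling): cDNA is digested with NlaIII (recognition site CATG), and
MmeI cuts 17 bp downstream of the ligated adaptor, so every transcript
is represented by a 21-bp signature — the 4-bp CATG site plus the next
17 bp — captured at the transcript's 3'-most CATG. Expression is then a
counting problem: how many times each signature occurs in each library.

The package models this end to end:

1. **Reference tag database** (`refdb`). Every CATG+17 window of every
   reference sequence, on both the sense strand and its reverse
   complement, becomes a virtual tag. Both strands are indexed because
   EST-derived unigene assemblies have unreliable orientation. The
   3'-most full-length sense-strand window is flagged *canonical*; this
   flag is what the simulator sequences, but mapping consults every
   indexed site. A gene is *taggable* iff it yields at least one
   virtual tag. Windows containing non-ACGT characters are skipped
   (they could never be observed as a clean tag).

2. **Clean-tag filtering** (`preprocess`). A raw tag survives if it has
   length 21, does not begin with a configured adaptor prefix, contains
   only A/C/G/T, and has library copy number ≥ 2. Rules are applied in
   the order malformed → adaptor → N → singleton so the removal
   counters are unambiguous; singleton status is judged on the
   post-N-filter multiset. Raw totals always reconcile:
   raw = clean + Σ removed. The default adaptor list is empty (adaptor
   sequences are platform-specific); the simulator's own prefix is
   passed explicitly in the pipeline.

3. **Mapping** (`tagmap`). A clean tag is first looked up verbatim;
   only if there is no exact site are its 63 Hamming-distance-1
   neighbours consulted (exact hits take precedence — the standard
   choice, which avoids inflating ambiguity). The matched *gene set*
   determines the status: one gene → unambiguous, several → ambiguous,
   none → unknown. Multiple sites within one gene (either strand)
   still count as one gene. Ties at distance 1 across genes are left
   ambiguous; there is no scoring tie-break.

4. **Quantification** (`quantify`). A gene's raw count is the sum of
   its unambiguous tag counts. Ambiguous tags matching 2–20 genes are
   then distributed across their candidates in proportion to the
   candidates' unambiguous counts, in a single pass (equal split when
   no candidate has unique evidence); tags matching more than 20 genes
   are discarded but accounted, so mapped mass is conserved. TPM is
   distributed count / clean-tag total × 10⁶. The denominator is
   deliberately *clean* tags, not mapped tags — the two differ by the
   unknown-tag fraction, and using clean totals keeps libraries with
   different mappable fractions comparable. Saturation curves
   subsample the library without replacement (prefixes of one shuffle
   per replicate, which makes each replicate's curve monotone by
   construction) and count genes with ≥ 1 unambiguous tag.

## Differential expression

With one library per stage there are no biological replicates; the only
tractable sampling model is the tag-counting process. The
Audic–Claverie posterior predictive is used: given count x in a library
of N₁ clean tags, the count Y in a library of N₂ follows

    P(Y = k | x) = (N₂/N₁)^k (x+k)! / (x! k!) / (1 + N₂/N₁)^(x+k+1),

i.e. Y | x ~ NegativeBinomial(x+1, N₁/(N₁+N₂)). Tails are evaluated
exactly via the regularized incomplete beta function (each tail with
its own evaluation — never as 1 − other, which would lose all precision
for extreme counts). The two-sided p-value is

    p = min(1, 2 · min(P(Y ≤ y), P(Y > y))).

Taking the complementary pair (≤, >) rather than the point-inclusive
pair (≤, ≥) makes the p-value *exactly* invariant under exchanging the
libraries, p(x, y, N₁, N₂) = p(y, x, N₂, N₁); the point-inclusive
convention only holds this symmetry approximately when N₁ ≠ N₂.

A gene is called differentially expressed between two stages when it
clears all four parts of the filter:

* TPM ≥ 20 in at least one of the two stages (detection-reliability
  floor; tag counts below this are dominated by sampling noise),
* p ≤ 0.001,
* |log₂(TPM_B / TPM_A)| ≥ 1,
* Benjamini–Hochberg q < 0.05, the BH family being the genes passing
  the TPM filter within that one comparison (comparisons are reported
  separately, so families are not pooled).

Numerical conventions: a zero TPM is replaced by the TPM equivalent of
a single tag (10⁶ / clean total of that library) before forming the
ratio, a detection-limit floor that keeps ratios finite; fractional
distributed counts are rounded to the nearest integer for the count
test only, while TPM keeps the fractional value. DE testing defaults to
distributed counts with a flag (`use_distributed=False`) for
unambiguous-only counts.

Operating characteristics (measured by `scripts/acceptance.py` and the
test suite, not asserted from theory): on a null simulation (2,000
genes, two libraries of 3×10⁵ tags from identical abundances, 200
pairs) the fraction of TPM-filtered genes with p ≤ 0.001 is ≈ 0.001 and
stays below 0.002; on fourfold changes planted at TPM 100 the four-part
filter reaches sensitivity ≈ 1.0 with false-discovery proportion ≈ 0.

## Trajectory analysis

The nine default stages — 0h, 6h, 24h, 48h (dedifferentiating
hypocotyl explants), NEC (non-embryogenic callus), EC (embryogenic
callus), GE, TE, CE (globular/torpedo/cotyledon embryos) — are grouped
into three developmental-process windows over consecutive-stage
comparisons: dedifferentiation (0h→6h→24h→48h→NEC), transition
(NEC→EC), and embryo development (EC→GE→TE→CE). Up/down histograms are
computed per consecutive comparison (the windows are defined on
consecutive stages; a fixed-baseline mode would answer a different
question). A gene belongs to a process if it is DE in ≥ 1 comparison of
that window; the three-process Venn diagram reports all seven exclusive
regions.

**Clustering.** Expression profiles are log₂(TPM+1), standardized per
gene and rescaled to unit norm. On such vectors the Pearson correlation
is the plain dot product and 1 − r = ‖u − v‖²/2, so k-means with
squared Euclidean distance on these vectors is exactly k-means under
Pearson correlation distance. Lloyd iteration with k-means++ seeding is
run with a fixed number of restarts under a seeded generator, keeping
the lowest within-cluster scatter; the objective is checked to be
non-increasing at every iteration. Zero-variance profiles map to the
zero vector (r ≡ 0, distance 1 to everything — a neutral convention
that avoids NaNs). "Hierarchical k-means" structure is obtained by
nesting: k types at the top level (default k = 5), then k = 2..4
sub-clusters fitted within each type.

**Choosing k.** The leave-one-stage-out figure of merit: for each held
-out stage, cluster the genes on the remaining stages and score the RMS
deviation of the held-out stage's z-scores from their cluster means;
sum over stages. The knee is the smallest k whose relative improvement
going to k+1 drops below 10%. On synthetic data built from three
well-separated templates the knee sits at k = 3.

## qRT-PCR cross-validation

Relative expression by the 2^−ΔΔCt method: ΔCt = Ct_target −
Ct_reference averaged over replicates (the reference transcript is
polyubiquitin in this assay), ΔΔCt differenced against a baseline
stage, amplification efficiency fixed at 2.0 (no dilution-series
correction). The sequencing side of the comparison uses log₂ TPM ratios
against the same baseline, with the single-tag floor substituted for
zeros, matching the qPCR ratio definition. Concordance is the Pearson
correlation (r and R²) of paired log₂ values after an inner join on
(gene, stage), overall or per stage; groups with fewer than 3 pairs are
skipped with a warning.

## The synthetic-data generator

The generator (`simulate`) produces the study conditions the analysis
assumes, with full ground truth:

* **Transcriptome**: `n_genes` random sequences (default 2,000, length
  300–2,000 nt); a fraction `taggable_fraction` (default 0.94, the
  order observed for the real unigene set) is guaranteed a full-length
  sense CATG site, the remainder carries no CATG at all.
* **True abundances**: each gene gets an archetype — five trajectory
  types plus flat (default mix 10% each type, 50% flat) — realized as
  a log₂ template over the stages (up throughout; down throughout; up
  during dedifferentiation then down; down then up; complex
  double-peaked, with half of those genes sign-flipped to create the
  opposed sub-cluster), scaled by `de_log2fc` (default 2), plus
  per-gene-per-stage jitter (sd 0.3 log₂) and a per-gene baseline
  (log-normal, sd 4 log₂ units, giving roughly the five-decade dynamic
  range of real libraries). Abundances are normalized to sum to 1 per
  stage; true DE flags are recomputable from the abundance table.
* **Libraries**: `library_depth` clean-target tags per stage (default
  3×10⁵ — same shape as the real ~3.5 M-tag libraries at desk scale).
  Only canonical tags are sequenced (the wet protocol); genes without
  a usable site emit nothing and their mass is renormalized away.
  Corruptions: per-base substitution error (default 0.005/base, ~10%
  of 21-mers affected — these become low-count near-miss tags, which
  is precisely what the singleton filter and one-mismatch mapping
  exist for); off-reference tags (default 50% of clean tags, matching
  the real libraries' majority-unknown composition) drawn as
  CATG-anchored species verified unmappable even at one mismatch; and
  adaptor-prefixed, N-containing and unique-singleton tags (1%, 1%,
  2%) that the clean-tag filter removes.

What the generator does **not** model: read-level qualities or FASTQ,
PCR duplicates, fragment-position biases, paralogous gene families with
correlated sequences (ambiguity arises only from shared or near-miss
tags that occur by construction or chance), and biological replicate
variance. Passing tests therefore demonstrate the pipeline's
correctness and its sampling-statistical behaviour, not robustness to
real-library artefacts beyond the corruptions listed.

## Reported study numbers

The accounting module reproduces the published table conventions
exactly: percentages are computed from each row's own absolute numbers
and rounded half-up to two decimals; the Average row carries the
rounded mean of the count columns but the *mean of the per-library
percentages* (the convention of the published table — e.g. 38.06 for
unambiguous tags, where the ratio of means would give 38.08); the
gene-percentage denominator is the full reference gene count (20,671),
which is the only denominator consistent with the printed values. The
published total (32,108,458 clean tags) and means (3,567,606 clean;
1,358,600 unambiguous — the table's rounded value; the running text
floors it to 1,358,599) are recomputed from the nine per-library
counts by `summary_table`.

## Problem sizes

Defaults throughout the test suite and acceptance script use 100–2,000
genes and 10⁴–3×10⁵ tags per library — the same structure as the real
data two orders of magnitude smaller, which keeps every check exact,
seeded and fast while preserving the statistics that matter (counting
noise at the TPM ≥ 20 boundary is governed by absolute counts, so the
null and power simulations use the depth at which that boundary means
counts of ~6, as it does at full scale with proportionally more genes).

## Known limitations

* The one-pass proportional multi-read split is not an EM estimator;
  genes whose evidence is *only* ambiguous receive equal splits.
* The Audic–Claverie test measures sampling significance only; with
  single libraries per stage, "DE" calls conflate biological change
  with any library-preparation difference between samples.
* Mapping is tag-to-tag (no positional or splice awareness) by design;
  the assay itself has no positional information beyond the 3'-most
  site.
* BLAST/GO/KEGG annotation of DE genes is out of scope (external,
  version-dependent databases); the annotation-partition numbers
  appear only as published inputs in the accounting checks.
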