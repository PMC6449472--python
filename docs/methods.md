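# Methods

## Allele-sequence separation

The separation procedure treats the elementary contig set of a heterozygous
diploid assembly as a mixture of haploid-unique contigs, allelic duplicates,
and segmental duplications, and discriminates them by non-repeat alignment
coverage.

**Chaining.** For each ordered contig pair and strand, the self-alignment
matches are chained by an exact maximum-weight increasing-subsequence
dynamic programme (O(n²), vectorized inner maximum): retained matches have
strictly increasing query starts and strictly increasing (forward) or
decreasing (reverse) target starts; weight is summed match length. A
query-side gap above `max_chain_gap` (default 10 kb) splits the chain and
the heaviest fragment is kept. With n matches per pair in the hundreds to
low thousands, exactness is affordable and removes a whole class of
heuristic-chaining artefacts.

**Merging.** At percent-scale heterozygosity an alignment fragments into
short exact or near-exact matches at every SNP and indel (mean segment
≈ 1/divergence ≈ 40 bp at 2.35% + 0.235%). Consecutive chain members whose
query and target gaps are both ≤ `match_join_gap` (default 100 bp, i.e.
clearly intra-alignment discontinuities, not structural breaks) coalesce
into one block before coverage is computed. Without this merge the covered
fraction of a true allelic pair saturates near 0.85–0.90 instead of ~1, and
the 85% decision threshold sits on top of the noise.

**Coverage fraction.** `aligned = |union(blocks) \ mask| /
(contig_length − |mask|)`: repeats are excluded from numerator and
denominator alike, so a contig is judged only on its unique sequence. A
fully repetitive contig has an undefined fraction; it is reported as 0 (and
so retained as haploid — the conservative direction).

**Classification.** Contigs are visited in strictly decreasing length order
(ties lexicographic). Candidate partners are strictly longer contigs still
labeled haploid; the partner with the highest aligned fraction decides.
Thresholds: aligned fraction ≥ 0.85 or shared-read fraction ≥ 0.85 calls
the shorter contig allelic (the two criteria combine with OR; boundary
behavior is ≥, configurable). Contigs already called allelic cannot absorb
later contigs, which prevents transitive chains from emptying the haploid
set. Equal-length pairs have no "shorter" member; both are kept with a
warning. An allelic call whose length-weighted chain identity falls below
`min_chain_identity` (default 0.90) is restored to the haploid set — the
quantifiable proxy for a manual dot-plot check. The procedure is single
pass; it does not re-align after removal.

## k-mer genome profiling

Canonical k-mers (lexicographic min of forward and reverse-complement
encodings; k odd to avoid palindromic ambiguity, default 17) are counted
with a 2-bit packed, binary-doubling vectorized encoder; windows containing
N are skipped. The depth histogram is smoothed with a 3-point moving
average for peak calling only.

* **Error valley**: first depth at which the count sequence turns upward; a
  monotone-decreasing spectrum has no coverage peak and is an error.
* **Peak assignment**: the tallest above-valley peak is the homozygous peak
  unless a companion local maximum exists near twice its depth. This
  disambiguation matters: at h ≈ 2% and k = 17 the number of distinct
  half-depth (heterozygous) k-mer forms exceeds the full-depth forms, so
  the global maximum is the c/2 peak, not c.
* **Genome size**: above-valley k-mer mass divided by the homozygous peak
  depth. Low-depth (error) k-mers are excluded by construction.
* **Heterozygosity**: with `b` = (distinct k-mers between the valley and the
  het/hom midpoint) / (same + 2 × distinct above the midpoint),
  `h = 1 − (1 − b)^(1/k)`. The factor 2 reflects that one heterozygous
  window contributes two half-depth forms while a homozygous window
  contributes one full-depth form; under this weighting `b` estimates
  `1 − (1−h)^k` exactly in the noise-free limit.

The estimator is intentionally simpler than mixture-model spectrum fitting:
no error/repeat components are fit, so accuracy degrades when repeats are
abundant or coverage peaks overlap (c/2 and c separated by less than ~3
standard deviations).

## Read and subread filtering

Illumina rules (checked in fixed order N → low-quality → adapter, first hit
recorded): any N drops the read; more than 20% of bases below Q20 drops it
(strictly greater — exactly 20% is kept); an ungapped overlap of a read
suffix with the adapter prefix longer than 10 bp at ≤ 3 mismatches (or a
full internal adapter occurrence) drops it. A pair is dropped when either
mate fails, keeping the library properly paired. PCR duplicates are exact
(seq1, seq2) tuple re-occurrences among surviving pairs, first kept;
reverse-complement collapsing and positional duplicate marking are out of
scope. Subreads are kept when read score ≥ 0.80 and length ≥ 500 bp (both
boundaries inclusive, mirroring strict "remove if below" rules). Counters
reconcile exactly: kept + Σ dropped = input.

## Repeat masking

The built-in masker is a desk-scale surrogate for homology-based masking,
sufficient because downstream only needs repeat *spans* excluded from
coverage arithmetic. Interspersed repeats: positions covered by any 15-mer
whose multiplicity across the contig set exceeds `freq_threshold` (default
4× the mean multiplicity), in runs of ≥ 50 bp. Tandem repeats: a direct
periodicity scan for ≥ 2 adjacent approximate copies of a pattern of ≤ 6 bp
with mismatch fraction ≤ 0.1 versus the periodic extension of the leading
pattern (a transient excursion above the budget is tolerated within a small
grace window so one mismatch inside an otherwise clean array does not
truncate it). External masks (BED) merge with the built-in ones; merged
masks are canonical (sorted, non-overlapping) and idempotent under merging.

## Variant comparison

Two near-identical molecules are aligned globally with affine gap scoring
(match +1, mismatch −1, gap open −2, gap extend −1; Needleman–Wunsch via
Biopython). SNVs are mismatching aligned columns; an indel event is one
maximal gap run, so a 12-bp deletion is one event. Affine (rather than
unit) gap costs are load-bearing: under unit costs an optimal alignment may
split a multi-base gap into several single-base gaps wherever intervening
bases match by chance, inflating event counts. Circular molecules are first
rotated to a shared unique 21-mer anchor; absence of any shared anchor is
an error. Memory is quadratic; intended scale is tens of kb (a 16-kb pair
aligns in a few seconds).

## Synthetic data

The simulator generates the regime the pipeline assumes, with every planted
difference recorded:

* **Diploid genome** — haplotype 0 is uniform random ACGT with three
  dispersed repeat families (500-bp units at ~99% copy identity) overwritten
  to a target repeat fraction; haplotype 1 applies SNPs (default 2.35%) and
  geometric-length indels (default rate one tenth of the SNP rate, mean
  2 bp — the SNP:indel ratio is a modeling default, configurable) to
  haplotype 0. The variant ledger reconstructs haplotype 1 from haplotype 0
  exactly, which is asserted in tests.
* **Elementary contigs** — primary contigs tile haplotype 0 exactly
  (truncated-normal lengths, mean 50 kb, min 10 kb); a configurable
  fraction of primaries (default 0.6) also emit an allelic copy cut from
  the corresponding haplotype-1 span and truncated by 5–20%, so truth is
  well defined: the allelic copy is always the strictly shorter of its
  pair.
* **Reads** — paired-end reads with substitution errors carrying sub-Q20
  qualities, N injection, 33-bp adapter tails and exact PCR-duplicate
  re-emissions at configurable rates; pair count = ⌈coverage·G/(2·ℓ)⌉.
  Subreads have log-normal lengths and Beta-distributed scores (defaults
  give mean score 0.837).
* **Self-matches** — for each contig pair, k-mers (default k = 21) unique
  within both contigs seed matches that are diagonal-merged and extended to
  maximal exact matches, standing in for an external whole-genome aligner
  so the pipeline runs with no binary dependency. Forward strand only: the
  simulator never emits reverse-complement allelic copies, while the
  chaining and classification code does handle minus-strand matches
  ingested from real PAF/coords input. Identity is 1.0 by construction, so
  the identity-based restoration path is exercised with constructed
  fixtures rather than simulated ones.

What passing on this generator does **not** show: robustness to real
long-read error profiles (chimeras, homopolymer errors), structural
variation beyond small indels, reverse-complement haplotigs, GC bias, or
homology masking of diverged repeat families — conclusions about real data
carry the usual caveats.

## Problem sizes and numerical choices

Evaluation runs use a 2 Mb diploid (≈ 60–70 contigs) for partition tests,
1 Mb at 50× for genome-size recovery, and 0.5–1 Mb diploids at 25×/haplotype
for heterozygosity recovery — sizes at which every stage is exact rather
than subsampled and a full run stays interactive. Determinism: every
stochastic stage takes a seed; the pipeline derives per-stage child seeds
from one master seed via SHA-256, so stages are independently reproducible.
Chain DP ties resolve to the earliest candidate by match order
(sorted by query then target start); classification ties (equal aligned
fraction) resolve to the lexicographically first partner.
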