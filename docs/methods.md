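# Methods

## Coordinate model and overlap rule

All coordinates are 0-based half-open (BED convention); RepeatMasker
`genoStart` is treated as 0-based per the UCSC table convention. Overlap
between two intervals is strand-blind and requires at least `min_bp`
shared bases (default 1). The ≥ 1 bp rule is used uniformly: for sharing
across species, for the CTCF/YY1 co-binding partition, and for feature
overlap. The replicate-merge rule keeps events present (≥ 1 bp overlap)
in every replicate — with the first replicate's coordinates, a convention
chosen for determinism — plus replicate-unique events with per-event
FDR < 0.05.

## Projection and conservation classification

Orthology is represented as blocks of per-species segments; within a
species, segments must not overlap, which makes binary search exact. An
interval is projected block-by-block: the overlapped sub-interval is
mapped by offset, proportionally rescaled when segment lengths differ
(floor on the start offset, ceiling on the end offset, so a non-empty
interval never collapses), and coordinate-reversed across opposite
strands. An anchor event projecting to several blocks in a target species
is shared if *any* projected piece overlaps a peak — the most permissive
reading of the ≥ 1 bp rule.

Class labels are assigned from the sharing count s (own species included)
among K species: s = K → ALL, s = 2 → TWO_WAY, s = K−1 → SIX_WAY (its
name reflecting the seven-species study design), 3 ≤ s ≤ K−2 →
THREE_TO_FIVE, and s = 1 → SPECIES_SPECIFIC when the event has block
coverage toward at least one other species, otherwise UNALIGNED. The
TWO_WAY check precedes the K−1 check so small-K toy worlds behave
sensibly. Pairwise shared fractions are means over the two anchoring
directions, because anchoring is not symmetric at the event level;
classifications themselves are reported per anchor species. The FDR
sensitivity sweep re-filters the partner species' peaks at each grid
cutoff and reports the raw per-cutoff shared fraction without further
aggregation, since how such a sweep should be pooled across species is a
reporting choice best left to the caller.

## Co-binding classes, features, expression

The partition is exhaustive and exclusive per factor; an event
overlapping several partners yields one pair per overlap but is tallied
once. Feature association compares per-species overlap fractions of
CTCF-only versus CTCF–YY1 events with a two-sided Mann–Whitney rank-sum
test across species; species with an empty class are dropped from the
test with a logged warning. Transcripts are assigned to classes by ≥ 1 bp
overlap with priority CTCF–YY1 > CTCF-only > YY1-only, so a transcript
touching at least one co-bound pair always lands in the co-bound class.
The expression test is the two-sided rank-sum by default: the classes are
unpaired samples, for which a signed-rank test is not well defined; a
signed-rank variant is available behind a flag but requires equal class
sizes and is not endorsed.

## Repeat enrichment and ages

The background probability p_bg for a family is the median, over `n_rand`
(default 100) randomizations, of the fraction of events overlapping the
family when each event is re-placed uniformly on its own chromosome with
its length preserved. Uniform placement with per-chromosome length
preservation is the simplest background consistent with shuffled-interval
randomization; overlaps among randomized events are permitted. p_bg is
floored at 1/(n·n_rand + 1) so a zero median cannot produce a degenerate
test. The p-value is the exact upper binomial tail P(X ≥ k); k counts
*events* overlapping ≥ 1 element of the family, not element hits.
Benjamini–Hochberg correction is applied across families within a
species, significance is read at adjusted p ≤ 0.01, and −log p is
reported in base 10. Repeat age is (milliDiv/1000)/μ with μ = 2.2e−9
(mammalian) or 4.5e−9 (rodent) substitutions per bp per year. Summit
profiles use 200 windows of 50 bp (10 kb) centered on each summit;
windows running off the chromosome are zero-filled and the event flagged
as truncated.

## Motif-word statistics

PWM scores are log2(p_i(base)/p_i(consensus)) summed over positions, so
the consensus word scores exactly 0 and everything else is ≤ 0; the
default match cutoff is −15. Both strands are scanned; a minus-strand hit
records the reverse complement of the genomic window (the word in PWM
orientation), and overlapping hits on opposite strands at the same locus
count separately. Windows containing any non-ACGT base are skipped; a PWM
with zero probability at a consensus base is rejected.

Word tables keep hits whose start position lies inside a bound region;
`factor` is the *merged* bound bases divided by 10⁶, and words whose
maximum raw count across species is below 5 are dropped — the threshold
applies to raw counts because normalized counts would make it
unit-dependent. normWord uses add-one pseudocounts on both sides of the
log ratio; clade-level nocc is the clade maximum, mirroring the maximum
over the comparison set. Selection fits the sample mean/SD of all
normWord values (a moment fit; the null is unimodal and approximately
normal by construction), converts each score to an upper-tail p, and
applies Benjamini–Hochberg at FDR 0.05; the implied normWord cutoff is
the smallest selected score, reported as +∞ when nothing passes.
Repeat-embedded counting requires the whole L-mer to lie inside a single
annotated repeat element.

## The synthetic world

The generator emulates the data a multi-primate LCL ChIP-seq comparison
supplies, with known ground truth:

* **Species.** Seven primate-like species at divergence times 0, 6, 9,
  16, 29, 29 and 40 My from the anchor, each with a 10 Mb two-chromosome
  genome (6 + 4 Mb). The reduced genome keeps a full analysis under a
  second while leaving every rate estimable; sizes scale linearly.
* **Alignment.** Blocks of ~6 kb alternate with exponential gaps to cover
  an `alignable_fraction` (default 0.6) of the anchor genome. Per-block
  membership of a non-anchor species is Bernoulli(exp(−d/τ)) with
  τ = 60 My, so sharing declines smoothly with divergence; 10 % of
  non-anchor segments sit on the minus strand to exercise coordinate
  reversal. Segments are equal-length within a block: alignments are
  treated as a black-box orthology map, and indel structure is not
  modeled.
* **Events.** Each block is cut into 600 bp slots and every planted event
  group occupies exactly one slot, so orthologous groups can never
  collide after projection and planted class labels are recovered exactly
  up to sampling noise. 2000 CTCF event groups draw a class from the
  planted proportions (0.10 unaligned, 0.10 species-specific, 0.10
  two-way, 0.25 three-to-five, 0.15 six-way, 0.30 all); slots are
  allocated smallest-adequate-membership-first so blocks shared by many
  species remain available for the classes that need them. Events are
  200–400 bp with uniform summits, gamma-distributed scores and FDR
  uniform below 0.05. A class-dependent fraction of CTCF groups (0.15
  rising to 0.45 for the all-species class) receives a co-located YY1
  event, emulating the observed association of conserved CTCF binding
  with YY1; 600 YY1-only groups and 150 species-specific noise events per
  non-anchor species complete the sets.
* **Repeats.** For a family with planted enrichment e, the number of
  copies placed directly onto randomly chosen events is
  n·p₀·(e−1)/(1−p₀), with p₀ the expected background overlap rate from
  the family's footprint; the remainder fall uniformly, so the expected
  event-overlap rate is e times background. milliDiv values are normal
  (clipped at 0) per family.
* **Words.** A background vocabulary of 300 random 14-mers occurs at a
  common rate of 15 per Mb of bound sequence in every species (Poisson
  counts, positions uniform inside events), so null normalized
  occurrences are exchangeable; the planted word occurs at `fold` (10)
  times that rate in the focal species only.
* **Expression.** Transcripts span sampled events of each co-binding
  class (500 per class) and draw log2 values from N(5 + shift, 1) with a
  per-class planted shift.

All generators are pure functions of (config, seed); sub-generators draw
from independent streams spawned from the single world seed, so
regenerating any component is reproducible in isolation.

What the generator does *not* model — read-level noise, peak-caller
artifacts, sequence evolution, GC/mappability biases, correlated repeat
landscapes, cell-line effects — bounds what passing tests show: they
demonstrate that the statistics recover planted structure at realistic
sizes and control their error rates under the stated null, not that the
pipeline is robust to every artifact of real ChIP-seq data.

## Problem sizes and tolerances

Verification runs use the full study-scale world (7 species, 2000 CTCF
events, 10 Mb genomes). Class-proportion recovery is checked within 3
binomial standard errors at n = 2000; the divergence trend requires
Pearson r < −0.9; projection is compared exactly against per-base offset
mapping on 1000 random intervals over 100 random blocks; binomial tails
are compared against direct summation to 1e−12 for all k, n ≤ 200; the
repeat test must keep its null significant fraction at adjusted p ≤ 0.01
at or below 0.02 over 20 seeds and flag a planted 5× enrichment in ≥ 95 %
of 50 seeds; word selection must recover a planted 10× expansion in
≥ 95 % of 50 seeds with ~0 null selections; the expression comparison
must reject a +2 log2 shift at p < 1e−6 with n = 500 per class and hold a
~5 % null rejection rate over 200 replicates; and a full pipeline re-run
with a fixed seed must be bit-identical.

## Known limitations

* Projection is not indel-aware; proportional rescaling is a coarse
  substitute for gapped alignment columns.
* The intersection-merge keeps first-replicate coordinates; other
  conventions (span union, midpoint) would shift boundaries by a few bp.
* The binomial repeat test treats events as exchangeable; clustered
  binding would make the background overdispersed, which the
  randomization median only partly absorbs.
* The normal fit for normWord selection is a moment fit; heavy-tailed
  word backgrounds (e.g. strongly repeat-driven vocabularies) would merit
  a robust location/scale estimate instead.
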