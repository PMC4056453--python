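# primatecons

Comparative analysis of transcription-factor binding across species:
conservation classification of ChIP-seq binding events over orthology
blocks, CTCF–YY1 co-binding and its feature/expression associations,
randomization-calibrated repeat-element enrichment, and motif-word
statistics for detecting species-specific binding-sequence expansions.
A seeded synthetic-world generator reproduces the statistical structure of
a multi-primate ChIP-seq study so every stage is testable end to end
without any downloads.

The package is aimed at regulatory-genomics analysts who have per-species
peak calls (BED-like, with score/FDR/summit), an orthology-block table
standing in for a whole-genome multiple alignment (e.g. EPO), RepeatMasker
tables, feature annotations and expression estimates, and who want the
cross-species conservation/co-binding/repeat/motif-word analyses as
reusable, tested library calls.

## The statistics at the core

**Conservation classes.** Each binding event of an anchor species is
projected through alignment blocks onto every other study species; a
projection overlapping (≥ 1 bp) a peak in the other species marks the
event *shared* with it. The sharing count (own species included) maps onto
six classes: unaligned, species-specific (aligned), shared between exactly
two species, among three to five, among K−1, or among all K species.
Pairwise shared fractions are averaged over the two anchoring directions,
and their Pearson correlation with divergence time summarizes the
evolutionary trend.

**Co-binding partition.** A CTCF event overlapping (≥ 1 bp) any YY1 event
is CTCF–YY1 co-bound, and symmetrically; classes are compared for feature
overlap (e.g. CpG islands) across species and for log2 transcript
expression with two-sided Mann–Whitney rank-sum tests.

**Repeat enrichment.** For each repeat family, the number of events *k*
(of *n*) overlapping the family is tested against Binomial(n, p_bg), where
p_bg is the median overlap fraction of *n* uniformly re-placed events over
100 randomizations; p-values are Benjamini–Hochberg corrected within a
species. Repeat copies are aged as (milliDiv/1000)/μ with μ = 2.2×10⁻⁹
(mammal) or 4.5×10⁻⁹ (rodent) substitutions per bp per year.

**Motif words.** PWM matches are collected as exact L-mers (14-mers for
CTCF); per species *j* and word *i*,

    nocc[i,j] = count[i,j] / factor[j],   factor[j] = bound bases / 10⁶

and a word's specificity for a focal species (or clade) S against a
comparison set R is

    normWord = log2( (nocc(S) + 1) / (max_{r∈R} nocc(r) + 1) ).

Expanded words are selected by fitting a normal distribution to all
normWord values and controlling the upper tail at FDR 0.05
(Benjamini–Hochberg).

## Worked example

```python
from primatecons import synthetic, classify_conservation, pairwise_shared_fraction, \
    overlap_divergence_correlation, classify_cobinding

cfg = synthetic.default_world(seed=1)          # 7 species, 2000 CTCF events
amap = synthetic.generate_alignment_map(cfg)
events, truth = synthetic.generate_binding_events(cfg, amap)

sets = {sp: events[sp]["CTCF"] for sp in events}
cls = classify_conservation(sets, amap, anchor="hsap")
for label, frac in cls.class_fractions().items():
    print(f"{label:<17s} {frac:.3f}")

fractions = {sp: pairwise_shared_fraction(sets["hsap"], sets[sp], amap)
             for sp in sets if sp != "hsap"}
r, p = overlap_divergence_correlation(fractions, cfg.divergence_map)
print(f"divergence trend: r = {r:.2f} (p = {p:.4f})")

part = classify_cobinding(events["hsap"]["CTCF"], events["hsap"]["YY1"])
print(f"CTCF events co-bound by YY1: {part.fraction_ctcf_cobound():.2f}")
print(f"YY1 events co-bound by CTCF: {part.fraction_yy1_cobound():.2f}")
```

prints

```
UNALIGNED         0.106
SPECIES_SPECIFIC  0.091
TWO_WAY           0.111
THREE_TO_FIVE     0.248
SIX_WAY           0.143
ALL               0.300
divergence trend: r = -0.97 (p = 0.0017)
CTCF events co-bound by YY1: 0.29
YY1 events co-bound by CTCF: 0.49
```

The recovered class fractions match the generator's planted proportions
(0.10/0.10/0.10/0.25/0.15/0.30), pairwise sharing declines steeply with
divergence time, and roughly a third of CTCF events carry a co-located
YY1 event while about half of YY1 events sit on CTCF.

The same analysis runs from the shell:

```sh
primatecons simulate --seed 1 --out world/
primatecons run --config run.yaml      # simulate -> conserve -> cobind -> repeats -> words
```

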