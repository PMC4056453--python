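"""Seeded generator of multi-species synthetic binding "worlds".

The generator emulates the statistical structure the comparative analysis
assumes, so every downstream stage can be exercised with known ground truth:

* K species with known divergence times from an anchor species;
* an orthology-block map tiling a configurable fraction of the anchor
  genome, with per-block species membership decaying exponentially with
  divergence time (so pairwise sharing declines with distance);
* binding events planted with known conservation-class memberships,
  summits, scores and per-event FDRs; a class-dependent fraction of CTCF
  events receives a co-located YY1 event;
* repeat families with planted binding enrichment and milliDiv ages;
* motif-word occurrences with planted species-specific expansions;
* transcript expression values with planted shifts by co-binding class.

Orthology is simulated in the anchor coordinate frame: every block is cut
into fixed-size *slots* and each planted event group occupies exactly one
slot, so event groups can never collide across species after projection.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import AlignmentBlock, AlignmentMap, Segment, write_block_table
from .core import (
    BindingEventSet,
    FeatureAnnotation,
    GenomicInterval,
    RepeatElement,
    write_binding_bed,
    write_features_bed,
    write_repeatmasker,
)

CLASS_LABELS = [
    "UNALIGNED",
    "SPECIES_SPECIFIC",
    "TWO_WAY",
    "THREE_TO_FIVE",
    "SIX_WAY",
    "ALL",
]

# sub-stream identifiers so each generator draws from an independent stream
_STREAM_MAP = 1
_STREAM_EVENTS = 2
_STREAM_REPEATS = 3
_STREAM_EXPRESSION = 4
_STREAM_WORDS = 5
_STREAM_FEATURES = 6
_STREAM_TRANSCRIPTS = 7


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class SpeciesConfig:
    """One study species: name, chromosome lengths, divergence from anchor (My)."""

    name: str
    genome: dict[str, int]
    divergence_my: float = 0.0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.genome.values()):
            raise ValueError(f"{self.name}: chromosome lengths must be positive")
        if self.divergence_my < 0:
            raise ValueError(f"{self.name}: divergence_my must be >= 0")


@dataclass
class RepeatSpec:
    """A planted repeat family: element count, enrichment fold and age model."""

    rep_name: str
    count: int
    planted_enrichment: float = 1.0
    milli_div_mean: float = 100.0
    milli_div_sd: float = 20.0
    length: int = 300
    rep_class: str = "LTR"
    rep_family: str = "ERVK"


@dataclass
class WordSpec:
    """A planted motif-word expansion in one focal species.

    ``fold`` multiplies the focal species' expected normalized occurrence of
    ``word`` relative to the shared background rate (occurrences per Mb of
    bound sequence).
    """

    word: str = "TGGCCACCAGGGGG"
    species: str | None = None
    fold: float = 10.0
    n_background_words: int = 300
    rate_per_mb: float = 15.0


@dataclass
class ExpressionSpec:
    """Planted log2-expression shifts per co-binding class."""

    shifts: dict[str, float] = field(
        default_factory=lambda: {"CTCF_ONLY": 0.0, "CTCF_YY1": 0.0, "YY1_ONLY": 0.0}
    )
    n_per_class: int = 500
    base_mean: float = 5.0
    sd: float = 1.0


DEFAULT_CLASS_PROPORTIONS = {
    "UNALIGNED": 0.10,
    "SPECIES_SPECIFIC": 0.10,
    "TWO_WAY": 0.10,
    "THREE_TO_FIVE": 0.25,
    "SIX_WAY": 0.15,
    "ALL": 0.30,
}

# co-binding probability rises with the sharing class, emulating the observed
# association of conserved CTCF events with YY1
DEFAULT_COBIND_PROB = {
    "UNALIGNED": 0.15,
    "SPECIES_SPECIFIC": 0.18,
    "TWO_WAY": 0.22,
    "THREE_TO_FIVE": 0.30,
    "SIX_WAY": 0.38,
    "ALL": 0.45,
}

DEFAULT_CPG_PROB = {"CTCF_ONLY": 0.15, "CTCF_YY1": 0.50, "YY1_ONLY": 0.15}


@dataclass
class WorldConfig:
    """Everything the synthetic world depends on, including the seed."""

    species: list[SpeciesConfig]
    n_events: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    alignable_fraction: float = 0.6
    block_length: int = 6000
    slot_length: int = 600
    event_length: tuple[int, int] = (200, 400)
    membership_tau_my: float = 60.0
    minus_strand_prob: float = 0.1
    cobind_prob: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COBIND_PROB))
    n_yy1_only: int = 600
    extra_specific_per_species: int = 150
    repeat_spec: list[RepeatSpec] = field(default_factory=list)
    word_spec: WordSpec | None = None
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        if any(not (0 <= v <= 1) for v in self.class_proportions.values()):
            raise ValueError("class proportions must lie in [0, 1]")
        if not (0 <= self.alignable_fraction <= 1):
            raise ValueError("alignable_fraction must lie in [0, 1]")
        if self.event_length[1] + 2 > self.slot_length:
            raise ValueError("slot_length must exceed the maximum event length")

    @property
    def anchor(self) -> SpeciesConfig:
        return self.species[0]

    @property
    def divergence_map(self) -> dict[str, float]:
        return {s.name: s.divergence_my for s in self.species}


def default_species(genome: Mapping[str, int] | None = None) -> list[SpeciesConfig]:
    """Seven primate-like species ordered by divergence time from the anchor."""
    if genome is None:
        genome = {"chr1": 6_000_000, "chr2": 4_000_000}
    times = [("hsap", 0.0), ("ptro", 6.0), ("ggor", 9.0), ("ppyg", 16.0),
             ("mmul", 29.0), ("pham", 29.0), ("cjac", 40.0)]
    return [SpeciesConfig(n, dict(genome), t) for n, t in times]


def default_world(seed: int = 0, **overrides) -> WorldConfig:
    """The study-condition world: 7 species, 2000 events, default proportions."""
    cfg = WorldConfig(species=default_species(), seed=seed)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown WorldConfig field {key!r}")
        setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg


# ------------------------------------------------------------ alignment map

def generate_alignment_map(config: WorldConfig) -> AlignmentMap:
    """Tile the anchor genome with orthology blocks.

    Blocks alternate with exponentially distributed gaps so that
    ``alignable_fraction`` of the anchor genome is covered in expectation.
    Per-block species membership is Bernoulli(exp(-divergence/tau)); the
    anchor is a member of every block.  Non-anchor segments are laid out on
    that species' own chromosomes with small random inter-segment gaps, and
    carry a minus strand with probability ``minus_strand_prob``.
    """
    rng = _rng(config.seed, _STREAM_MAP)
    f = config.alignable_fraction
    if f == 0:
        return AlignmentMap([])
    anchor = config.anchor
    others = config.species[1:]
    tau = config.membership_tau_my
    member_p = {s.name: math.exp(-s.divergence_my / tau) for s in others}
    gap_mean = config.block_length * (1.0 - f) / f
    blocks: list[AlignmentBlock] = []
    cursors = {s.name: {c: 0 for c in s.genome} for s in others}
    bi = 0
    for chrom, length in anchor.genome.items():
        pos = 0
        while True:
            gap = int(rng.exponential(gap_mean)) if gap_mean > 0 else 0
            blen = int(rng.uniform(0.8, 1.2) * config.block_length)
            start = pos + gap
            if start + blen > length:
                break
            segs = {anchor.name: Segment(chrom, start, start + blen, "+")}
            for s in others:
                if rng.random() < member_p[s.name]:
                    cur = cursors[s.name][chrom] + int(rng.integers(0, 201))
                    if cur + blen > s.genome.get(chrom, 0):
                        raise ValueError(
                            f"alignable_fraction {f} not achievable on "
                            f"{s.name}:{chrom} (genome too short)"
                        )
                    strand = "-" if rng.random() < config.minus_strand_prob else "+"
                    segs[s.name] = Segment(chrom, cur, cur + blen, strand)
                    cursors[s.name][chrom] = cur + blen
            blocks.append(AlignmentBlock(f"b{bi:06d}", segs))
            bi += 1
            pos = start + blen
    return AlignmentMap(blocks)


# ----------------------------------------------------------- event planting

def _map_offsets(seg_from: Segment, seg_to: Segment, off_s: int, off_e: int) -> tuple[int, int]:
    """Map block-local offsets between segments (generator-side arithmetic)."""
    lf, lt = seg_from.length, seg_to.length
    if lf != lt:
        off_s2 = (off_s * lt) // lf
        off_e2 = -((-off_e * lt) // lf)
    else:
        off_s2, off_e2 = off_s, off_e
    if (seg_from.strand == "-") != (seg_to.strand == "-"):
        return seg_to.start + (lt - off_e2), seg_to.start + (lt - off_s2)
    return seg_to.start + off_s2, seg_to.start + off_e2


class _SlotPool:
    """Slot allocator over alignment blocks, bucketed by other-member count."""

    def __init__(self, amap: AlignmentMap, anchor: str, slot_length: int,
                 rng: np.random.Generator):
        self.amap = amap
        self.anchor = anchor
        self.slot_length = slot_length
        self.block_others: list[list[str]] = []
        self.free: list[list[tuple[int, int]]] = []  # per block, anchor-frame slot spans
        self.by_species: dict[str, list[int]] = {}
        max_m = 0
        for bi, block in enumerate(amap.blocks):
            seg = block.segments[anchor]
            others = sorted(sp for sp in block.segments if sp != anchor)
            self.block_others.append(others)
            n_slots = seg.length // slot_length
            slots = [
                (seg.start + i * slot_length, seg.start + (i + 1) * slot_length)
                for i in range(n_slots)
            ]
            rng.shuffle(slots)
            self.free.append(slots)
            for sp in others:
                self.by_species.setdefault(sp, []).append(bi)
            max_m = max(max_m, len(others))
        # lazy bucket queues: block index repeated once per initial slot
        self.bucket: list[list[int]] = [[] for _ in range(max_m + 1)]
        for bi, slots in enumerate(self.free):
            self.bucket[len(self.block_others[bi])].extend([bi] * len(slots))
        for q in self.bucket:
            rng.shuffle(q)
        self.rng = rng

    def take(self, min_others: int) -> tuple[int, tuple[int, int]] | None:
        """Pop a free slot from any block with >= min_others other members.

        Buckets are consumed smallest-adequate-first so blocks shared by many
        species stay available for the classes that require them.
        """
        for m in range(min_others, len(self.bucket)):
            while self.bucket[m]:
                bi = self.bucket[m].pop()
                if self.free[bi]:
                    return bi, self.free[bi].pop()
        return None

    def take_for_species(self, species: str) -> tuple[int, tuple[int, int]] | None:
        """Pop a free slot from a block in which ``species`` is a member."""
        blocks = self.by_species.get(species, [])
        if not blocks:
            return None
        for _ in range(200):
            bi = blocks[int(self.rng.integers(0, len(blocks)))]
            if self.free[bi]:
                return bi, self.free[bi].pop()
        for bi in blocks:  # fallback: linear scan
            if self.free[bi]:
                return bi, self.free[bi].pop()
        return None


def _anchor_gaps(config: WorldConfig, amap: AlignmentMap) -> dict[str, list[tuple[int, int]]]:
    anchor = config.anchor
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in anchor.genome}
    for block in amap.blocks:
        seg = block.segments[anchor.name]
        spans[seg.chrom].append((seg.start, seg.end))
    gaps: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in anchor.genome.items():
        covered = sorted(spans[chrom])
        out = []
        pos = 0
        for s, e in covered + [(length, length)]:
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        gaps[chrom] = out
    return gaps


def generate_binding_events(
    config: WorldConfig, amap: AlignmentMap
) -> tuple[dict[str, dict[str, BindingEventSet]], pd.DataFrame]:
    """Plant CTCF and YY1 binding events with known conservation classes.

    Returns ``(events, truth)`` where ``events[species][factor]`` is a
    :class:`BindingEventSet` and ``truth`` records, per planted event group,
    its factor, conservation class, member species and co-binding flag.
    """
    rng = _rng(config.seed, _STREAM_EVENTS)
    anchor = config.anchor.name
    species_names = [s.name for s in config.species]
    n_species = len(species_names)
    rows: dict[str, dict[str, list]] = {
        sp: {"CTCF": [], "YY1": []} for sp in species_names
    }
    truth_rows: list[dict] = []

    pool = _SlotPool(amap, anchor, config.slot_length, rng) if len(amap) else None
    gap_slots: list[tuple[str, int, int]] = []
    for chrom, gaps in _anchor_gaps(config, amap).items():
        for gs, ge in gaps:
            for i in range((ge - gs) // config.slot_length):
                gap_slots.append(
                    (chrom, gs + i * config.slot_length, gs + (i + 1) * config.slot_length)
                )
    rng.shuffle(gap_slots)

    labels_order = CLASS_LABELS
    probs = np.array([config.class_proportions.get(lab, 0.0) for lab in labels_order])

    def extras_needed(label: str) -> int:
        if label in ("UNALIGNED", "SPECIES_SPECIFIC"):
            return 0
        if label == "TWO_WAY":
            return 1
        if label == "THREE_TO_FIVE":
            lo, hi = 2, n_species - 3
            if hi < lo:
                raise ValueError("THREE_TO_FIVE class infeasible with < 5 species")
            return int(rng.integers(lo, hi + 1))
        if label == "SIX_WAY":
            return n_species - 2
        return n_species - 1  # ALL

    def event_attrs(start: int, end: int):
        summit = int(rng.integers(start, end))
        score = float(4.0 + rng.gamma(2.0, 5.0))
        fdr = float(rng.uniform(0.0, 0.045))
        return summit, score, fdr

    def place_group(gid: str, factor: str, label: str) -> None:
        le = int(rng.integers(config.event_length[0], config.event_length[1] + 1))
        if label == "UNALIGNED":
            if not gap_slots:
                raise ValueError("insufficient unaligned space for requested UNALIGNED events")
            chrom, ss, se = gap_slots.pop()
            off = int(rng.integers(0, se - ss - le + 1))
            start, end = ss + off, ss + off + le
            summit, score, fdr = event_attrs(start, end)
            rows[anchor][factor].append((chrom, start, end, gid, score, ".", fdr, summit))
            truth_rows.append(
                {"group_id": gid, "factor": factor, "label": label,
                 "members": anchor, "cobound": False, "block_id": ".",
                 "chrom": chrom, "start": start, "end": end}
            )
            return
        k = extras_needed(label)
        need_m = max(k, 1)
        taken = pool.take(need_m) if pool is not None else None
        if taken is None:
            raise ValueError(f"no free slot with >= {need_m} other member species "
                             f"for class {label}")
        bi, (ss, se) = taken
        block = amap.blocks[bi]
        others_avail = pool.block_others[bi]
        members = [anchor]
        if k:
            chosen = rng.choice(len(others_avail), size=k, replace=False)
            members += [others_avail[int(c)] for c in sorted(chosen)]
        seg_a = block.segments[anchor]
        off = int(rng.integers(0, se - ss - le + 1))
        a_start, a_end = ss + off, ss + off + le
        cobound = False
        if factor == "CTCF":
            cobound = bool(rng.random() < config.cobind_prob.get(label, 0.0))
        if cobound:
            delta = int(rng.integers(-(le // 3), le // 3 + 1))
            delta = max(ss - a_start, min(delta, se - a_end))
            y_start, y_end = a_start + delta, a_end + delta
        for sp in members:
            seg = block.segments[sp]
            s, e = _map_offsets(seg_a, seg, a_start - seg_a.start, a_end - seg_a.start)
            summit, score, fdr = event_attrs(s, e)
            rows[sp][factor].append((seg.chrom, s, e, gid, score, ".", fdr, summit))
            if cobound:
                ys, ye = _map_offsets(seg_a, seg, y_start - seg_a.start, y_end - seg_a.start)
                summit, score, fdr = event_attrs(ys, ye)
                rows[sp]["YY1"].append((seg.chrom, ys, ye, gid + "_y", score, ".", fdr, summit))
        truth_rows.append(
            {"group_id": gid, "factor": factor, "label": label,
             "members": ",".join(members), "cobound": cobound,
             "block_id": block.block_id, "chrom": seg_a.chrom,
             "start": a_start, "end": a_end}
        )

    ctcf_labels = (
        [labels_order[i] for i in rng.choice(len(labels_order), size=config.n_events, p=probs)]
        if config.n_events
        else []
    )
    for i, label in enumerate(ctcf_labels):
        place_group(f"c{i:05d}", "CTCF", label)
    yy1_labels = (
        [labels_order[i] for i in rng.choice(len(labels_order), size=config.n_yy1_only, p=probs)]
        if config.n_yy1_only
        else []
    )
    for i, label in enumerate(yy1_labels):
        place_group(f"y{i:05d}", "YY1", label)

    # species-specific noise events in the non-anchor species
    if pool is not None and config.extra_specific_per_species:
        for sp in species_names[1:]:
            for i in range(config.extra_specific_per_species):
                taken = pool.take_for_species(sp)
                if taken is None:
                    break
                bi, (ss, se) = taken
                block = amap.blocks[bi]
                seg_a = block.segments[anchor]
                seg = block.segments[sp]
                le = int(rng.integers(config.event_length[0], config.event_length[1] + 1))
                off = int(rng.integers(0, se - ss - le + 1))
                s, e = _map_offsets(seg_a, seg, ss + off - seg_a.start, ss + off + le - seg_a.start)
                summit, score, fdr = event_attrs(s, e)
                gid = f"x_{sp}_{i:05d}"
                factor = "CTCF" if rng.random() < 0.75 else "YY1"
                rows[sp][factor].append((seg.chrom, s, e, gid, score, ".", fdr, summit))
                truth_rows.append(
                    {"group_id": gid, "factor": factor, "label": "OTHER_SPECIFIC",
                     "members": sp, "cobound": False, "block_id": block.block_id,
                     "chrom": seg.chrom, "start": s, "end": e}
                )

    events: dict[str, dict[str, BindingEventSet]] = {}
    from .core import EVENT_COLUMNS

    for sp in species_names:
        events[sp] = {}
        for factor in ("CTCF", "YY1"):
            df = pd.DataFrame(rows[sp][factor], columns=EVENT_COLUMNS)
            events[sp][factor] = BindingEventSet(sp, factor, df)
    truth = pd.DataFrame(
        truth_rows,
        columns=["group_id", "factor", "label", "members", "cobound",
                 "block_id", "chrom", "start", "end"],
    )
    return events, truth


def uniform_event_set(
    species: str,
    factor: str,
    genome: Mapping[str, int],
    n: int,
    rng: np.random.Generator,
    event_length: tuple[int, int] = (200, 400),
) -> BindingEventSet:
    """Uniformly placed scored events: the generator's null binding model."""
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    le = rng.integers(event_length[0], event_length[1] + 1, size=n)
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        starts[i] = rng.integers(0, genome[chroms[ci[i]]] - le[i] + 1)
    ends = starts + le
    summits = starts + rng.integers(0, le)
    return BindingEventSet.from_arrays(
        species, factor,
        [chroms[i] for i in ci], starts, ends, summit=summits,
        score=4.0 + rng.gamma(2.0, 5.0, size=n),
        fdr=rng.uniform(0.0, 0.045, size=n),
        name=[f"u{i:06d}" for i in range(n)],
    )


# ------------------------------------------------------------------ repeats

def generate_repeat_annotation(
    config: WorldConfig,
    events: Mapping[str, Mapping[str, BindingEventSet]],
    species: Sequence[str] | None = None,
) -> tuple[dict[str, list[RepeatElement]], pd.DataFrame]:
    """Place repeat families with planted binding enrichment.

    For each :class:`RepeatSpec`, elements are placed so the probability a
    CTCF binding event overlaps that family is ``planted_enrichment`` times
    the background rate of a uniformly placed interval: a calculated number
    of elements is planted directly onto randomly chosen events, the rest
    fall uniformly.  milliDiv values are drawn from the family's normal age
    model (clipped at 0).
    """
    rng = _rng(config.seed, _STREAM_REPEATS)
    if species is None:
        species = [s.name for s in config.species]
    genome_of = {s.name: s.genome for s in config.species}
    out: dict[str, list[RepeatElement]] = {}
    truth_rows = []
    for sp in species:
        genome = genome_of[sp]
        chroms = list(genome)
        lengths = np.array([genome[c] for c in chroms], dtype=float)
        gsize = lengths.sum()
        ev = events[sp]["CTCF"].df
        n_ev = len(ev)
        le_mean = float((ev.end - ev.start).mean()) if n_ev else 300.0
        elements: list[RepeatElement] = []
        for spec in config.repeat_spec:
            p0 = min(0.5, spec.count * (spec.length + le_mean) / gsize)
            m_planted = 0
            if spec.planted_enrichment > 1.0 and n_ev and p0 < 1:
                m_planted = int(round(n_ev * p0 * (spec.planted_enrichment - 1.0) / (1.0 - p0)))
                if m_planted > min(spec.count, n_ev):
                    raise ValueError(
                        f"{spec.rep_name}: enrichment {spec.planted_enrichment} infeasible "
                        f"with {spec.count} elements and {n_ev} events"
                    )
            milli = np.maximum(
                0, np.round(rng.normal(spec.milli_div_mean, spec.milli_div_sd, size=spec.count))
            ).astype(int)
            # planted copies sit on randomly chosen events (>= 10 bp overlap)
            target_idx = (
                rng.choice(n_ev, size=m_planted, replace=False) if m_planted else []
            )
            j = 0
            for ti in target_idx:
                e_start = int(ev.start.iloc[ti])
                e_len = int(ev.end.iloc[ti] - e_start)
                shift = int(rng.integers(-(spec.length - 10), e_len - 10 + 1))
                r_start = max(0, e_start + shift)
                chrom = ev.chrom.iloc[ti]
                r_start = min(r_start, genome[chrom] - spec.length)
                elements.append(
                    RepeatElement(
                        GenomicInterval(chrom, r_start, r_start + spec.length, "+"),
                        spec.rep_name, spec.rep_class, spec.rep_family, int(milli[j]),
                    )
                )
                j += 1
            n_uniform = spec.count - m_planted
            ci = rng.choice(len(chroms), size=n_uniform, p=lengths / lengths.sum())
            for c in ci:
                chrom = chroms[int(c)]
                r_start = int(rng.integers(0, genome[chrom] - spec.length + 1))
                elements.append(
                    RepeatElement(
                        GenomicInterval(chrom, r_start, r_start + spec.length, "+"),
                        spec.rep_name, spec.rep_class, spec.rep_family, int(milli[j]),
                    )
                )
                j += 1
            truth_rows.append(
                {"species": sp, "rep_name": spec.rep_name, "count": spec.count,
                 "planted_enrichment": spec.planted_enrichment,
                 "n_planted_on_events": m_planted, "background_p": p0}
            )
        elements.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.rep_name))
        out[sp] = elements
    return out, pd.DataFrame(truth_rows)


# ----------------------------------------------------------------- features

def generate_cpg_islands(
    config: WorldConfig,
    partitions: Mapping[str, "object"],
    prob_by_class: Mapping[str, float] | None = None,
    island_length: int = 500,
    n_background: int = 200,
) -> dict[str, list[FeatureAnnotation]]:
    """CpG-island features with a planted preference for co-bound events.

    ``partitions`` maps species to a co-binding partition (see
    :mod:`primatecons.cobinding`); each event receives an island overlapping
    it with a class-dependent probability, plus uniform background islands.
    """
    rng = _rng(config.seed, _STREAM_FEATURES)
    if prob_by_class is None:
        prob_by_class = DEFAULT_CPG_PROB
    genome_of = {s.name: s.genome for s in config.species}
    out: dict[str, list[FeatureAnnotation]] = {}
    for sp, part in partitions.items():
        genome = genome_of[sp]
        feats: list[FeatureAnnotation] = []
        fid = 0
        class_sets = {
            "CTCF_ONLY": part.ctcf_only,
            "CTCF_YY1": part.ctcf_cobound,
            "YY1_ONLY": part.yy1_only,
        }
        for cls, evset in class_sets.items():
            p = prob_by_class.get(cls, 0.0)
            for row in evset.df.itertuples(index=False):
                if rng.random() >= p:
                    continue
                mid = (int(row.start) + int(row.end)) // 2
                start = max(0, mid - island_length // 2)
                start = min(start, genome[row.chrom] - island_length)
                feats.append(
                    FeatureAnnotation(
                        "cpg_island",
                        GenomicInterval(row.chrom, start, start + island_length),
                        f"{sp}_cpg{fid:05d}",
                    )
                )
                fid += 1
        chroms = list(genome)
        lengths = np.array([genome[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=n_background, p=lengths / lengths.sum())
        for c in ci:
            chrom = chroms[int(c)]
            start = int(rng.integers(0, genome[chrom] - island_length + 1))
            feats.append(
                FeatureAnnotation(
                    "cpg_island",
                    GenomicInterval(chrom, start, start + island_length),
                    f"{sp}_cpg{fid:05d}",
                )
            )
            fid += 1
        feats.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.id))
        out[sp] = feats
    return out


# --------------------------------------------------------------- expression

def generate_transcripts(
    config: WorldConfig, partition: "object"
) -> tuple[list[FeatureAnnotation], dict[str, str]]:
    """Transcripts overlapping events of each co-binding class.

    Samples ``n_per_class`` events per class (with replacement when a class
    is smaller) and emits one transcript spanning each sampled event, so the
    planted class label is exactly what overlap-based assignment recovers.
    """
    rng = _rng(config.seed, _STREAM_TRANSCRIPTS)
    n = config.expression_spec.n_per_class
    class_sets = {
        "CTCF_ONLY": partition.ctcf_only,
        "CTCF_YY1": partition.ctcf_cobound,
        "YY1_ONLY": partition.yy1_only,
    }
    transcripts: list[FeatureAnnotation] = []
    labels: dict[str, str] = {}
    tid = 0
    for cls, evset in class_sets.items():
        if len(evset) == 0:
            continue
        idx = rng.choice(len(evset), size=n, replace=len(evset) < n)
        for i in idx:
            row = evset.df.iloc[int(i)]
            t_id = f"T{tid:06d}"
            transcripts.append(
                FeatureAnnotation(
                    "transcript",
                    GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    t_id,
                )
            )
            labels[t_id] = cls
            tid += 1
    return transcripts, labels


def generate_expression(
    config: WorldConfig, class_labels: Mapping[str, str]
) -> pd.DataFrame:
    """log2 transcript estimates with planted per-class mean shifts."""
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    spec = config.expression_spec
    ids = list(class_labels)
    shifts = np.array([spec.shifts.get(class_labels[t], 0.0) for t in ids])
    values = spec.base_mean + shifts + rng.normal(0.0, spec.sd, size=len(ids))
    return pd.DataFrame({"transcript_id": ids, "log2_estimate": values})


# -------------------------------------------------------------- motif words

_BASES = np.array(list("ACGT"))


def _random_words(rng: np.random.Generator, n: int, length: int, exclude: set[str]) -> list[str]:
    words: list[str] = []
    seen = set(exclude)
    while len(words) < n:
        w = "".join(_BASES[rng.integers(0, 4, size=length)])
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def generate_word_hits(
    config: WorldConfig, events: Mapping[str, Mapping[str, BindingEventSet]]
) -> dict[str, pd.DataFrame]:
    """Motif-word occurrences inside bound regions, per species.

    Background words occur at a common rate per Mb of bound sequence, so
    their normalized occurrences are equal across species in expectation.
    The planted word of ``config.word_spec`` occurs at ``fold`` times that
    rate in the focal species only.  Counts are Poisson; positions fall
    uniformly inside randomly chosen CTCF events.
    """
    spec = config.word_spec or WordSpec()
    rng = _rng(config.seed, _STREAM_WORDS)
    length = len(spec.word)
    focal = spec.species or config.species[0].name
    vocab = _random_words(rng, spec.n_background_words, length, {spec.word})
    out: dict[str, pd.DataFrame] = {}
    for sp_cfg in config.species:
        sp = sp_cfg.name
        ev = events[sp]["CTCF"].df
        if not len(ev):
            out[sp] = pd.DataFrame(columns=["chrom", "pos", "strand", "word", "score"])
            continue
        factor = events[sp]["CTCF"].total_bases() / 1e6
        if factor == 0:
            raise ValueError(f"{sp}: zero bound bases")
        all_words = vocab + [spec.word]
        lam = np.full(len(all_words), spec.rate_per_mb * factor)
        if sp == focal and spec.fold != 1.0:
            lam[-1] *= spec.fold
        counts = rng.poisson(lam)
        total = int(counts.sum())
        ev_idx = rng.integers(0, len(ev), size=total)
        starts = ev.start.to_numpy()[ev_idx]
        ev_len = (ev.end.to_numpy() - ev.start.to_numpy())[ev_idx]
        pos = starts + rng.integers(0, np.maximum(ev_len - length, 1))
        chroms = ev.chrom.to_numpy()[ev_idx]
        strands = np.where(rng.random(total) < 0.5, "+", "-")
        scores = rng.uniform(-12.0, 0.0, size=total)
        words = np.repeat(all_words, counts)
        df = pd.DataFrame(
            {"chrom": chroms, "pos": pos, "strand": strands, "word": words, "score": scores}
        ).sort_values(["chrom", "pos", "word"], kind="mergesort").reset_index(drop=True)
        out[sp] = df
    return out


# ------------------------------------------------------------------ bundles

@dataclass
class SyntheticWorld:
    """A fully generated world plus its ground truth."""

    config: WorldConfig
    amap: AlignmentMap
    events: dict[str, dict[str, BindingEventSet]]
    truth: pd.DataFrame
    repeats: dict[str, list[RepeatElement]]
    repeat_truth: pd.DataFrame
    word_hits: dict[str, pd.DataFrame]


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the alignment map, binding events, repeats and word hits."""
    amap = generate_alignment_map(config)
    events, truth = generate_binding_events(config, amap)
    repeats, repeat_truth = generate_repeat_annotation(
        config, events, species=[config.anchor.name] if config.repeat_spec else []
    )
    word_hits = generate_word_hits(config, events) if config.word_spec else {}
    return SyntheticWorld(config, amap, events, truth, repeats, repeat_truth, word_hits)


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write the world's flat files (BED6+2, block table, RepeatMasker TSV, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_block_table(world.amap, outdir / "blocks.tsv")
    for sp, by_factor in sorted(world.events.items()):
        for factor, evset in sorted(by_factor.items()):
            write_binding_bed(evset, outdir / f"{sp}_{factor}.bed")
    for sp, reps in sorted(world.repeats.items()):
        write_repeatmasker(reps, outdir / f"{sp}_rmsk.tsv")
    for sp, hits in sorted(world.word_hits.items()):
        hits.to_csv(outdir / f"{sp}_word_hits.tsv", sep="\t", index=False,
                    float_format="%.10g")
    world.truth.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    if len(world.repeat_truth):
        world.repeat_truth.to_csv(outdir / "truth_repeats.tsv", sep="\t", index=False,
                                  float_format="%.10g")
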