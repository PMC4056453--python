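"""Cross-species projection of binding events and conservation classification.

Binding events of an anchor species are projected onto every other study
species through a map of orthology blocks (a simplified stand-in for
whole-genome EPO multiple alignments).  An anchor event that projects onto a
peak in another species is *shared* with that species; the number of sharing
species (the event's own species included) maps onto six conservation
classes:

========================  ==========================================
label                     sharing species (K species in the study)
========================  ==========================================
UNALIGNED                 1, and no block coverage toward any other species
SPECIES_SPECIFIC          1, but covered by the alignment
TWO_WAY                   exactly 2
THREE_TO_FIVE             3 .. K-2
SIX_WAY                   K-1
ALL                       K
========================  ==========================================

Pairwise shared fractions are averaged over the two anchoring directions,
because anchoring is not symmetric at the event level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BindingEventSet, GenomicInterval

CLASS_LABELS = [
    "UNALIGNED",
    "SPECIES_SPECIFIC",
    "TWO_WAY",
    "THREE_TO_FIVE",
    "SIX_WAY",
    "ALL",
]


@dataclass(frozen=True)
class Segment:
    """One species' piece of an alignment block."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentBlock:
    """An orthology block: equal-role segments for a subset of species."""

    block_id: str
    segments: dict[str, Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"block {self.block_id} has no segments")


class AlignmentMap:
    """A collection of alignment blocks with a per-species interval index.

    Within one species, segments of different blocks must not overlap; this
    makes binary search over sorted segment starts exact.
    """

    def __init__(self, blocks: Sequence[AlignmentBlock]):
        self.blocks = list(blocks)
        self._index: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
        per_sp: dict[str, dict[str, list[tuple[int, int, int]]]] = {}
        for bi, block in enumerate(self.blocks):
            for sp, seg in block.segments.items():
                per_sp.setdefault(sp, {}).setdefault(seg.chrom, []).append(
                    (seg.start, seg.end, bi)
                )
        for sp, chroms in per_sp.items():
            self._index[sp] = {}
            for chrom, triples in chroms.items():
                triples.sort()
                starts = np.array([t[0] for t in triples], dtype=np.int64)
                ends = np.array([t[1] for t in triples], dtype=np.int64)
                bidx = np.array([t[2] for t in triples], dtype=np.int64)
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"overlapping segments for {sp}:{chrom}")
                self._index[sp][chrom] = (starts, ends, bidx)

    @property
    def species(self) -> list[str]:
        return sorted(self._index)

    def __len__(self) -> int:
        return len(self.blocks)

    def blocks_overlapping(self, species: str, iv: GenomicInterval) -> list[int]:
        """Indices of blocks whose ``species`` segment overlaps ``iv`` by >= 1 bp."""
        if species not in self._index:
            raise KeyError(f"unknown species {species!r}")
        chroms = self._index[species]
        if iv.chrom not in chroms:
            return []
        starts, ends, bidx = chroms[iv.chrom]
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        return bidx[lo:hi].tolist()


def project_interval(
    iv: GenomicInterval, amap: AlignmentMap, from_sp: str, to_sp: str
) -> list[GenomicInterval]:
    """Project an interval from one species onto another via alignment blocks.

    Each block overlapping ``iv`` in ``from_sp`` that also carries a
    ``to_sp`` segment contributes the offset-mapped overlapped sub-interval.
    Unequal segment lengths are mapped proportionally; segments on opposite
    strands reverse coordinates.  Returns an empty list when no block maps.
    """
    out: list[GenomicInterval] = []
    for bi in amap.blocks_overlapping(from_sp, iv):
        block = amap.blocks[bi]
        if to_sp not in block.segments:
            continue
        sf = block.segments[from_sp]
        st = block.segments[to_sp]
        clip_s = max(iv.start, sf.start)
        clip_e = min(iv.end, sf.end)
        if clip_e <= clip_s:
            continue
        off_s = clip_s - sf.start
        off_e = clip_e - sf.start
        lf, lt = sf.length, st.length
        if lf != lt:
            # proportional scaling: floor the start offset, ceil the end offset
            off_s2 = (off_s * lt) // lf
            off_e2 = -((-off_e * lt) // lf)
        else:
            off_s2, off_e2 = off_s, off_e
        off_e2 = min(max(off_e2, off_s2 + 1), lt)
        off_s2 = min(off_s2, off_e2 - 1)
        flip = (sf.strand == "-") != (st.strand == "-")
        if flip:
            t_start = st.start + (lt - off_e2)
            t_end = st.start + (lt - off_s2)
        else:
            t_start = st.start + off_s2
            t_end = st.start + off_e2
        out.append(GenomicInterval(st.chrom, int(t_start), int(t_end)))
    out.sort(key=lambda g: (g.chrom, g.start, g.end))
    return out


# ------------------------------------------------------------ classification

@dataclass
class ConservationClassification:
    """Per-event conservation labels for one anchor species' event set."""

    anchor: str
    n_species: int
    labels: list[str]
    sharing: list[frozenset[str]]

    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in CLASS_LABELS}
        for lab in self.labels:
            counts[lab] += 1
        return counts

    def class_fractions(self) -> dict[str, float]:
        n = len(self.labels)
        if n == 0:
            return {lab: 0.0 for lab in CLASS_LABELS}
        counts = self.class_counts()
        return {lab: counts[lab] / n for lab in CLASS_LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "n_sharing": [len(s) for s in self.sharing],
                "sharing_species": [",".join(sorted(s)) for s in self.sharing],
            }
        )


def label_for_count(n_sharing: int, n_species: int, aligned: bool) -> str:
    """Map a sharing count (own species included) onto the six class labels."""
    if n_sharing == 1:
        return "SPECIES_SPECIFIC" if aligned else "UNALIGNED"
    if n_sharing == n_species:
        return "ALL"
    if n_sharing == 2:
        return "TWO_WAY"
    if n_sharing == n_species - 1:
        return "SIX_WAY"
    return "THREE_TO_FIVE"


def classify_conservation(
    sets: Mapping[str, BindingEventSet], amap: AlignmentMap, anchor: str
) -> ConservationClassification:
    """Classify each anchor event into the six conservation classes.

    An anchor event is shared with another species when any projected piece
    overlaps (>= 1 bp) a binding event of that species.  Events with no block
    coverage toward any other species are UNALIGNED.
    """
    if not sets:
        raise ValueError("empty species map")
    if anchor not in sets:
        raise KeyError(f"anchor species {anchor!r} not in event sets")
    others = [sp for sp in sets if sp != anchor]
    n_species = len(sets)
    anchor_set = sets[anchor]
    labels: list[str] = []
    sharing: list[frozenset[str]] = []
    for iv in anchor_set.intervals():
        shared = {anchor}
        aligned = False
        for sp in others:
            pieces = project_interval(iv, amap, anchor, sp)
            if not pieces:
                continue
            aligned = True
            target = sets[sp]
            hit = target.any_overlap(
                [p.chrom for p in pieces],
                [p.start for p in pieces],
                [p.end for p in pieces],
            )
            if hit.any():
                shared.add(sp)
        labels.append(label_for_count(len(shared), n_species, aligned))
        sharing.append(frozenset(shared))
    return ConservationClassification(anchor, n_species, labels, sharing)


def _directional_shared_fraction(
    a: BindingEventSet, b: BindingEventSet, amap: AlignmentMap
) -> float:
    shared = 0
    for iv in a.intervals():
        pieces = project_interval(iv, amap, a.species, b.species)
        if not pieces:
            continue
        hit = b.any_overlap(
            [p.chrom for p in pieces], [p.start for p in pieces], [p.end for p in pieces]
        )
        if hit.any():
            shared += 1
    return shared / len(a)


def pairwise_shared_fraction(
    a: BindingEventSet, b: BindingEventSet, amap: AlignmentMap
) -> float:
    """Shared fraction between two species, averaged over anchoring direction."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("pairwise_shared_fraction requires non-empty event sets")
    return 0.5 * (
        _directional_shared_fraction(a, b, amap)
        + _directional_shared_fraction(b, a, amap)
    )


def overlap_divergence_correlation(
    fractions: Mapping[str, float], divergence_my: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation of shared fractions against divergence times."""
    species = [sp for sp in fractions if sp in divergence_my]
    if len(species) < 3:
        raise ValueError("need >= 3 species with both a fraction and a divergence time")
    x = np.array([divergence_my[sp] for sp in species], dtype=float)
    y = np.array([fractions[sp] for sp in species], dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fdr_sensitivity_overlap(
    anchor_set: BindingEventSet,
    other: BindingEventSet,
    amap: AlignmentMap,
    fdr_grid: Sequence[float],
) -> dict[float, float]:
    """Anchor-direction shared fraction as the other species' FDR cutoff relaxes."""
    grid = list(fdr_grid)
    if grid != sorted(grid):
        raise ValueError("fdr_grid must be sorted ascending")
    out: dict[float, float] = {}
    for g in grid:
        if g > 0.5:
            warnings.warn(f"FDR grid value {g} exceeds 0.5", stacklevel=2)
        filtered = other.filter_fdr(g)
        if len(filtered) == 0:
            out[g] = 0.0
        else:
            out[g] = _directional_shared_fraction(anchor_set, filtered, amap)
    return out


# -------------------------------------------------------------------- I/O

_BLOCK_COLS = ["block_id", "species", "chrom", "start", "end", "strand"]


def write_block_table(amap: AlignmentMap, path: str | Path) -> None:
    """One row per (block, species) segment, tab-separated."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_BLOCK_COLS) + "\n")
        for block in amap.blocks:
            for sp in sorted(block.segments):
                seg = block.segments[sp]
                fh.write(
                    f"{block.block_id}\t{sp}\t{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.strand}\n"
                )


def read_block_table(path: str | Path) -> AlignmentMap:
    df = pd.read_csv(path, sep="\t", dtype={"block_id": str})
    missing = [c for c in _BLOCK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"block table missing columns {missing}")
    blocks = []
    for bid, sub in df.groupby("block_id", sort=False):
        segs = {
            row.species: Segment(row.chrom, int(row.start), int(row.end), row.strand)
            for row in sub.itertuples(index=False)
        }
        blocks.append(AlignmentBlock(str(bid), segs))
    return AlignmentMap(blocks)


def read_maf(path: str | Path) -> AlignmentMap:
    """Read MAF alignment blocks as orthology blocks (gap columns collapsed).

    Sequence names must follow the ``species.chrom`` convention.  Blocks keep
    per-species ungapped spans; minus-strand MAF coordinates are converted to
    forward-strand coordinates.  Gap collapsing leaves segments of unequal
    length, which projection handles proportionally.
    """
    from Bio import AlignIO

    blocks = []
    for bi, aln in enumerate(AlignIO.parse(str(path), "maf")):
        segs = {}
        for rec in aln:
            if "." not in rec.id:
                raise ValueError(f"MAF sequence id {rec.id!r} is not species.chrom")
            sp, chrom = rec.id.split(".", 1)
            start = int(rec.annotations["start"])
            size = int(rec.annotations["size"])
            strand = "+" if rec.annotations["strand"] in (1, "+") else "-"
            if strand == "-":
                src = int(rec.annotations["srcSize"])
                start = src - start - size
            segs[sp] = Segment(chrom, start, start + size, strand)
        if segs:
            blocks.append(AlignmentBlock(f"maf_{bi}", segs))
    return AlignmentMap(blocks)
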