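"""Genomic-interval data model, overlap engine, and flat-file readers/writers.

All coordinates are 0-based half-open ``[start, end)`` (the BED convention).
RepeatMasker ``genoStart`` is likewise interpreted as 0-based, matching the
UCSC table convention.  Overlap is strand-blind everywhere: two intervals
overlap when they share at least ``min_bp`` bases on the same chromosome.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

EVENT_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "fdr", "summit"]


class ParseError(ValueError):
    """Raised when a flat file violates the documented dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the intervals share >= ``min_bp`` bases.  Strand is ignored."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


@dataclass(frozen=True)
class BindingEvent:
    """One scored ChIP binding event with its enrichment summit.

    ``summit`` is an absolute genomic position inside the interval, ``score``
    a non-negative enrichment score (CCAT-style, proportional to ChIP
    enrichment), ``fdr`` the per-event false-discovery estimate.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    fdr: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside event "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0, 1], got {self.fdr}")
        if self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")


class BindingEventSet:
    """One species x one factor collection of binding events.

    Events are stored columnar (a pandas DataFrame with the BED6+2 columns)
    and kept sorted by (chrom, start) with exact (chrom, start, end)
    duplicates collapsed.
    """

    def __init__(self, species: str, factor: str, df: pd.DataFrame | None = None):
        self.species = species
        self.factor = factor
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event frame missing columns: {missing}")
        df = df.loc[:, EVENT_COLUMNS].copy()
        if len(df):
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
            df = df.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
            df = df.reset_index(drop=True)
            for col, typ in (("start", np.int64), ("end", np.int64), ("summit", np.int64)):
                df[col] = df[col].astype(typ)
            df["score"] = df["score"].astype(float)
            df["fdr"] = df["fdr"].astype(float)
            bad = df.index[~(df["start"] < df["end"])]
            if len(bad):
                raise ValueError(f"event {bad[0]} has start >= end")
            bad = df.index[~((df["start"] <= df["summit"]) & (df["summit"] < df["end"]))]
            if len(bad):
                raise ValueError(f"event {bad[0]} has summit outside its interval")
        self.df = df
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    # ------------------------------------------------------------------ build
    @classmethod
    def from_events(cls, species: str, factor: str, events: Iterable[BindingEvent]) -> "BindingEventSet":
        rows = [
            (
                e.interval.chrom,
                e.interval.start,
                e.interval.end,
                e.name,
                e.score,
                e.interval.strand,
                e.fdr,
                e.summit,
            )
            for e in events
        ]
        df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        return cls(species, factor, df)

    @classmethod
    def from_arrays(
        cls,
        species: str,
        factor: str,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        summit: Sequence[int] | None = None,
        score: Sequence[float] | None = None,
        fdr: Sequence[float] | None = None,
        strand: Sequence[str] | None = None,
        name: Sequence[str] | None = None,
    ) -> "BindingEventSet":
        n = len(chrom)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        df = pd.DataFrame(
            {
                "chrom": list(chrom),
                "start": start,
                "end": end,
                "name": list(name) if name is not None else ["."] * n,
                "score": np.asarray(score, dtype=float) if score is not None else np.zeros(n),
                "strand": list(strand) if strand is not None else ["."] * n,
                "fdr": np.asarray(fdr, dtype=float) if fdr is not None else np.zeros(n),
                "summit": np.asarray(summit, dtype=np.int64)
                if summit is not None
                else (start + end) // 2,
            }
        )
        return cls(species, factor, df)

    # ----------------------------------------------------------------- access
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[BindingEvent]:
        for row in self.df.itertuples(index=False):
            yield BindingEvent(
                GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                int(row.summit),
                float(row.score),
                float(row.fdr),
                str(row.name),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BindingEventSet):
            return NotImplemented
        return (
            self.species == other.species
            and self.factor == other.factor
            and self.df.equals(other.df)
        )

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e), st)
            for c, s, e, st in zip(self.df.chrom, self.df.start, self.df.end, self.df.strand)
        ]

    def filter_fdr(self, max_fdr: float) -> "BindingEventSet":
        """Events with fdr <= ``max_fdr`` (the paper-style FDR relaxation filter)."""
        return BindingEventSet(self.species, self.factor, self.df[self.df.fdr <= max_fdr])

    def total_bases(self, merged: bool = True) -> int:
        """Total bound bases; overlapping events are merged by default."""
        if not len(self.df):
            return 0
        if not merged:
            return int((self.df.end - self.df.start).sum())
        total = 0
        for _, sub in self.df.groupby("chrom", sort=False):
            s = sub.start.to_numpy()
            e = sub.end.to_numpy()
            total += int(merged_length(s, e))
        return total

    # ---------------------------------------------------------------- overlap
    def _chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        if self._index is None:
            idx = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                starts = sub.start.to_numpy()
                ends = sub.end.to_numpy()
                idx[chrom] = (starts, np.maximum.accumulate(ends), ends)
            self._index = idx
        return self._index

    def any_overlap(
        self,
        chrom: Sequence[str] | str,
        start: Sequence[int],
        end: Sequence[int],
        min_bp: int = 1,
    ) -> np.ndarray:
        """Boolean array: does each query interval overlap >= min_bp with any event.

        Exact for ``min_bp == 1``; for larger ``min_bp`` events shorter than
        ``min_bp`` are excluded first so the prefix-max test stays exact.
        """
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if isinstance(chrom, str):
            chrom = [chrom] * len(start)
        out = np.zeros(len(start), dtype=bool)
        index = self._chrom_index()
        chrom_arr = np.asarray(chrom, dtype=object)
        for c in pd.unique(chrom_arr):
            if c not in index:
                continue
            starts, prefmax_end, ends = index[c]
            if min_bp > 1:
                keep = (ends - starts) >= min_bp
                if not keep.all():
                    s2, e2 = starts[keep], ends[keep]
                    order = np.argsort(s2, kind="mergesort")
                    starts = s2[order]
                    prefmax_end = np.maximum.accumulate(e2[order])
            mask = chrom_arr == c
            qs, qe = start[mask], end[mask]
            j = np.searchsorted(starts, qe - min_bp, side="right")
            hit = (j > 0) & ((qe - qs) >= min_bp)
            hit[hit] = prefmax_end[j[hit] - 1] >= qs[hit] + min_bp
            out[mask] = hit
        return out

    def overlapping_indices(self, iv: GenomicInterval) -> np.ndarray:
        """Row indices (into ``self.df``) of all events overlapping ``iv`` by >= 1 bp."""
        sub = self.df[self.df.chrom == iv.chrom]
        if not len(sub):
            return np.array([], dtype=np.int64)
        s = sub.start.to_numpy()
        e = sub.end.to_numpy()
        hit = (s < iv.end) & (e > iv.start)
        return sub.index.to_numpy()[hit]


def merged_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bases covered by the union of intervals on one chromosome."""
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    total = 0
    cur_s, cur_e = None, None
    for a, b in zip(s.tolist(), e.tolist()):
        if cur_e is None or a > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = a, b
        else:
            cur_e = max(cur_e, b)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals on one chromosome as sorted non-overlapping arrays."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="mergesort")
    s = np.asarray(starts)[order]
    e = np.asarray(ends)[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for a, b in zip(s[1:].tolist(), e[1:].tolist()):
        if a > out_e[-1]:
            out_s.append(a)
            out_e.append(b)
        else:
            out_e[-1] = max(out_e[-1], b)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


@dataclass(frozen=True)
class RepeatElement:
    """A RepeatMasker-style repeat copy with its milliDiv divergence."""

    interval: GenomicInterval
    rep_name: str
    rep_class: str = "."
    rep_family: str = "."
    milli_div: int = 0

    def __post_init__(self) -> None:
        if self.milli_div < 0:
            raise ValueError(f"milliDiv must be >= 0, got {self.milli_div}")


@dataclass(frozen=True)
class FeatureAnnotation:
    """A generic annotated genomic feature (CpG island, transcript, TSS, ...)."""

    kind: str
    interval: GenomicInterval
    id: str = "."


# --------------------------------------------------------------------- I/O

def read_binding_bed(path: str | Path, species: str, factor: str) -> BindingEventSet:
    """Read the BED6+2 binding-event dialect.

    Columns: chrom, start, end, name, score, strand, fdr, summit offset from
    start.  Missing optional columns default to fdr=0 and summit=midpoint.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not chrom or start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                fdr = float(fields[6]) if len(fields) > 6 else 0.0
                summit = start + int(fields[7]) if len(fields) > 7 else (start + end) // 2
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if not (start <= summit < end):
                raise ParseError(f"{path}:{lineno}: summit {summit} outside interval")
            if not (0.0 <= fdr <= 1.0):
                raise ParseError(f"{path}:{lineno}: fdr {fdr} outside [0, 1]")
            rows.append((chrom, start, end, name, score, strand, fdr, summit))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return BindingEventSet(species, factor, df)


def write_binding_bed(events: BindingEventSet, path: str | Path) -> None:
    """Write the BED6+2 dialect (summit stored as offset from start)."""
    with open(path, "w", newline="\n") as fh:
        for row in events.df.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        str(int(row.start)),
                        str(int(row.end)),
                        str(row.name),
                        format(float(row.score), ".10g"),
                        row.strand,
                        format(float(row.fdr), ".10g"),
                        str(int(row.summit) - int(row.start)),
                    ]
                )
                + "\n"
            )


_RMSK_COLS = [
    "genoName",
    "genoStart",
    "genoEnd",
    "strand",
    "repName",
    "repClass",
    "repFamily",
    "milliDiv",
]


def read_repeatmasker(path: str | Path) -> list[RepeatElement]:
    """Read a RepeatMasker-style TSV (header row optional)."""
    out: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "genoName":
                continue
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                milli = int(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if milli < 0:
                raise ParseError(f"{path}:{lineno}: negative milliDiv {milli}")
            strand = fields[3] if fields[3] in STRANDS else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(RepeatElement(iv, fields[4], fields[5], fields[6], milli))
    return out


def write_repeatmasker(repeats: Sequence[RepeatElement], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_RMSK_COLS) + "\n")
        for r in repeats:
            fh.write(
                "\t".join(
                    [
                        r.interval.chrom,
                        str(r.interval.start),
                        str(r.interval.end),
                        r.interval.strand,
                        r.rep_name,
                        r.rep_class,
                        r.rep_family,
                        str(r.milli_div),
                    ]
                )
                + "\n"
            )


def read_features_bed(path: str | Path, kind: str) -> list[FeatureAnnotation]:
    """Read plain BED (>= 3 columns) as FeatureAnnotation records of one kind."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            fid = f[3] if len(f) > 3 else f"{kind}_{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in STRANDS else "."
            out.append(
                FeatureAnnotation(kind, GenomicInterval(f[0], int(f[1]), int(f[2]), strand), fid)
            )
    return out


def write_features_bed(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for f in features:
            fh.write(
                f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}\t{f.id}\t0\t{f.interval.strand}\n"
            )


# --------------------------------------------------------- replicate merging

def merge_replicate_peaks(
    replicates: Sequence[BindingEventSet], unique_fdr_cutoff: float = 0.05
) -> BindingEventSet:
    """Merge replicate peak sets: intersection plus confident replicate-unique peaks.

    The merged set contains every first-replicate event that overlaps (>= 1 bp)
    an event in *every* replicate, plus events found in exactly one replicate
    whose per-event FDR is below ``unique_fdr_cutoff``.  Coordinates of
    intersection events are taken from the first replicate.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    species = {r.species for r in replicates}
    factor = {r.factor for r in replicates}
    if len(species) > 1 or len(factor) > 1:
        raise ValueError(f"mixed species/factor in replicates: {species} x {factor}")
    if len(replicates) == 1:
        r = replicates[0]
        return BindingEventSet(r.species, r.factor, r.df)

    first = replicates[0]
    in_all = np.ones(len(first), dtype=bool)
    for other in replicates[1:]:
        in_all &= other.any_overlap(first.df.chrom, first.df.start, first.df.end)
    parts = [first.df[in_all]]

    for i, rep in enumerate(replicates):
        unique = np.ones(len(rep), dtype=bool)
        for j, other in enumerate(replicates):
            if i == j:
                continue
            unique &= ~other.any_overlap(rep.df.chrom, rep.df.start, rep.df.end)
        sub = rep.df[unique & (rep.df.fdr < unique_fdr_cutoff).to_numpy()]
        parts.append(sub)

    merged = pd.concat(parts, ignore_index=True)
    return BindingEventSet(first.species, first.factor, merged)
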