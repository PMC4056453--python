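"""Repeat-element association: randomization-calibrated binomial enrichment,
repeat age from milliDiv, and summit-centered profiles.

The background probability that a binding event overlaps a repeat family is
estimated empirically: events are re-placed uniformly at random on their own
chromosomes (lengths preserved) ``n_rand`` times, and the median overlap
fraction across randomizations is taken as the binomial background
probability.  Observed overlap counts are then tested against
``Binomial(n, p_bg)`` (upper tail) and Benjamini-Hochberg adjusted across
families within a species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BindingEventSet, RepeatElement, merge_intervals

# substitutions per bp per year
MUTATION_RATES = {"mammal": 2.2e-9, "rodent": 4.5e-9}


@dataclass(frozen=True)
class RepeatAge:
    """Age of a repeat copy inferred from its milliDiv divergence."""

    milli_div: int
    mutation_rate: float
    age_years: float


def repeat_age(milli_div: int, lineage: str = "mammal") -> RepeatAge:
    """Age in years: (milliDiv / 1000) substitutions per bp / mutation rate."""
    if milli_div < 0:
        raise ValueError("milliDiv must be >= 0")
    if lineage not in MUTATION_RATES:
        raise ValueError(f"lineage must be one of {sorted(MUTATION_RATES)}")
    rate = MUTATION_RATES[lineage]
    return RepeatAge(milli_div, rate, (milli_div / 1000.0) / rate)


# ------------------------------------------------------------ randomization

def randomize_events(
    events: BindingEventSet,
    genome: Mapping[str, int],
    seed: int | np.random.Generator = 0,
) -> BindingEventSet:
    """Uniformly re-place each event on its own chromosome, length preserved."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = events.df
    lengths = (df.end - df.start).to_numpy()
    chrom_len = np.array([genome[c] for c in df.chrom], dtype=np.int64)
    if np.any(lengths > chrom_len):
        bad = int(np.argmax(lengths > chrom_len))
        raise ValueError(
            f"event {bad} (length {lengths[bad]}) longer than its chromosome"
        )
    new_start = rng.integers(0, chrom_len - lengths + 1)
    new_end = new_start + lengths
    offset = new_start + (df.summit - df.start).to_numpy()
    return BindingEventSet.from_arrays(
        events.species, events.factor, list(df.chrom), new_start, new_end,
        summit=offset, score=df.score.to_numpy(), fdr=df.fdr.to_numpy(),
        name=list(df.name), strand=list(df.strand),
    )


def _family_index(
    repeats: Sequence[RepeatElement],
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per family, per chromosome, merged (non-overlapping, sorted) intervals."""
    grouped: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in repeats:
        grouped.setdefault(r.rep_name, {}).setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end)
        )
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for name, chroms in grouped.items():
        out[name] = {}
        for chrom, pairs in chroms.items():
            s = np.array([p[0] for p in pairs], dtype=np.int64)
            e = np.array([p[1] for p in pairs], dtype=np.int64)
            out[name][chrom] = merge_intervals(s, e)
    return out


def _count_overlapping_events(
    chrom: np.ndarray, start: np.ndarray, end: np.ndarray,
    fam: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """Number of events overlapping (>= 1 bp) any merged family interval."""
    total = 0
    for c in np.unique(chrom):
        if c not in fam:
            continue
        fs, fe = fam[c]
        mask = chrom == c
        qs, qe = start[mask], end[mask]
        j = np.searchsorted(fs, qe, side="left")
        hit = (j > 0) & (fe[np.maximum(j - 1, 0)] > qs)
        total += int(hit.sum())
    return total


def repeat_enrichment_test(
    events: BindingEventSet,
    repeats: Sequence[RepeatElement],
    genome: Mapping[str, int],
    n_rand: int = 100,
    seed: int = 0,
    adjust: bool = True,
) -> pd.DataFrame:
    """Binomial enrichment of binding events in each repeat family.

    Returns one row per repeat name: observed overlapping events ``k``,
    total events ``n``, randomization-median background ``p_bg`` (floored at
    ``1/(n*n_rand + 1)`` so it is never 0), the upper-tail binomial
    ``p_value``, BH-adjusted ``p_adj`` and ``neg_log_p`` (base 10), sorted
    by p_value.
    """
    if n_rand < 10:
        raise ValueError("n_rand must be >= 10")
    fams = _family_index(repeats)
    if not fams:
        return pd.DataFrame(
            columns=["rep_name", "species", "k", "n", "p_bg", "p_value", "p_adj", "neg_log_p"]
        )
    df = events.df
    n = len(df)
    chrom = df.chrom.to_numpy()
    start = df.start.to_numpy()
    end = df.end.to_numpy()
    lengths = end - start
    chrom_len = np.array([genome[c] for c in chrom], dtype=np.int64)
    if np.any(lengths > chrom_len):
        raise ValueError("an event is longer than its chromosome")
    names = sorted(fams)
    observed = {name: _count_overlapping_events(chrom, start, end, fams[name]) for name in names}
    rng = np.random.default_rng(seed)
    rand_counts = {name: np.empty(n_rand, dtype=np.int64) for name in names}
    for r in range(n_rand):
        rs = rng.integers(0, chrom_len - lengths + 1)
        re_ = rs + lengths
        for name in names:
            rand_counts[name][r] = _count_overlapping_events(chrom, rs, re_, fams[name])
    floor = 1.0 / (n * n_rand + 1.0)
    rows = []
    for name in names:
        p_bg = max(float(np.median(rand_counts[name])) / n, floor)
        p_bg = min(p_bg, 1.0 - floor)
        k = observed[name]
        p_value = float(stats.binom.sf(k - 1, n, p_bg)) if k > 0 else 1.0
        rows.append((name, events.species, k, n, p_bg, p_value))
    out = pd.DataFrame(
        rows, columns=["rep_name", "species", "k", "n", "p_bg", "p_value"]
    )
    if adjust:
        out["p_adj"] = multipletests(out.p_value.to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = out["p_value"]
    with np.errstate(divide="ignore"):
        out["neg_log_p"] = -np.log10(np.maximum(out.p_value.to_numpy(), 5e-324))
    out = out.sort_values(["p_value", "rep_name"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------- summit profiles

@dataclass
class SummitProfile:
    """Per-event values in fixed windows centered on peak summits.

    ``matrix`` is events x n_windows; ``truncated`` flags events whose
    window grid ran off the chromosome (out-of-genome windows are
    zero-filled).
    """

    matrix: np.ndarray
    mode: str
    window_bp: int = 50
    truncated: np.ndarray | None = None

    def column_means(self) -> np.ndarray:
        if self.matrix.size == 0:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.mean(axis=0)


def summit_repeat_profile(
    events: BindingEventSet,
    track: Sequence[RepeatElement] | Mapping[str, np.ndarray],
    mode: str = "repeat_coverage",
    n_windows: int = 200,
    window_bp: int = 50,
    chrom_lengths: Mapping[str, int] | None = None,
) -> SummitProfile:
    """Windowed profile around each summit (default 200 x 50 bp = 10 kb).

    ``repeat_coverage`` mode gives the fraction of each window's bases
    covered by track elements; ``read_count`` mode sums a per-bp count array
    per window.
    """
    if mode not in ("repeat_coverage", "read_count"):
        raise ValueError("mode must be 'repeat_coverage' or 'read_count'")
    df = events.df
    n = len(df)
    half = n_windows * window_bp // 2
    matrix = np.zeros((n, n_windows))
    truncated = np.zeros(n, dtype=bool)

    if mode == "repeat_coverage":
        cov: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, pairs in _coverage_by_chrom(track).items():
            s, e = pairs
            cum = np.concatenate([[0], np.cumsum(e - s)])
            cov[chrom] = (s, e, cum)

        def window_values(chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
            if chrom not in cov:
                return np.zeros(len(a))
            s, e, cum = cov[chrom]

            def F(x: np.ndarray) -> np.ndarray:
                j = np.searchsorted(s, x, side="right")
                base = cum[j]
                partial = np.where(j > 0, np.clip(e[np.maximum(j - 1, 0)] - x, 0, None), 0)
                return base - partial

            return (F(b) - F(a)) / window_bp
    else:
        tracks = dict(track)  # chrom -> per-bp counts

        def window_values(chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
            if chrom not in tracks:
                return np.zeros(len(a))
            arr = tracks[chrom]
            cum = np.concatenate([[0], np.cumsum(arr)])
            a = np.clip(a, 0, len(arr))
            b = np.clip(b, 0, len(arr))
            return (cum[b] - cum[a]).astype(float)

    for i, (chrom, summit) in enumerate(zip(df.chrom, df.summit)):
        lo = int(summit) - half
        edges = lo + np.arange(n_windows + 1) * window_bp
        a, b = edges[:-1].copy(), edges[1:].copy()
        limit = chrom_lengths.get(chrom) if chrom_lengths else None
        if a[0] < 0 or (limit is not None and b[-1] > limit):
            truncated[i] = True
        a = np.clip(a, 0, None)
        b = np.maximum(np.clip(b, 0, None), a)
        if limit is not None:
            b = np.minimum(b, limit)
            a = np.minimum(a, b)
        matrix[i] = window_values(chrom, a, b)
    return SummitProfile(matrix, mode, window_bp, truncated)


def _coverage_by_chrom(
    track: Sequence[RepeatElement],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    grouped: dict[str, list[tuple[int, int]]] = {}
    for r in track:
        grouped.setdefault(r.interval.chrom, []).append((r.interval.start, r.interval.end))
    out = {}
    for chrom, pairs in grouped.items():
        s = np.array([p[0] for p in pairs], dtype=np.int64)
        e = np.array([p[1] for p in pairs], dtype=np.int64)
        out[chrom] = merge_intervals(s, e)
    return out
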