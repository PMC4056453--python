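"""PWM scanning and motif-word statistics (nocc, normWord).

A PWM match is recorded as the exact L-mer it covers (the *motif word*),
read in PWM orientation.  Per species, word counts inside bound regions are
normalized by the total number of bound bases per million:

    nocc[i, j] = count[i, j] / factor[j],   factor[j] = bound bases / 1e6

A word's specificity for a focal species (or clade) S against a comparison
set R is the pseudocounted log ratio

    normWord = log2( (nocc(S) + 1) / (max_{r in R} nocc(r) + 1) )

Species-specific words are selected by fitting a normal distribution to all
normWord values and Benjamini-Hochberg-controlling the upper tail at a
chosen FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BindingEventSet, RepeatElement, merge_intervals

_ALPHABET = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities.

    ``probs`` is an (L, 4) array over A, C, G, T; rows must sum to 1.
    Scores are log2 ratios against the consensus base, so the consensus
    word scores exactly 0 and every other word scores <= 0.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be an (L, 4) matrix over A,C,G,T")
        if np.any(self.probs < 0):
            raise ValueError("PWM probabilities must be >= 0")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        cons_p = self.probs[np.arange(len(self.probs)), self.probs.argmax(axis=1)]
        if np.any(cons_p == 0):
            raise ValueError("PWM has zero probability at a consensus base")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    def score_matrix(self) -> np.ndarray:
        """(L, 5) log2(p/p_consensus) lookup; column 4 (N) is -inf."""
        cons = self.probs.max(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            lut = np.log2(self.probs / cons)
        return np.hstack([lut, np.full((self.length, 1), -np.inf)])

    @classmethod
    def from_file(cls, path: str | Path) -> "PWM":
        """Tab-separated position x base matrix with header ``A C G T``."""
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c.upper() in _ALPHABET]
        if len(cols) != 4:
            raise ValueError(f"PWM file must have columns A, C, G, T; got {list(df.columns)}")
        ordered = sorted(cols, key=lambda c: _ALPHABET.index(c.upper()))
        return cls(df[ordered].to_numpy())

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(self.probs, columns=list(_ALPHABET)).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_pwm(
    sequence: str, pwm: PWM, cutoff: float = -15.0, chrom: str = "."
) -> pd.DataFrame:
    """Scan both strands; hits with score >= cutoff, sorted by position.

    Windows containing any non-ACGT base are skipped.  Minus-strand hits
    report the reverse complement of the genomic window (the word in PWM
    orientation) at the window's forward-strand position.
    """
    L = pwm.length
    n = len(sequence) - L + 1
    cols = ["chrom", "pos", "strand", "word", "score"]
    if n <= 0:
        return pd.DataFrame(columns=cols)
    code = _encode(sequence)
    lut = pwm.score_matrix()
    # minus strand: score of revcomp(window) = sum_i lut[L-1-i, comp(code[p+i])]
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    lut_rc = lut[::-1][:, [3, 2, 1, 0, 4]]
    plus = np.zeros(n)
    minus = np.zeros(n)
    for i in range(L):
        plus += lut[i, code[i : i + n]]
        minus += lut_rc[i, code[i : i + n]]
    rows = []
    for strand, scores in (("+", plus), ("-", minus)):
        idx = np.where(scores >= cutoff)[0]
        for p in idx.tolist():
            word = sequence[p : p + L].upper()
            if strand == "-":
                word = reverse_complement(word)
            rows.append((chrom, p, strand, word, float(scores[p])))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


# ------------------------------------------------------------- word tables

@dataclass
class MotifWordTable:
    """Per-word, per-species raw counts and normalized occurrences."""

    counts: pd.DataFrame  # index word, columns species
    factors: pd.Series  # bound Mb per species

    @property
    def nocc(self) -> pd.DataFrame:
        return self.counts / self.factors

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)


def _in_bound(hits: pd.DataFrame, bound: BindingEventSet) -> np.ndarray:
    if not len(hits):
        return np.zeros(0, dtype=bool)
    return bound.any_overlap(list(hits.chrom), hits.pos.to_numpy(), hits.pos.to_numpy() + 1)


def build_word_table(
    hits_by_species: Mapping[str, pd.DataFrame],
    bound_by_species: Mapping[str, BindingEventSet],
    min_count: int = 5,
) -> MotifWordTable:
    """Count bound motif words per species and normalize by bound megabases.

    A hit contributes when its position lies inside a bound region of its
    species.  Words whose maximum raw count across species is below
    ``min_count`` are dropped.
    """
    species = sorted(hits_by_species)
    factors = {}
    counts: dict[str, pd.Series] = {}
    for sp in species:
        bound = bound_by_species[sp]
        bases = bound.total_bases()
        if bases == 0:
            raise ValueError(f"{sp}: zero bound bases")
        factors[sp] = bases / 1e6
        hits = hits_by_species[sp]
        inside = _in_bound(hits, bound)
        counts[sp] = hits.loc[inside, "word"].value_counts()
    table = pd.DataFrame(counts).fillna(0).astype(int)
    table.columns = species
    table = table[table.max(axis=1) >= min_count]
    table = table.sort_index()
    table.index.name = "word"
    return MotifWordTable(table, pd.Series(factors))


def norm_word_scores(
    table: MotifWordTable,
    focal: str | Sequence[str],
    comparison: Sequence[str],
) -> pd.DataFrame:
    """normWord per word for a focal species (or clade) against a comparison set.

    For a clade, the clade-level nocc is the maximum over clade members,
    mirroring the max over the comparison set.  Returns a frame with
    columns ``word``, ``nocc_focal``, ``max_nocc_comparison``, ``normword``.
    """
    focal_list = [focal] if isinstance(focal, str) else list(focal)
    comparison = list(comparison)
    if not comparison:
        raise ValueError("comparison set must be non-empty")
    if set(focal_list) & set(comparison):
        raise ValueError("focal species must not appear in the comparison set")
    nocc = table.nocc
    missing = [s for s in focal_list + comparison if s not in nocc.columns]
    if missing:
        raise KeyError(f"species not in table: {missing}")
    ns = nocc[focal_list].max(axis=1)
    nr = nocc[comparison].max(axis=1)
    out = pd.DataFrame(
        {
            "word": nocc.index,
            "nocc_focal": ns.to_numpy(),
            "max_nocc_comparison": nr.to_numpy(),
            "normword": np.log2((ns.to_numpy() + 1.0) / (nr.to_numpy() + 1.0)),
        }
    )
    return out.reset_index(drop=True)


def select_specific_words(
    scores: pd.DataFrame, fdr: float = 0.05
) -> tuple[list[str], float]:
    """Select expanded words by a normal fit to normWord and BH at ``fdr``.

    Fits mean/SD to all normWord values, converts each to an upper-tail
    p-value, applies Benjamini-Hochberg, and returns the selected words with
    the implied normWord cutoff (the smallest selected normWord, or +inf
    when nothing is selected).
    """
    values = scores["normword"].to_numpy(dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 normWord scores to fit the null")
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("normWord scores have zero variance")
    p = stats.norm.sf((values - mu) / sd)
    reject = multipletests(p, alpha=fdr, method="fdr_bh")[0]
    selected = [str(w) for w in scores.loc[reject, "word"]]
    cutoff = float(values[reject].min()) if reject.any() else float("inf")
    return selected, cutoff


def count_repeat_embedded_words(
    selected: Sequence[str],
    hits: pd.DataFrame,
    bound: BindingEventSet,
    repeats: Sequence[RepeatElement],
    word_length: int | None = None,
) -> pd.DataFrame:
    """Per selected word, bound occurrences lying fully inside a repeat element.

    A hit counts when its position is inside a bound region and the whole
    L-mer ``[pos, pos+L)`` fits inside a single annotated repeat element.
    Returns columns ``word``, ``count``, ``log10_count`` (log10(count + 1)).
    """
    selected = list(selected)
    if not selected:
        return pd.DataFrame(columns=["word", "count", "log10_count"])
    if word_length is None:
        word_length = len(selected[0])
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.interval.chrom, []).append((r.interval.start, r.interval.end))
    # containment in a single element: index elements sorted by start with
    # prefix-max end; the L-mer [p, p+L) is inside some element iff an element
    # with start <= p has end >= p + L
    idx = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        s = np.array([p[0] for p in pairs], dtype=np.int64)
        e = np.array([p[1] for p in pairs], dtype=np.int64)
        idx[chrom] = (s, np.maximum.accumulate(e))
    sub = hits[hits.word.isin(selected)]
    if len(sub):
        inside_bound = _in_bound(sub, bound)
        sub = sub[inside_bound]
    counts = {w: 0 for w in selected}
    for row in sub.itertuples(index=False):
        if row.chrom not in idx:
            continue
        s, pme = idx[row.chrom]
        j = np.searchsorted(s, row.pos, side="right")
        if j > 0 and pme[j - 1] >= row.pos + word_length:
            counts[row.word] += 1
    out = pd.DataFrame(
        {"word": selected, "count": [counts[w] for w in selected]}
    )
    out["log10_count"] = np.log10(out["count"] + 1.0)
    return out
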