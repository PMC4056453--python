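"""CTCF/YY1 co-binding partition and its feature / expression associations.

A CTCF event is *co-bound* when it overlaps (>= 1 bp) any YY1 event, and
symmetrically; the partition into CTCF-only, CTCF-YY1 (event pairs) and
YY1-only classes is exhaustive and exclusive per factor.  Feature
associations are per-species overlap fractions compared across species with
a two-sided Mann-Whitney rank-sum test; transcript expression is compared
between classes the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BindingEventSet, FeatureAnnotation, GenomicInterval

logger = logging.getLogger(__name__)

COBIND_CLASSES = ["CTCF_ONLY", "CTCF_YY1", "YY1_ONLY"]


@dataclass
class CobindPartition:
    """Partition of one species' CTCF and YY1 events by mutual overlap."""

    species: str
    ctcf_only: BindingEventSet
    yy1_only: BindingEventSet
    ctcf_cobound: BindingEventSet
    yy1_cobound: BindingEventSet
    pairs: pd.DataFrame  # columns: ctcf_index, yy1_index (into the cobound frames)

    @property
    def n_ctcf(self) -> int:
        return len(self.ctcf_only) + len(self.ctcf_cobound)

    @property
    def n_yy1(self) -> int:
        return len(self.yy1_only) + len(self.yy1_cobound)

    def fraction_ctcf_cobound(self) -> float:
        return len(self.ctcf_cobound) / self.n_ctcf if self.n_ctcf else 0.0

    def fraction_yy1_cobound(self) -> float:
        return len(self.yy1_cobound) / self.n_yy1 if self.n_yy1 else 0.0

    def class_events(self, cls: str) -> BindingEventSet:
        if cls == "CTCF_ONLY":
            return self.ctcf_only
        if cls == "YY1_ONLY":
            return self.yy1_only
        if cls == "CTCF_YY1":
            return self.ctcf_cobound
        raise KeyError(cls)


def classify_cobinding(ctcf: BindingEventSet, yy1: BindingEventSet) -> CobindPartition:
    """Partition events by >= 1 bp cross-factor overlap.

    A CTCF event overlapping several YY1 events yields one pair per overlap
    but is counted once in the class tallies.
    """
    if ctcf.species != yy1.species:
        raise ValueError(f"species mismatch: {ctcf.species} vs {yy1.species}")
    c_hit = yy1.any_overlap(ctcf.df.chrom, ctcf.df.start, ctcf.df.end)
    y_hit = ctcf.any_overlap(yy1.df.chrom, yy1.df.start, yy1.df.end)
    sp = ctcf.species
    ctcf_only = BindingEventSet(sp, "CTCF", ctcf.df[~c_hit])
    ctcf_cob = BindingEventSet(sp, "CTCF", ctcf.df[c_hit])
    yy1_only = BindingEventSet(sp, "YY1", yy1.df[~y_hit])
    yy1_cob = BindingEventSet(sp, "YY1", yy1.df[y_hit])

    pair_rows = []
    for ci, iv in enumerate(ctcf_cob.intervals()):
        for yi in yy1_cob.overlapping_indices(iv):
            pair_rows.append((ci, int(yi)))
    pairs = pd.DataFrame(pair_rows, columns=["ctcf_index", "yy1_index"])
    return CobindPartition(sp, ctcf_only, yy1_only, ctcf_cob, yy1_cob, pairs)


# --------------------------------------------------------- feature overlap

@dataclass
class AssociationSummary:
    """Cross-species summary of class x feature overlap fractions."""

    feature_kind: str
    fractions: pd.DataFrame  # index species, columns classes
    mean: pd.Series
    se: pd.Series
    p_value: float | None  # CTCF_ONLY vs CTCF_YY1 across species


def _feature_index(features: Sequence[FeatureAnnotation], kind: str) -> BindingEventSet:
    rows = [
        (f.interval.chrom, f.interval.start, f.interval.end)
        for f in features
        if f.kind == kind
    ]
    if not rows:
        return BindingEventSet("features", kind)
    chrom, start, end = zip(*rows)
    return BindingEventSet.from_arrays("features", kind, list(chrom), start, end)


def feature_association(
    partitions: Mapping[str, CobindPartition],
    features: Mapping[str, Sequence[FeatureAnnotation]],
    feature_kind: str,
) -> AssociationSummary:
    """Fraction of events per class overlapping >= 1 feature, across species.

    Species with an empty class are omitted from the rank-sum comparison
    with a logged warning.  The p-value compares the per-species CTCF-only
    fractions against the CTCF-YY1 fractions (two-sided rank-sum).
    """
    if not partitions:
        raise ValueError("need at least one species")
    rows = {}
    usable = []
    for sp, part in partitions.items():
        feat_idx = _feature_index(features.get(sp, []), feature_kind)
        fracs = {}
        complete = True
        for cls in COBIND_CLASSES:
            evset = part.class_events(cls)
            if len(evset) == 0:
                logger.warning("%s: class %s empty; omitted from the test", sp, cls)
                fracs[cls] = np.nan
                complete = False
                continue
            hit = feat_idx.any_overlap(evset.df.chrom, evset.df.start, evset.df.end)
            fracs[cls] = float(hit.mean())
        rows[sp] = fracs
        if complete:
            usable.append(sp)
    frame = pd.DataFrame.from_dict(rows, orient="index")[COBIND_CLASSES].sort_index()
    mean = frame.mean()
    se = frame.std(ddof=1) / np.sqrt(frame.notna().sum())
    p_value: float | None = None
    if len(usable) >= 2:
        a = frame.loc[usable, "CTCF_ONLY"].to_numpy()
        b = frame.loc[usable, "CTCF_YY1"].to_numpy()
        p_value = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return AssociationSummary(feature_kind, frame, mean, se, p_value)


# ------------------------------------------------------------- expression

@dataclass
class ExpressionComparison:
    """Per-class log2 expression values and between-class test p-values."""

    values: dict[str, np.ndarray]
    summaries: pd.DataFrame  # five-number summary per class
    p_ctcf_vs_cobound: float | None
    p_ctcf_vs_yy1_containing: float | None
    test: str = "ranksum"


def _five_number(x: np.ndarray) -> dict[str, float]:
    q = np.percentile(x, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def expression_comparison(
    partition: CobindPartition,
    transcripts: Sequence[FeatureAnnotation],
    expression: Mapping[str, float],
    test: str = "ranksum",
) -> ExpressionComparison:
    """Compare log2 transcript estimates between co-binding classes.

    Transcripts are assigned by >= 1 bp overlap with class events; a
    transcript overlapping at least one CTCF-YY1 pair is CTCF_YY1 regardless
    of other overlaps, then CTCF_ONLY, then YY1_ONLY.  Comparisons with a
    class of < 2 transcripts are reported as unavailable (None).  The
    default test is the two-sided Mann-Whitney rank-sum; ``test="signed_rank"``
    uses the Wilcoxon signed-rank test and requires equal class sizes.
    """
    if test not in ("ranksum", "signed_rank"):
        raise ValueError("test must be 'ranksum' or 'signed_rank'")
    usable = [t for t in transcripts if t.id in expression]
    chrom = [t.interval.chrom for t in usable]
    start = np.array([t.interval.start for t in usable], dtype=np.int64)
    end = np.array([t.interval.end for t in usable], dtype=np.int64)
    expr = np.array([float(expression[t.id]) for t in usable])

    def any_hit(*sets: BindingEventSet) -> np.ndarray:
        hit = np.zeros(len(usable), dtype=bool)
        for s in sets:
            hit |= s.any_overlap(chrom, start, end)
        return hit

    hit_pair = any_hit(partition.ctcf_cobound, partition.yy1_cobound)
    hit_ctcf = any_hit(partition.ctcf_only)
    hit_yy1 = any_hit(partition.yy1_only)
    arrays = {
        "CTCF_YY1": expr[hit_pair],
        "CTCF_ONLY": expr[hit_ctcf & ~hit_pair],
        "YY1_ONLY": expr[hit_yy1 & ~hit_pair & ~hit_ctcf],
    }
    summaries = pd.DataFrame(
        {
            cls: _five_number(arr) if len(arr) else
            {"min": np.nan, "q1": np.nan, "median": np.nan, "q3": np.nan, "max": np.nan}
            for cls, arr in arrays.items()
        }
    ).T

    def compare(a: np.ndarray, b: np.ndarray) -> float | None:
        if len(a) < 2 or len(b) < 2:
            return None
        if test == "signed_rank":
            if len(a) != len(b):
                raise ValueError("signed-rank comparison requires equal class sizes")
            return float(stats.wilcoxon(a, b).pvalue)
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    yy1_containing = np.concatenate([arrays["CTCF_YY1"], arrays["YY1_ONLY"]])
    return ExpressionComparison(
        arrays,
        summaries,
        compare(arrays["CTCF_ONLY"], arrays["CTCF_YY1"]),
        compare(arrays["CTCF_ONLY"], yy1_containing),
        test,
    )
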