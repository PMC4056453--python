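"""PWM scanning, nocc/normWord statistics, and expanded-word selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from primatecons import synthetic
from primatecons.core import GenomicInterval, RepeatElement
from primatecons.words import (
    PWM,
    build_word_table,
    count_repeat_embedded_words,
    norm_word_scores,
    reverse_complement,
    scan_pwm,
    select_specific_words,
)
from conftest import make_events


@pytest.fixture
def toy_pwm():
    # consensus ACG
    return PWM(np.array([
        [0.7, 0.1, 0.1, 0.1],
        [0.1, 0.6, 0.2, 0.1],
        [0.05, 0.05, 0.8, 0.1],
    ]))


class TestPWM:
    def test_consensus_and_validation(self, toy_pwm):
        assert toy_pwm.consensus == "ACG"
        with pytest.raises(ValueError):
            PWM(np.array([[0.5, 0.6, 0.0, 0.0]]))  # row sum != 1

    def test_file_round_trip(self, tmp_path, toy_pwm):
        path = tmp_path / "pwm.tsv"
        toy_pwm.to_file(path)
        back = PWM.from_file(path)
        assert np.allclose(back.probs, toy_pwm.probs)


class TestScan:
    def test_consensus_scores_zero(self, toy_pwm):
        hits = scan_pwm("ACG", toy_pwm)
        plus = hits[hits.strand == "+"]
        assert len(plus) == 1 and plus.iloc[0].score == 0.0
        assert plus.iloc[0].word == "ACG"

    def test_all_scores_nonpositive(self, toy_pwm):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        hits = scan_pwm(seq, toy_pwm, cutoff=-100.0)
        assert (hits.score <= 1e-12).all()

    def test_cutoff_excludes_low_scores(self):
        # 2-position PWM with a strongly disfavoured base
        pwm = PWM(np.array([[0.97, 0.01, 0.01, 0.01], [0.01, 0.97, 0.01, 0.01]]))
        worst = 2 * math.log2(0.01 / 0.97)
        hits = scan_pwm("TG", pwm, cutoff=worst + 0.1)
        assert len(hits[hits.strand == "+"]) == 0
        hits = scan_pwm("TG", pwm, cutoff=worst - 0.1)
        assert len(hits[hits.strand == "+"]) == 1

    def test_hand_summed_scores(self):
        pwm = PWM(np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.8, 0.2]]))
        hits = scan_pwm("CG", pwm, cutoff=-50)
        plus = hits[hits.strand == "+"].iloc[0]
        # log2(0.5/0.5) + log2(0.8/0.8) = 0
        assert plus.score == pytest.approx(0.0)
        hits = scan_pwm("CT", pwm, cutoff=-50)
        plus = hits[hits.strand == "+"].iloc[0]
        assert plus.score == pytest.approx(math.log2(0.2 / 0.8))

    def test_n_windows_skipped(self, toy_pwm):
        hits = scan_pwm("ANG", toy_pwm, cutoff=-1000)
        assert len(hits) == 0

    def test_minus_strand_word_in_pwm_orientation(self, toy_pwm):
        # revcomp of consensus ACG is CGT; scanning CGT should hit on '-'
        hits = scan_pwm("CGT", toy_pwm)
        minus = hits[hits.strand == "-"]
        assert len(minus) == 1
        assert minus.iloc[0].word == "ACG" and minus.iloc[0].score == 0.0

    @given(st.text(alphabet="ACGT", min_size=3, max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_strand_symmetry(self, seq):
        pwm = PWM(np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.6, 0.2, 0.1],
            [0.05, 0.05, 0.8, 0.1],
        ]))
        fwd = scan_pwm(seq, pwm, cutoff=-30)
        rev = scan_pwm(reverse_complement(seq), pwm, cutoff=-30)
        # mirrored positions, swapped strands, identical score multiset
        assert sorted(np.round(fwd.score, 9)) == sorted(np.round(rev.score, 9))
        n = len(seq) - pwm.length
        mirrored = sorted((n - p, {"+": "-", "-": "+"}[s]) for p, s in zip(fwd.pos, fwd.strand))
        assert mirrored == sorted(zip(rev.pos, rev.strand))


def _hits(sp_rows):
    return pd.DataFrame(sp_rows, columns=["chrom", "pos", "strand", "word", "score"])


class TestWordTable:
    def test_nocc_formula(self):
        bound = {"a": make_events("a", "CTCF", [("chr1", 0, 2_000_000)])}
        hits = {"a": _hits([("chr1", i, "+", "AAA", 0.0) for i in range(10)])}
        table = build_word_table(hits, bound, min_count=5)
        assert table.factors["a"] == 2.0
        assert table.counts.loc["AAA", "a"] == 10
        assert table.nocc.loc["AAA", "a"] == 5.0

    def test_min_count_filter(self):
        bound = {"a": make_events("a", "CTCF", [("chr1", 0, 1_000_000)])}
        hits = {"a": _hits([("chr1", i, "+", "AAA", 0.0) for i in range(4)]
                           + [("chr1", i, "+", "CCC", 0.0) for i in range(5)])}
        table = build_word_table(hits, bound, min_count=5)
        assert "AAA" not in table.counts.index
        assert "CCC" in table.counts.index

    def test_hits_outside_bound_ignored(self):
        bound = {"a": make_events("a", "CTCF", [("chr1", 0, 100)])}
        hits = {"a": _hits([("chr1", 5, "+", "AAA", 0.0)] * 6
                           + [("chr1", 5000, "+", "AAA", 0.0)] * 6)}
        table = build_word_table(hits, bound, min_count=5)
        assert table.counts.loc["AAA", "a"] == 6

    def test_scale_invariance_of_nocc(self):
        for scale in (2, 5):
            bound = {"a": make_events("a", "CTCF", [("chr1", 0, 1_000_000 * scale)])}
            hits = {"a": _hits([("chr1", i, "+", "AAA", 0.0) for i in range(6 * scale)])}
            table = build_word_table(hits, bound, min_count=5)
            assert table.nocc.loc["AAA", "a"] == pytest.approx(6.0)

    def test_zero_bound_bases_rejected(self):
        from primatecons.core import BindingEventSet

        bound = {"a": BindingEventSet("a", "CTCF")}
        with pytest.raises(ValueError, match="zero bound bases"):
            build_word_table({"a": _hits([])}, bound)


class TestNormWord:
    def _table(self, noccs):
        """Table with one word and given per-species nocc (factor 1 Mb)."""
        bound = {
            sp: make_events(sp, "CTCF", [("chr1", 0, 1_000_000)]) for sp in noccs
        }
        hits = {
            sp: _hits([("chr1", i, "+", "AAAA", 0.0) for i in range(int(v))])
            for sp, v in noccs.items()
        }
        return build_word_table(hits, bound, min_count=1)

    @pytest.mark.parametrize(
        "ns,nr,expected",
        [(15, 3, 2.0), (0, 15, -4.0), (7, 7, 0.0)],
    )
    def test_forced_arithmetic(self, ns, nr, expected):
        table = self._table({"S": ns, "r1": nr, "r2": max(nr - 1, 0)})
        out = norm_word_scores(table, "S", ["r1", "r2"])
        assert out.normword.iloc[0] == pytest.approx(expected)

    def test_antisymmetry_two_species(self):
        table = self._table({"S": 12, "R": 5})
        fwd = norm_word_scores(table, "S", ["R"]).normword.iloc[0]
        rev = norm_word_scores(table, "R", ["S"]).normword.iloc[0]
        assert fwd == pytest.approx(-rev)

    def test_clade_uses_maximum(self):
        table = self._table({"a": 3, "b": 15, "r": 3})
        out = norm_word_scores(table, ["a", "b"], ["r"])
        assert out.normword.iloc[0] == pytest.approx(math.log2(16 / 4))

    def test_focal_in_comparison_rejected(self):
        table = self._table({"a": 3, "b": 4})
        with pytest.raises(ValueError):
            norm_word_scores(table, "a", ["a", "b"])
        with pytest.raises(ValueError):
            norm_word_scores(table, "a", [])


class TestSelection:
    def test_null_normal_scores_select_nothing(self):
        rng = np.random.default_rng(123)
        n_sel = []
        for _ in range(10):
            scores = pd.DataFrame(
                {"word": [f"w{i}" for i in range(10_000)],
                 "normword": rng.normal(0, 1, 10_000)}
            )
            sel, cutoff = select_specific_words(scores, fdr=0.05)
            n_sel.append(len(sel))
        assert np.mean(n_sel) < 0.5

    def test_planted_outlier_selected(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(
            {"word": [f"w{i}" for i in range(2000)] + ["PLANTED"],
             "normword": list(rng.normal(0, 0.4, 2000)) + [4.0]}
        )
        sel, cutoff = select_specific_words(scores, fdr=0.05)
        assert "PLANTED" in sel
        assert cutoff <= 4.0

    def test_empty_selection_reports_inf_cutoff(self):
        scores = pd.DataFrame(
            {"word": [f"w{i}" for i in range(50)],
             "normword": np.linspace(-0.1, 0.1, 50)}
        )
        sel, cutoff = select_specific_words(scores)
        assert sel == [] and cutoff == float("inf")

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_specific_words(pd.DataFrame({"word": ["a"], "normword": [0.0]}))
        scores = pd.DataFrame({"word": [f"w{i}" for i in range(20)],
                               "normword": [1.0] * 20})
        with pytest.raises(ValueError, match="variance"):
            select_specific_words(scores)


class TestRepeatEmbedded:
    def test_counts_hits_fully_inside_repeats(self):
        bound = make_events("a", "CTCF", [("chr1", 0, 10_000)])
        hits = _hits([
            ("chr1", 100, "+", "AAA", 0.0),   # inside repeat
            ("chr1", 200, "+", "AAA", 0.0),   # inside repeat
            ("chr1", 298, "+", "AAA", 0.0),   # straddles repeat end -> excluded
            ("chr1", 5000, "+", "AAA", 0.0),  # outside repeats
            ("chr1", 150, "+", "CCC", 0.0),
        ])
        reps = [RepeatElement(GenomicInterval("chr1", 50, 300), "R1")]
        out = count_repeat_embedded_words(["AAA", "CCC"], hits, bound, reps)
        counts = dict(zip(out.word, out["count"]))
        assert counts == {"AAA": 2, "CCC": 1}
        assert out.log10_count.iloc[0] == pytest.approx(math.log10(3))

    def test_no_repeats_all_zero(self):
        bound = make_events("a", "CTCF", [("chr1", 0, 1000)])
        hits = _hits([("chr1", 5, "+", "AAA", 0.0)])
        out = count_repeat_embedded_words(["AAA"], hits, bound, [])
        assert (out["count"] == 0).all()

    def test_end_to_end_planted_expansion_recovered(self):
        cfg = synthetic.default_world(seed=40)
        cfg.word_spec = synthetic.WordSpec(species="mmul")
        amap = synthetic.generate_alignment_map(cfg)
        events, _ = synthetic.generate_binding_events(cfg, amap)
        hits = synthetic.generate_word_hits(cfg, events)
        bound = {sp: events[sp]["CTCF"] for sp in hits}
        table = build_word_table(hits, bound)
        scores = norm_word_scores(table, "mmul", [s for s in table.species if s != "mmul"])
        sel, _ = select_specific_words(scores)
        assert cfg.word_spec.word in sel
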