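"""Projection arithmetic, conservation classes, pairwise sharing, FDR sweep."""

import numpy as np
import pytest

from primatecons.conservation import (
    AlignmentBlock,
    AlignmentMap,
    Segment,
    classify_conservation,
    fdr_sensitivity_overlap,
    overlap_divergence_correlation,
    pairwise_shared_fraction,
    project_interval,
    read_block_table,
    read_maf,
    write_block_table,
)
from primatecons.core import GenomicInterval
from conftest import make_events, make_map


def brute_force_projection(iv, amap, from_sp, to_sp):
    """Per-base offset mapping: the independent projection oracle."""
    covered = set()
    for block in amap.blocks:
        if from_sp not in block.segments or to_sp not in block.segments:
            continue
        sf, st_ = block.segments[from_sp], block.segments[to_sp]
        if sf.chrom != iv.chrom or sf.length != st_.length:
            continue
        flip = (sf.strand == "-") != (st_.strand == "-")
        for b in range(max(iv.start, sf.start), min(iv.end, sf.end)):
            off = b - sf.start
            if flip:
                covered.add((st_.chrom, st_.start + sf.length - 1 - off))
            else:
                covered.add((st_.chrom, st_.start + off))
    return covered


class TestProjection:
    def test_plus_strand_offset(self, two_species_map):
        iv = GenomicInterval("chr1", 1100, 1200)
        out = project_interval(iv, two_species_map, "A", "B")
        assert out == [GenomicInterval("chr2", 5100, 5200)]

    def test_minus_strand_reversal(self, two_species_map):
        iv = GenomicInterval("chr1", 3000, 3100)
        out = project_interval(iv, two_species_map, "A", "B")
        # block b2 is 500 bp, B on minus strand: first 100 bases map to the tail
        assert out == [GenomicInterval("chr2", 8400, 8500)]

    def test_identity_projection_clips_to_blocks(self, two_species_map):
        iv = GenomicInterval("chr1", 900, 1100)
        out = project_interval(iv, two_species_map, "A", "A")
        assert out == [GenomicInterval("chr1", 1000, 1100)]

    def test_outside_blocks_empty(self, two_species_map):
        assert project_interval(GenomicInterval("chr1", 1, 500), two_species_map, "A", "B") == []

    def test_unknown_species_raises(self, two_species_map):
        with pytest.raises(KeyError):
            project_interval(GenomicInterval("chr1", 1100, 1200), two_species_map, "Z", "B")

    def test_proportional_scaling(self):
        amap = make_map(("b", {"A": ("chr1", 0, 100), "B": ("chr2", 0, 200)}))
        out = project_interval(GenomicInterval("chr1", 25, 50), amap, "A", "B")
        assert out == [GenomicInterval("chr2", 50, 100)]

    def test_matches_per_base_oracle_on_random_blocks(self):
        rng = np.random.default_rng(42)
        blocks = []
        a_pos = b_pos = 0
        for i in range(100):
            length = int(rng.integers(50, 200))
            a_pos += int(rng.integers(10, 100))
            b_pos += int(rng.integers(10, 100))
            strand = "-" if rng.random() < 0.3 else "+"
            blocks.append(
                AlignmentBlock(
                    f"b{i}",
                    {
                        "A": Segment("chr1", a_pos, a_pos + length),
                        "B": Segment("chr2", b_pos, b_pos + length, strand),
                    },
                )
            )
            a_pos += length
            b_pos += length
        amap = AlignmentMap(blocks)
        span = a_pos
        for _ in range(1000):
            s = int(rng.integers(0, span - 1))
            e = s + int(rng.integers(1, 400))
            iv = GenomicInterval("chr1", s, e)
            pieces = project_interval(iv, amap, "A", "B")
            got = {(p.chrom, b) for p in pieces for b in range(p.start, p.end)}
            assert got == brute_force_projection(iv, amap, "A", "B")

    def test_round_trip_overlaps_original(self):
        rng = np.random.default_rng(3)
        amap = make_map(
            ("b1", {"A": ("chr1", 100, 600), "B": ("chr2", 900, 1400, "-")}),
            ("b2", {"A": ("chr1", 700, 900), "B": ("chr2", 2000, 2200)}),
        )
        for _ in range(50):
            s = int(rng.integers(100, 880))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 50)))
            for p in project_interval(iv, amap, "A", "B"):
                back = project_interval(p, amap, "B", "A")
                assert any(max(q.start, iv.start) < min(q.end, iv.end) for q in back)


class TestClassification:
    def test_three_species_toy(self):
        amap = make_map(
            ("b1", {"A": ("chr1", 0, 1000), "B": ("chr1", 0, 1000), "C": ("chr1", 0, 1000)}),
        )
        sets = {
            "A": make_events("A", "CTCF", [("chr1", 100, 200), ("chr1", 400, 500), ("chr1", 5000, 5100)]),
            "B": make_events("B", "CTCF", [("chr1", 120, 220)]),
            "C": make_events("C", "CTCF", [("chr1", 800, 900)]),
        }
        cls = classify_conservation(sets, amap, "A")
        assert cls.labels == ["TWO_WAY", "SPECIES_SPECIFIC", "UNALIGNED"]
        assert cls.sharing[0] == frozenset({"A", "B"})
        fr = cls.class_fractions()
        assert abs(sum(fr.values()) - 1.0) < 1e-12

    def test_all_species_shared(self):
        amap = make_map(
            ("b1", {s: ("chr1", 0, 1000) for s in "ABC"}),
        )
        sets = {s: make_events(s, "CTCF", [("chr1", 10, 60)]) for s in "ABC"}
        cls = classify_conservation(sets, amap, "A")
        assert cls.labels == ["ALL"]

    def test_empty_species_map_rejected(self, two_species_map):
        with pytest.raises(ValueError):
            classify_conservation({}, two_species_map, "A")

    def test_recovers_planted_labels(self, small_world_config):
        from primatecons import synthetic

        amap = synthetic.generate_alignment_map(small_world_config)
        events, truth = synthetic.generate_binding_events(small_world_config, amap)
        sets = {sp: events[sp]["CTCF"] for sp in events}
        cls = classify_conservation(sets, amap, "hsap")
        planted = truth[(truth.factor == "CTCF") & (truth.label != "OTHER_SPECIFIC")]
        anchor_df = events["hsap"]["CTCF"].df
        planted_by_name = dict(zip(planted.group_id, planted.label))
        got = dict(zip(anchor_df.name, cls.labels))
        mismatches = sum(
            1 for gid, lab in planted_by_name.items() if got.get(gid) != lab
        )
        assert mismatches == 0


class TestPairwiseSharing:
    def test_identical_sets_identity_map(self):
        amap = make_map(("b", {"A": ("chr1", 0, 10_000), "B": ("chr1", 0, 10_000)}))
        a = make_events("A", "CTCF", [("chr1", 100, 200), ("chr1", 400, 500)])
        b = make_events("B", "CTCF", [("chr1", 100, 200), ("chr1", 400, 500)])
        assert pairwise_shared_fraction(a, b, amap) == 1.0

    def test_disjoint_sets(self):
        amap = make_map(("b", {"A": ("chr1", 0, 10_000), "B": ("chr1", 0, 10_000)}))
        a = make_events("A", "CTCF", [("chr1", 100, 200)])
        b = make_events("B", "CTCF", [("chr1", 5000, 5100)])
        assert pairwise_shared_fraction(a, b, amap) == 0.0

    def test_direction_average_hand_count(self):
        # a: 4 events, 2 shared; b: 2 events, both shared -> mean(0.5, 1.0)
        amap = make_map(("b", {"A": ("chr1", 0, 10_000), "B": ("chr1", 0, 10_000)}))
        a = make_events("A", "CTCF", [("chr1", 0, 100), ("chr1", 200, 300),
                                      ("chr1", 400, 500), ("chr1", 600, 700)])
        b = make_events("B", "CTCF", [("chr1", 50, 120), ("chr1", 250, 310)])
        assert pairwise_shared_fraction(a, b, amap) == pytest.approx(0.75)

    def test_empty_set_rejected(self, two_species_map):
        a = make_events("A", "CTCF", [("chr1", 1100, 1150)])
        from primatecons.core import BindingEventSet

        with pytest.raises(ValueError):
            pairwise_shared_fraction(a, BindingEventSet("B", "CTCF"), two_species_map)


class TestDivergenceCorrelation:
    def test_strictly_decreasing_gives_minus_one(self):
        fr = {"a": 0.9, "b": 0.7, "c": 0.5}
        dv = {"a": 5.0, "b": 25.0, "c": 45.0}
        r, _ = overlap_divergence_correlation(fr, dv)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # closed form for (0.9, 0.7, 0.5) against (5, 25, 40)
        x = np.array([5.0, 25.0, 40.0])
        y = np.array([0.9, 0.7, 0.5])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r, _ = overlap_divergence_correlation(
            {"a": 0.9, "b": 0.7, "c": 0.5}, {"a": 5.0, "b": 25.0, "c": 40.0}
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            overlap_divergence_correlation(
                {"a": 0.5, "b": 0.5, "c": 0.5}, {"a": 1.0, "b": 2.0, "c": 3.0}
            )


class TestFdrSensitivity:
    def _setup(self):
        amap = make_map(("b", {"A": ("chr1", 0, 10_000), "B": ("chr1", 0, 10_000)}))
        anchor = make_events("A", "CTCF", [("chr1", 0, 100), ("chr1", 200, 300)])
        other = make_events(
            "B", "CTCF", [("chr1", 10, 90), ("chr1", 210, 290)], fdr=[0.01, 0.3]
        )
        return amap, anchor, other

    def test_step_at_rescuing_fdr(self):
        amap, anchor, other = self._setup()
        out = fdr_sensitivity_overlap(anchor, other, amap, [0.05, 0.2, 0.3, 0.5])
        assert out[0.05] == 0.5
        assert out[0.2] == 0.5
        assert out[0.3] == 1.0
        assert out[0.5] == 1.0

    def test_monotone_nondecreasing(self):
        amap, anchor, other = self._setup()
        out = fdr_sensitivity_overlap(anchor, other, amap, [0.01, 0.1, 0.3, 0.5])
        vals = [out[g] for g in sorted(out)]
        assert vals == sorted(vals)

    def test_warns_above_half(self):
        amap, anchor, other = self._setup()
        with pytest.warns(UserWarning):
            fdr_sensitivity_overlap(anchor, other, amap, [0.6])

    def test_unsorted_grid_rejected(self):
        amap, anchor, other = self._setup()
        with pytest.raises(ValueError):
            fdr_sensitivity_overlap(anchor, other, amap, [0.3, 0.1])


class TestBlockTableIO:
    def test_round_trip(self, tmp_path, two_species_map):
        path = tmp_path / "blocks.tsv"
        write_block_table(two_species_map, path)
        back = read_block_table(path)
        assert len(back) == len(two_species_map)
        iv = GenomicInterval("chr1", 1100, 1200)
        assert project_interval(iv, back, "A", "B") == project_interval(
            iv, two_species_map, "A", "B"
        )

    def test_maf_reader(self, tmp_path):
        maf = (
            "##maf version=1\n"
            "a score=1.0\n"
            "s A.chr1 1000 50 + 100000 " + "A" * 50 + "\n"
            "s B.chr2 2000 50 + 100000 " + "A" * 50 + "\n"
            "\n"
        )
        path = tmp_path / "toy.maf"
        path.write_text(maf)
        amap = read_maf(path)
        out = project_interval(GenomicInterval("chr1", 1010, 1020), amap, "A", "B")
        assert out == [GenomicInterval("chr2", 2010, 2020)]
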