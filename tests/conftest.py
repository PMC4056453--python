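import numpy as np
import pandas as pd
import pytest

from primatecons.conservation import AlignmentBlock, AlignmentMap, Segment
from primatecons.core import BindingEventSet


def make_map(*blocks):
    """AlignmentMap from (block_id, {species: (chrom, start, end[, strand])})."""
    out = []
    for bid, segs in blocks:
        out.append(
            AlignmentBlock(
                bid,
                {
                    sp: Segment(*vals) if len(vals) == 4 else Segment(*vals, "+")
                    for sp, vals in segs.items()
                },
            )
        )
    return AlignmentMap(out)


def make_events(species, factor, triples, fdr=None):
    """BindingEventSet from (chrom, start, end) triples."""
    chrom = [t[0] for t in triples]
    start = [t[1] for t in triples]
    end = [t[2] for t in triples]
    return BindingEventSet.from_arrays(
        species, factor, chrom, start, end,
        fdr=fdr if fdr is not None else [0.0] * len(triples),
    )


@pytest.fixture
def two_species_map():
    return make_map(
        ("b1", {"A": ("chr1", 1000, 2000), "B": ("chr2", 5000, 6000)}),
        ("b2", {"A": ("chr1", 3000, 3500), "B": ("chr2", 8000, 8500, "-")}),
    )


@pytest.fixture
def small_world_config():
    from primatecons import synthetic

    return synthetic.default_world(
        seed=11, n_events=300, n_yy1_only=100, extra_specific_per_species=30
    )
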