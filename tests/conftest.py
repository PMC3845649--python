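import warnings

import numpy as np
import pytest

from strainforge.simulate import (AncestorConfig, apply_events, build_ancestor,
                                  simulate_short_reads)
from strainforge.simulate.reads import ReadSimConfig

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def small_ancestor():
    """20-kb AT-biased ancestor with two identical IS copies."""
    return build_ancestor(AncestorConfig(
        length=20_000, gc=0.36,
        placements=[("is", {"family": "IS5", "length": 900, "tir_len": 30,
                            "starts": [4_000, 12_000]})]), seed=11)


@pytest.fixture(scope="session")
def plain_ancestor():
    """Feature-less 12-kb ancestor (no repeats: unique mapping everywhere)."""
    return build_ancestor(AncestorConfig(length=12_000, gc=0.36), seed=23)


def short_lib(seq, seed, depth=30.0, insert_mean=700.0, insert_sd=70.0,
              eps_sub=0.002, name="reads"):
    cfg = ReadSimConfig(technology="short", read_length=100, paired=True,
                        insert_mean=insert_mean, insert_sd=insert_sd,
                        eps_sub=eps_sub, depth=depth)
    return simulate_short_reads(seq, cfg, seed, name=name)


@pytest.fixture(scope="session")
def mapped_plain(plain_ancestor):
    """Error-free library mapped to the plain ancestor, with pileup."""
    from strainforge.align import (ReferenceIndex, assign_multimappers,
                                   map_read_pairs)
    from strainforge.variants import pileup

    reads = short_lib(plain_ancestor.sequence, seed=5, eps_sub=0.0)
    index = ReferenceIndex(plain_ancestor.name, plain_ancestor.sequence, k=17)
    records = map_read_pairs(reads, index)
    assign_multimappers(records, 1)
    pile = pileup(records, plain_ancestor.name, plain_ancestor.sequence)
    return reads, index, records, pile


def rng(seed=0):
    return np.random.default_rng(seed)
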