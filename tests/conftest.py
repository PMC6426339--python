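import numpy as np
import pandas as pd
import pytest

from damidkit import FragmentMap, GenomeIndex, build_fragment_map


@pytest.fixture
def toy_genome():
    # GATC at 2 and 8 -> cuts at 4 and 10 -> fragments [0,4) [4,10) [10,14)
    return GenomeIndex({"c1": "AAGATCTTGATCAA"})


@pytest.fixture
def toy_fmap(toy_genome):
    return build_fragment_map(toy_genome)


@pytest.fixture
def make_fmap():
    """Factory for uniform synthetic fragment maps."""

    def _make(n_frags, frag_len=100, chroms=("chr1",)):
        starts = {c: np.arange(n_frags, dtype=np.int64) * frag_len for c in chroms}
        ends = {c: starts[c] + frag_len for c in chroms}
        return FragmentMap(list(chroms), starts, ends)

    return _make


@pytest.fixture
def make_alignments():
    """Factory for alignment DataFrames from (chrom, start, end, mapq, flag) rows."""

    def _make(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq", "flag"])

    return _make
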