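import numpy as np
import pytest

from splicequant.alignments import AlignmentRecord
from splicequant.annotation import Intron


def make_intron(start, end, strand="+", chrom="chr1", intron_id=None, gene_id="g"):
    return Intron(chrom, start, end, strand,
                  intron_id or f"{chrom}:{start}-{end}:{strand}", gene_id)


def make_record(blocks, mate="second", strand="+", chrom="chr1", read_id="r"):
    return AlignmentRecord(read_id, mate, chrom, strand, tuple(tuple(b) for b in blocks))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def intron():
    return make_intron(1000, 1200)
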