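import numpy as np
import pytest

from microinv.io_core import ReferenceGenome, decode
from microinv.segments import MSP, make_msp


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_sequence(rng, n, gc=0.5):
    p = [0.5 - gc / 2, gc / 2, gc / 2, 0.5 - gc / 2]
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def random_genome(rng, n, contig="chr1", gc=0.5):
    return ReferenceGenome({contig: random_sequence(rng, n, gc)})


def random_msp_instance(rng, n_msps, read_len=40, ref_len=40):
    """Random MSPs over random targets; returns (msps, read_target,
    ref_target).  M/MS are recomputed from the sequences so segment
    invariants hold by construction."""
    read_target = random_sequence(rng, read_len)
    ref_target = random_sequence(rng, ref_len)
    msps = []
    while len(msps) < n_msps:
        span = int(rng.integers(3, 16))
        rs = int(rng.integers(0, read_len - span + 1))
        fs = int(rng.integers(0, ref_len - span + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        m = make_msp(read_target, ref_target, rs, rs + span, fs, fs + span, strand)
        if m is not None:
            msps.append(m)
    return msps, read_target, ref_target


@pytest.fixture
def small_genome(rng):
    return random_genome(rng, 5000)
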