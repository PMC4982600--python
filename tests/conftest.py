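import numpy as np
import pytest

from motifarch.intervals import GenomicInterval
from motifarch.synthetic_matrices import ap1_pwm, nfy_pwm


@pytest.fixture(scope="session")
def ap1():
    return ap1_pwm()


@pytest.fixture(scope="session")
def nfy():
    return nfy_pwm()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_iv(chrom, start, end, name=""):
    return GenomicInterval(chrom, start, end, name)


@pytest.fixture
def random_intervals(rng):
    """Factory for random interval lists on a couple of chromosomes."""

    def make(n, max_pos=10_000, max_len=300, chroms=("chr1", "chr2")):
        out = []
        for i in range(n):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, max_pos))
            length = int(rng.integers(1, max_len))
            out.append(GenomicInterval(chrom, start, start + length, f"iv{i}"))
        return out

    return make


def random_dna(rng, n, gc=0.41):
    bases = np.array(list("ACGT"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(bases, size=n, p=p))
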