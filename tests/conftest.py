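import numpy as np
import pytest

from metalign import Genome, random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    """3 kbp genome with a planted exact duplication and an N run."""
    g = random_genome(3000, seed=7)
    seq = list(g.sequence)
    seq[1200:1500] = seq[200:500]          # 300 bp duplication
    seq[2000:2010] = "N" * 10              # assembly-gap style N run
    return Genome("toy", "".join(seq))


@pytest.fixture
def clean_genome():
    """Repeat-free-with-high-probability random genome."""
    return random_genome(100_000, seed=11)
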