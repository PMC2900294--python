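import numpy as np
import pytest

from nucpattern import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_windows(rng):
    """Factory for n random ACGT windows of a given width."""
    def make(n, width=51):
        lut = np.array(list("ACGT"))
        return ["".join(row) for row in lut[rng.integers(0, 4, size=(n, width))]]
    return make


@pytest.fixture(scope="session")
def small_genome():
    """One 120-kb chromosome with planted dyads at the default conditions."""
    spec = syn.GeneratorSpec(seed=42, genome_length=120_000)
    genome, truth = syn.simulate_genome(spec)
    return spec, genome, truth
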