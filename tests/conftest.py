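import pytest

import k4gauge as kg
from k4gauge.simulate import SimConfig


@pytest.fixture(scope="session")
def small_genome():
    """Six 300-kb chromosomes: big enough for +/-5 kb windows, fast to simulate."""
    return kg.default_toy_genome(300_000)


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def features(small_genome):
    tss, enh = kg.simulate_features(small_genome, n_tss=60, n_enh=30, seed=11)
    return tss, enh
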