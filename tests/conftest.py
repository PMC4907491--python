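import pytest

import readbias as rb


@pytest.fixture(scope="session")
def small_ref():
    """2 kb uniform-composition reference."""
    return rb.simulate_reference(2000, seed=11, name="chr1")


@pytest.fixture(scope="session")
def biased_track(small_ref):
    """Strongly dinucleotide-biased read starts on the small reference."""
    model = rb.BiasModel(order=2, beta=20.0)
    return rb.place_reads(small_ref, model, 5000, seed=12)


@pytest.fixture(scope="session")
def small_pool(small_ref, biased_track):
    config = rb.PoolConfig(strata=rb.default_strata(0.02), seed=3)
    return rb.build_pool([small_ref], [biased_track], config)
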