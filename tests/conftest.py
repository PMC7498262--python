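import numpy as np
import pytest

from cooccupy import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def sox_pwm():
    return sd.default_sox_pwm()


@pytest.fixture(scope="session")
def tcf_pwm():
    return sd.default_tcf_pwm()


@pytest.fixture(scope="session")
def small_genome():
    """100 kb uniform-composition Markov genome, fixed seed."""
    return sd.simulate_genome(100_000, seed=11)


@pytest.fixture(scope="session")
def planted(small_genome):
    """Default planted dataset: 200 peaks at fractions 0.5/0.25/0/0.25."""
    return sd.plant_peaks(small_genome, 200, seed=11)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
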