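import numpy as np
import pytest

from editscan import BenchmarkConfig, DistanceParams, KernelParams, make_benchmark

BASES = "ACGT"


def random_dna(rng, length):
    return "".join(BASES[i] for i in rng.integers(4, size=length))


def random_context(rng, length=41):
    """Random odd-length DNA string with 'A' at the center."""
    s = list(random_dna(rng, length))
    s[length // 2] = "A"
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def dp_default():
    return DistanceParams(w=0.5, l1=41, l2=31)


@pytest.fixture(scope="session")
def kp_default():
    return KernelParams(gamma=0.1)


@pytest.fixture(scope="session")
def bench_small():
    """Small strong-signal benchmark shared across test modules."""
    return make_benchmark(BenchmarkConfig(
        genome_length=60_000, n_sites=100, negative_rate=2e-3,
        mutation_prob=0.05, seed=7,
    ))
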