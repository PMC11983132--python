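import numpy as np
import pytest

from magrec.params import SimParams
from magrec.simulate.genome import build_hybrid_genome


def tiny_params(**kw) -> SimParams:
    """A small two-chromosome genome for fast unit tests."""
    defaults = dict(
        n_chromosomes=2,
        chrom_lengths=(150_000, 150_000),
        repeat_copies=4,
        repeat_length=3_000,
        rdna_unit_length=1_000,
        rdna_copy_number=10,
        cut_probability=0.004,
        seed=11,
        exact_depth=True,
        marker_noise=0.0,
    )
    defaults.update(kw)
    return SimParams(**defaults)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return tiny_params()


@pytest.fixture(scope="session")
def small_build(small_params):
    return build_hybrid_genome(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
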