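import numpy as np
import pytest

from befpartition import CommunityModel, CommunitySample, generate_community


@pytest.fixture
def two_species():
    """M=[4,2], Y=[3,0.5] with Q=N=2: dRY=[0.25,-0.25], dY=0.5."""
    return CommunitySample.from_arrays([4.0, 2.0], [3.0, 0.5])


@pytest.fixture
def two_species_pool10():
    """Same biomasses embedded in a pool of 10: dRY=[0.65,0.15]."""
    return CommunitySample.from_arrays([4.0, 2.0], [3.0, 0.5], pool_size=10)


@pytest.fixture
def community_q10():
    """Small fully observed community with nonzero CE and SE."""
    sample, truth = generate_community(CommunityModel(pool_size=10, seed=5))
    return sample, truth


def random_sample(rng: np.random.Generator, n: int, q: int | None = None) -> CommunitySample:
    """Ad-hoc community with positive M and arbitrary non-negative Y."""
    m = rng.uniform(0.5, 50.0, size=n)
    y = rng.uniform(0.0, 50.0, size=n)
    return CommunitySample.from_arrays(m, y, pool_size=q if q is not None else n)
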