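import numpy as np
import pytest

from degmeta import GeneUniverse, SignedGeneSet, generate_universe


@pytest.fixture
def tiny_universe() -> GeneUniverse:
    return GeneUniverse.from_iterable(f"AT1G{i:05d}" for i in range(10))


@pytest.fixture
def universe_1k() -> GeneUniverse:
    return generate_universe(1000, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def signed(label: str, **directions: int) -> SignedGeneSet:
    """Shorthand: signed('a', g1=+1, g2=-1)."""
    return SignedGeneSet(label=label, directions=dict(directions))
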