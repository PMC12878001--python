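import pytest

from retrofict.toyworld import ToyWorld, enumerate_pool, generate_toy_reactions


@pytest.fixture(scope="session")
def world():
    return ToyWorld(seed=11)


@pytest.fixture(scope="session")
def toy_pairs(world):
    """(MappedReaction, GroundTruth) pairs: 40 per family where available."""
    return generate_toy_reactions(world, 40)


@pytest.fixture(scope="session")
def templates_r0(world):
    return world.templates("r0")


@pytest.fixture(scope="session")
def templates_r1(world):
    return world.templates("r1")


@pytest.fixture(scope="session")
def pool(world):
    return enumerate_pool(world, 300)
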