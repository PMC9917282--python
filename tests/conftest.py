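import pytest

from s9conf.synth import ToySpec, closure_trajectory, make_toy_structure


@pytest.fixture(scope="session")
def toy_closed():
    """Closed-like pose: assembled triad, domains in contact, RR-SQ network."""
    return make_toy_structure(ToySpec(seed=7))


@pytest.fixture(scope="session")
def toy_trio():
    """Planted closed / intermediate / open along the closure trajectory."""
    return {
        "closed": make_toy_structure(closure_trajectory(0.0, seed=7)),
        "intermediate": make_toy_structure(closure_trajectory(1.5, seed=7)),
        "open": make_toy_structure(closure_trajectory(6.0, seed=7)),
    }


@pytest.fixture(scope="session")
def toy_sb1():
    """Closed-like pose with the planted interdomain Glu-Arg salt bridge."""
    return make_toy_structure(ToySpec(network="SB1", seed=7))
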