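import numpy as np
import pytest

from mirffl import ReactionNetwork, Reaction, Species, calibrate_cd69_model


@pytest.fixture(scope="session")
def cd69_params():
    """Calibrated translational-repression parameters for the CD69 circuit."""
    return calibrate_cd69_model()


def birth_death_network(birth: float, death: float, x0: int = 0) -> ReactionNetwork:
    """Zero-order birth / linear death: stationary law is Poisson(birth/death)."""
    return ReactionNetwork(
        [Species("X", x0)],
        [
            Reaction("birth", birth, {"X": 1}),
            Reaction("death", death, {"X": -1}, {"X": 1}),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20150225)
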