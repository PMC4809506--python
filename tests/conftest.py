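import numpy as np
import pytest

from bvrpop.markov import build_scheme


@pytest.fixture
def two_state():
    """C <-> O scheme with unit rates."""
    return build_scheme({
        "name": "two_state",
        "states": ["C", "O"],
        "transitions": [
            {"from": "C", "to": "O", "rate": "1.0"},
            {"from": "O", "to": "C", "rate": "1.0"},
        ],
        "open_states": ["O"],
    })


def make_two_state(alpha: float, beta: float, name: str = "cs"):
    return build_scheme({
        "name": name,
        "states": ["C", "O"],
        "transitions": [
            {"from": "C", "to": "O", "rate": str(alpha)},
            {"from": "O", "to": "C", "rate": str(beta)},
        ],
        "open_states": ["O"],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
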