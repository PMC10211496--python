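import numpy as np
import pytest

from trpwm.pwm import CompositionProfile, PositionWeightMatrix
from trpwm.seqio import DnaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_profile_mono():
    return CompositionProfile(p1=np.full(4, 0.25), p2=np.full(4, 0.25))


def random_sequence(rng, length, alphabet="ACGT"):
    return DnaSequence("rand", "".join(rng.choice(list(alphabet), size=length)))


def diagonal_matrix(unit: str, match: float = 10.0, mismatch: float = -10.0) -> PositionWeightMatrix:
    """Matrix whose row i strongly prefers the i-th base of ``unit`` (mono)."""
    order = {"A": 0, "T": 1, "C": 2, "G": 3}
    w = np.full((len(unit), 4), mismatch)
    for i, b in enumerate(unit):
        w[i, order[b]] = match
    return PositionWeightMatrix(w=w, mode="mono")
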