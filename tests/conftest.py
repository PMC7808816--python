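import numpy as np
import pytest

from lumiprot.model import BoosterParams
from lumiprot.seqio import ALPHABET, ProteinSequence
from lumiprot.synthetic import worked_example


@pytest.fixture
def example_seq() -> ProteinSequence:
    """MCRAACGECFR — the short reference peptide (L = 11)."""
    return worked_example()


@pytest.fixture
def light_params() -> BoosterParams:
    """A small booster for fast unit tests (not the tuned defaults)."""
    return BoosterParams(n_estimators=40, max_depth=3)


def random_sequence(rng: np.random.Generator, length: int, sid: str = "r") -> ProteinSequence:
    return ProteinSequence(sid, "".join(rng.choice(list(ALPHABET), size=length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
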