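import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from tatscan.alignment import ScoringScheme

RES20 = "ACDEFGHIKLMNPQRSTVWY"
RES21 = RES20 + "X"


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_protein(rng: np.random.Generator, length: int, alphabet: str = RES20) -> str:
    return "".join(alphabet[k] for k in rng.integers(len(alphabet), size=length))
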