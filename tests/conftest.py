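import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "acgt") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
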