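import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def data_dir() -> Path:
    """Optional external data (GenBank/WormBase downloads); may not exist."""
    return Path(__file__).resolve().parent.parent / "data" / "external"
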