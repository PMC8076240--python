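import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracle helpers importable as a plain module
sys.path.insert(0, str(Path(__file__).parent))

from mirhomology import FixtureSpec, Kingdom, MiRNALibrary, MiRNARecord, make_screen_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_plant():
    return MiRNALibrary(
        records=[
            MiRNARecord("pla-1", Kingdom.PLANT, "UGAAGCUGCCAGCAUGAUCUGA"),
            MiRNARecord("pla-2", Kingdom.PLANT, "ACGUACGUACGUACGUACGUAC"),
        ],
        kingdom=Kingdom.PLANT,
    )


@pytest.fixture
def tiny_animal():
    return MiRNALibrary(
        records=[
            MiRNARecord("ani-1", Kingdom.ANIMAL, "UGAAGCUGCCAGCAUGAUCUGA"),
            MiRNARecord("ani-2", Kingdom.ANIMAL, "CCCGGGAAAUUUCCCGGGAAAU"),
            MiRNARecord("ani-3", Kingdom.ANIMAL, "GUGCAAAUCUAUGCAAAACUGA"),
        ],
        kingdom=Kingdom.ANIMAL,
    )


@pytest.fixture(scope="session")
def default_fixture():
    """The default planted-homolog screen fixture (deterministic)."""
    return make_screen_fixture(FixtureSpec(rng_seed=0))


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))
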