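import numpy as np
import pytest

from saflex.alphabet import (
    StructuralAlphabet,
    StructuralLetter,
    load_alphabet,
    packaged_alphabet_path,
)
from saflex.synthetic import SyntheticSpec, random_alphabet


@pytest.fixture(scope="session")
def alphabet27() -> StructuralAlphabet:
    """The packaged 27-letter alphabet (synthetic parameters)."""
    return load_alphabet(packaged_alphabet_path())


@pytest.fixture(scope="session")
def toy_alphabet() -> StructuralAlphabet:
    """Small 2-letter alphabet with standard-normal-ish emissions."""
    letters = [
        StructuralLetter(code="A1", legacy_code="A", sl_class="helix",
                         frequency=0.5, mu=np.zeros(4), sigma=np.eye(4)),
        StructuralLetter(code="C1", legacy_code="B", sl_class="coil",
                         frequency=0.5, mu=np.full(4, 3.0), sigma=0.5 * np.eye(4)),
    ]
    return StructuralAlphabet(letters=letters,
                              transition=np.array([[0.9, 0.1], [0.2, 0.8]]))


@pytest.fixture(scope="session")
def synthetic_alphabet() -> StructuralAlphabet:
    return random_alphabet(SyntheticSpec(m=4, n=6, seed=11))
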