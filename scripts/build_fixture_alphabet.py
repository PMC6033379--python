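"""Regenerate the packaged synthetic 27-letter alphabet file.

The file carries the published 27-letter nomenclature — class-based codes,
legacy single-character codes, helix/coil/strand classes and training-set
frequencies — but SYNTHETIC Gaussian emission parameters and a SYNTHETIC
class-structured transition matrix, since the authentic numeric parameter
tables are not machine-readable here.  Means are anchored at the descriptor
vectors of ideal helix / strand geometry fixtures (coils scattered between
them), covariances are random SPD matrices, and transitions favour staying
within a secondary-structure class with no direct helix <-> strand moves.
Deterministic: running this script always reproduces the same file.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from saflex.alphabet import StructuralAlphabet, StructuralLetter, save_alphabet, validate_alphabet
from saflex.descriptors import trace_to_fragments
from saflex.synthetic import helix_fixture, strand_fixture

SEED = 20270

# published nomenclature: (code, legacy single-character code, frequency %)
TABLE = [
    ("A1", "A", 12.6), ("A2", "V", 5.6), ("A3", "W", 5.3), ("A4", "a", 2.6),
    ("C1", "B", 4.7), ("C2", "Z", 4.5), ("C3", "P", 4.4), ("C4", "K", 4.1),
    ("C5", "Q", 4.1), ("C6", "G", 3.4), ("C7", "S", 3.2), ("C8", "I", 2.9),
    ("C9", "H", 2.7), ("C10", "D", 2.0), ("C11", "E", 2.0), ("C12", "J", 2.0),
    ("C13", "U", 2.0), ("C14", "Y", 2.0), ("C15", "F", 1.9), ("C16", "C", 1.8),
    ("C17", "R", 1.7), ("C18", "O", 1.5),
    ("B1", "M", 5.3), ("B2", "L", 5.1), ("B3", "N", 4.9), ("B4", "X", 4.7),
    ("B5", "T", 3.0),
]

CLASS_OF_PREFIX = {"A": "helix", "B": "strand", "C": "coil"}


def main() -> None:
    rng = np.random.default_rng(SEED)
    helix_mu = trace_to_fragments(helix_fixture(8)).values.mean(axis=0)
    strand_mu = trace_to_fragments(strand_fixture(8)).values.mean(axis=0)

    letters = []
    for code, legacy, freq in TABLE:
        cls = CLASS_OF_PREFIX[code[0]]
        if cls == "helix":
            mu = helix_mu + rng.normal(scale=0.25, size=4)
            scale = 0.15
        elif cls == "strand":
            mu = strand_mu + rng.normal(scale=0.35, size=4)
            scale = 0.3
        else:  # coils spread over the region between the two anchors
            w = rng.uniform(0.15, 0.85)
            mu = w * helix_mu + (1 - w) * strand_mu + rng.normal(scale=1.0, size=4)
            scale = 0.6
        A = rng.normal(scale=scale, size=(4, 4))
        sigma = A @ A.T + 0.05 * np.eye(4)
        sigma = np.round((sigma + sigma.T) / 2, 6)
        letters.append(StructuralLetter(
            code=code, legacy_code=legacy, sl_class=cls,
            frequency=freq / 100.0, mu=np.round(mu, 6), sigma=sigma,
        ))

    m = len(letters)
    classes = np.array([sl.sl_class for sl in letters])
    pi = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            ci, cj = classes[i], classes[j]
            if ci == cj:
                w = 4.0 if i == j else 0.8
            elif "coil" in (ci, cj):
                w = 0.25
            else:
                w = 0.0  # no direct helix <-> strand transitions
            pi[i, j] = w * rng.uniform(0.5, 1.5)
    # A4-like letters bridge missing regions: give the last helix letter the
    # strongest self-transition of the alphabet
    a4 = 3
    pi[a4, a4] = pi.sum(axis=1).max()
    pi = pi / pi.sum(axis=1, keepdims=True)
    pi = np.round(pi, 6)
    for i in range(m):
        pi[i, i] = 0.0
        pi[i, i] = 1.0 - pi[i].sum()

    alphabet = StructuralAlphabet(letters=letters, transition=pi)
    violations = validate_alphabet(alphabet)
    assert not violations, violations
    self_tr = np.diag(alphabet.transition)
    assert np.argmax(self_tr) == a4, "A4 must have the highest self-transition"

    out = Path(__file__).resolve().parents[1] / "src" / "saflex" / "data" / "saflex27_synthetic.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    save_alphabet(alphabet, out)
    print(f"wrote {out} ({out.stat().st_size} bytes, m={m})")


if __name__ == "__main__":
    main()
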