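"""Structural-alphabet parameter sets: containers, JSON I/O, validation.

An alphabet is an ordered list of structural letters, each a multivariate
Gaussian over the four fragment descriptors, together with a row-stochastic
transition matrix.  The starting distribution of the letter Markov chain is
uniform by model definition, so it is never stored.  Letter classes follow
the helix / coil / strand secondary-structure grouping, and each letter
carries both its class-based code (e.g. ``A1``, ``C15``) and the legacy
single-character code of the earlier HMM-SA nomenclature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

SL_CLASSES = ("helix", "coil", "strand")

#: class implied by the first character of a letter code (A=helix, B=strand, C=coil)
CODE_PREFIX_CLASS = {"A": "helix", "B": "strand", "C": "coil"}

ROW_SUM_TOL = 1e-9


@dataclass
class StructuralLetter:
    """One letter: a 4-D Gaussian emission plus nomenclature metadata.

    Parameters
    ----------
    code : str
        Class-based identifier, e.g. ``"A1"`` (helix), ``"B3"`` (strand),
        ``"C15"`` (coil).
    legacy_code : str
        Single-character identifier in the legacy HMM-SA nomenclature.
    sl_class : str
        One of ``"helix"``, ``"coil"``, ``"strand"``.
    frequency : float
        Training-set frequency in [0, 1]; informational only, never used in
        inference (the chain start is uniform).
    mu : ndarray, shape (4,)
        Mean descriptor vector, in angstroms.
    sigma : ndarray, shape (4, 4)
        Descriptor covariance matrix, in squared angstroms; symmetric
        positive definite.
    """

    code: str
    legacy_code: str
    sl_class: str
    frequency: float
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(4)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(4, 4)


@dataclass
class StructuralAlphabet:
    """An ordered set of structural letters with Markov transitions.

    The letter order is the file order; all matrices produced by the engine
    index letters in this order.  ``start`` is always uniform (1/m).
    """

    letters: list[StructuralLetter]
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)

    @property
    def m(self) -> int:
        return len(self.letters)

    @property
    def start(self) -> np.ndarray:
        return np.full(self.m, 1.0 / self.m)

    @property
    def codes(self) -> list[str]:
        return [sl.code for sl in self.letters]

    @property
    def classes(self) -> list[str]:
        return [sl.sl_class for sl in self.letters]

    def index_of(self, code: str) -> int:
        return self.codes.index(code)

    # cached per-letter Cholesky factors keyed by availability pattern are
    # owned by the engine, not stored here, to keep this container plain data.


class AlphabetFormatError(ValueError):
    """Raised when an alphabet file cannot be parsed."""


class AlphabetValidationError(ValueError):
    """Raised when a parsed alphabet violates model invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid alphabet:\n" + "\n".join(violations))


def validate_alphabet(a: StructuralAlphabet) -> list[str]:
    """Check all alphabet invariants; return a list of violation messages.

    Returns an empty list iff the alphabet is valid.  Reports, never raises.
    """
    out: list[str] = []
    m = a.m
    if m < 2:
        out.append(f"alphabet has {m} letters; at least 2 required")
    codes = [sl.code for sl in a.letters]
    legacy = [sl.legacy_code for sl in a.letters]
    for name, vals in (("code", codes), ("legacy_code", legacy)):
        seen = set()
        for v in vals:
            if v in seen:
                out.append(f"duplicate {name} {v!r}")
            seen.add(v)
    for sl in a.letters:
        if sl.sl_class not in SL_CLASSES:
            out.append(f"letter {sl.code}: unknown class {sl.sl_class!r}")
        if not (0.0 <= sl.frequency <= 1.0):
            out.append(f"letter {sl.code}: frequency {sl.frequency} outside [0, 1]")
        if sl.mu.shape != (4,) or not np.all(np.isfinite(sl.mu)):
            out.append(f"letter {sl.code}: mu must be a finite 4-vector")
        if sl.sigma.shape != (4, 4):
            out.append(f"letter {sl.code}: sigma must be 4x4")
            continue
        if not np.allclose(sl.sigma, sl.sigma.T, rtol=0, atol=1e-10):
            out.append(f"letter {sl.code}: sigma is not symmetric")
            continue
        try:
            np.linalg.cholesky(sl.sigma)
        except np.linalg.LinAlgError:
            out.append(f"letter {sl.code}: sigma is not positive definite")
    if a.transition.shape != (m, m):
        out.append(f"transition matrix shape {a.transition.shape} != ({m}, {m})")
    else:
        if np.any(a.transition < 0):
            rows = np.unique(np.nonzero(a.transition < 0)[0])
            for r in rows:
                out.append(f"transition row {r} ({codes[r]}): negative entries")
        sums = a.transition.sum(axis=1)
        for r in np.nonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]:
            out.append(f"transition row {r} ({codes[r]}): sums to {sums[r]:.12g}, not 1")
    return out


def _letter_from_record(rec: dict, idx: int) -> StructuralLetter:
    try:
        return StructuralLetter(
            code=str(rec["code"]),
            legacy_code=str(rec["legacy_code"]),
            sl_class=str(rec["class"]),
            frequency=float(rec["frequency"]),
            mu=np.asarray(rec["mu"], dtype=float),
            sigma=np.asarray(rec["sigma"], dtype=float),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise AlphabetFormatError(f"letter record {idx}: {exc!r}") from exc


def load_alphabet(path: str | Path) -> StructuralAlphabet:
    """Load and validate an alphabet from its native JSON format.

    The file holds ``{"letters": [...], "transition": [[...]]}``; letter
    order in memory is file order.  Raises :class:`AlphabetFormatError` on
    parse problems and :class:`AlphabetValidationError` (listing every
    violated invariant) on semantic problems.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AlphabetFormatError(f"cannot parse alphabet file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "letters" not in doc or "transition" not in doc:
        raise AlphabetFormatError(f"{path}: expected object with 'letters' and 'transition'")
    letters = [_letter_from_record(rec, i) for i, rec in enumerate(doc["letters"])]
    try:
        transition = np.asarray(doc["transition"], dtype=float)
    except (TypeError, ValueError) as exc:
        raise AlphabetFormatError(f"{path}: transition matrix: {exc}") from exc
    a = StructuralAlphabet(letters=letters, transition=transition)
    violations = validate_alphabet(a)
    if violations:
        raise AlphabetValidationError(violations)
    return a


def save_alphabet(a: StructuralAlphabet, path: str | Path) -> None:
    """Write an alphabet to the native JSON format (decimal numbers).

    ``save_alphabet`` followed by :func:`load_alphabet` reproduces every
    field bit-identically for finite decimal parameters (Python round-trips
    floats through ``repr``).
    """
    doc = {
        "letters": [
            {
                "code": sl.code,
                "legacy_code": sl.legacy_code,
                "class": sl.sl_class,
                "frequency": sl.frequency,
                "mu": sl.mu.tolist(),
                "sigma": sl.sigma.tolist(),
            }
            for sl in a.letters
        ],
        "transition": a.transition.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def legacy_code_map(a: StructuralAlphabet) -> dict[str, str]:
    """Bidirectional mapping between class-based codes and legacy characters.

    Returns a single dict containing both directions (``"A1" -> "A"`` and
    ``"A" -> "A1"``); it is a bijection over the alphabet's letters.
    """
    fwd = {sl.code: sl.legacy_code for sl in a.letters}
    rev = {sl.legacy_code: sl.code for sl in a.letters}
    if len(fwd) != a.m or len(rev) != a.m:
        raise AlphabetValidationError(["legacy_code_map: codes are not unique"])
    return {**fwd, **rev}


def alphabet_from_tables(
    records: list[dict],
    transition: np.ndarray,
) -> StructuralAlphabet:
    """Converter from tabular letter parameters to a validated alphabet.

    ``records`` is a list of dicts with keys ``code``, ``legacy_code``,
    ``class`` (optional; inferred from the code prefix when absent),
    ``frequency`` (in percent or fraction; values > 1 are divided by 100),
    ``mu`` (4 values) and ``sigma`` (4x4).  This is the single ingestion
    point for externally published parameter tables; the packaged fixture
    was produced through it.
    """
    letters = []
    for i, rec in enumerate(records):
        rec = dict(rec)
        code = str(rec["code"])
        rec.setdefault("class", CODE_PREFIX_CLASS.get(code[:1], "coil"))
        freq = float(rec["frequency"])
        rec["frequency"] = freq / 100.0 if freq > 1.0 else freq
        letters.append(_letter_from_record(rec, i))
    a = StructuralAlphabet(letters=letters, transition=np.asarray(transition, dtype=float))
    violations = validate_alphabet(a)
    if violations:
        raise AlphabetValidationError(violations)
    return a


def packaged_alphabet_path() -> Path:
    """Path of the packaged 27-letter alphabet file.

    The packaged file carries the published 27-letter nomenclature (codes,
    legacy codes, classes, training frequencies) but synthetic Gaussian and
    transition parameters, as its name indicates; load the authentic
    parameter file through :func:`load_alphabet` when available.
    """
    return Path(resources.files("saflex") / "data" / "saflex27_synthetic.json")
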