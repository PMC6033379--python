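"""Four-descriptor geometry of overlapping 4-residue backbone fragments.

Fragment ``i`` covers C-alpha atoms ``i .. i+3`` (1-based); a chain of
``n_res`` residues yields ``n_res - 3`` fragments, consecutive fragments
overlapping on three atoms.  The descriptors are

* ``X1 = |Ca_i   - Ca_i+2|``
* ``X2 = |Ca_i   - Ca_i+3|``
* ``X3 = |Ca_i+1 - Ca_i+3|``
* ``X4 = eta * |Ca_i+3 - H|`` where ``H`` is the orthogonal projection of
  ``Ca_i+3`` on the plane of the first three atoms and ``eta = +1`` iff the
  cross product (Ca_i -> Ca_i+2) x (Ca_i -> Ca_i+1) points to the same side
  of the plane as ``Ca_i+3``.

X4's sign encodes local handedness: mirror reflection flips it and nothing
else.  A descriptor is available only when every atom it requires is
present; the available subset J drives the missing-data marginalization in
the HMM engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import CAlphaTrace

logger = logging.getLogger(__name__)

#: relative positions (within the 4-atom fragment) each descriptor requires
DESCRIPTOR_ATOMS = {1: (0, 2), 2: (0, 3), 3: (1, 3), 4: (0, 1, 2, 3)}

#: cross-product norm below this fraction of the segment-length product
#: marks the p0,p1,p2 plane as degenerate (X4 unavailable)
COLLINEARITY_TOL = 1e-9


@dataclass
class FragmentSeries:
    """Descriptor values and availability for the fragments of one chain.

    Attributes
    ----------
    values : ndarray, shape (n, 4)
        Descriptor values in angstroms; NaN where unavailable.
    available : list of frozenset
        Per-fragment subset J of {1,2,3,4} of computable descriptors.
    source_labels : list
        Per-fragment tuple of the four residue labels it covers (may be
        None for series built directly in descriptor space).
    """

    values: np.ndarray
    available: list[frozenset]
    source_labels: list | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1, 4)
        self.available = [frozenset(j) for j in self.available]
        if len(self.available) != self.n:
            raise ValueError("available must have one entry per fragment")
        for i, j in enumerate(self.available):
            row = self.values[i]
            idx = [d - 1 for d in j]
            if idx and not np.all(np.isfinite(row[idx])):
                raise ValueError(f"fragment {i}: non-finite value among available descriptors")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "FragmentSeries":
        """Fully-available series from an (n, 4) descriptor array."""
        values = np.asarray(values, dtype=float).reshape(-1, 4)
        full = frozenset({1, 2, 3, 4})
        return cls(values=values, available=[full] * values.shape[0])


def missing_pattern(missing_rel_positions: set[int]) -> frozenset:
    """Available-descriptor set J given missing atoms (relative positions 0-3).

    A descriptor is in J iff all atoms it requires lie outside the missing
    set; with every atom missing, J is empty and the fragment is totally
    uninformative.
    """
    missing = set(missing_rel_positions)
    return frozenset(
        d for d, atoms in DESCRIPTOR_ATOMS.items() if not missing.intersection(atoms)
    )


def fragment_descriptors(
    p0, p1, p2, p3, present=(True, True, True, True)
) -> tuple[np.ndarray, frozenset]:
    """Descriptors of one fragment from its four C-alpha positions.

    Returns a 4-vector (NaN where unavailable) and the availability set J.
    Atoms marked absent in ``present`` propagate to J through the
    requirement table; a degenerate (collinear) base plane additionally
    drops X4 with a logged warning rather than raising.
    """
    pts = [np.asarray(p, dtype=float) if p is not None else None for p in (p0, p1, p2, p3)]
    missing = {k for k in range(4) if not present[k] or pts[k] is None}
    avail = set(missing_pattern(missing))
    x = np.full(4, np.nan)
    if 1 in avail:
        x[0] = np.linalg.norm(pts[0] - pts[2])
    if 2 in avail:
        x[1] = np.linalg.norm(pts[0] - pts[3])
    if 3 in avail:
        x[2] = np.linalg.norm(pts[1] - pts[3])
    if 4 in avail:
        u = pts[2] - pts[0]  # p0 -> p2
        v = pts[1] - pts[0]  # p0 -> p1
        normal = np.cross(u, v)
        nn = np.linalg.norm(normal)
        if nn < COLLINEARITY_TOL * max(np.linalg.norm(u) * np.linalg.norm(v), 1e-300):
            logger.warning("degenerate base plane (collinear C-alphas); X4 unavailable")
            avail.discard(4)
        else:
            w = pts[3] - pts[0]
            # signed distance of p3 from plane(p0,p1,p2); eta = sign of
            # normal . (p3 - H), and p3 - H is the normal component of w
            x[3] = float(np.dot(normal, w) / nn)
    return x, frozenset(avail)


def trace_to_fragments(t: CAlphaTrace) -> FragmentSeries:
    """Fragment series of a C-alpha trace, availability from its mask.

    The trace must span at least 4 residue positions; fragment i (1-based)
    covers positions i..i+3 and n = n_res - 3.
    """
    if t.length < 4:
        raise ValueError(f"trace has {t.length} residue positions; at least 4 required")
    n = t.length - 3
    values = np.full((n, 4), np.nan)
    available: list[frozenset] = []
    labels = []
    for i in range(n):
        window = slice(i, i + 4)
        pres = t.present[window]
        pts = [t.coords[i + k] if pres[k] else None for k in range(4)]
        x, j = fragment_descriptors(*pts, present=pres)
        values[i] = x
        available.append(j)
        labels.append(tuple(t.residue_labels[window]))
    return FragmentSeries(values=values, available=available, source_labels=labels)


def fragments_to_csv(series: FragmentSeries, path) -> None:
    """Dump a fragment series as CSV (empty cell = unavailable descriptor)."""
    import pandas as pd

    rows = []
    for i in range(series.n):
        label = None
        if series.source_labels is not None:
            label = "{}{}".format(*series.source_labels[i][0])
        j = series.available[i]
        rows.append(
            {
                "fragment_index": i + 1,
                "first_residue_label": label,
                **{
                    f"X{d}": (series.values[i, d - 1] if d in j else None)
                    for d in (1, 2, 3, 4)
                },
                "J_bitmask": sum(1 << (d - 1) for d in j),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
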