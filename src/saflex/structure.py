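"""PDB parsing into per-chain C-alpha traces with explicit missing masks.

A trace is the ordered list of residue positions of one chain, each either
carrying a C-alpha coordinate or marked missing.  Missing positions are
inferred from gaps in the author residue numbering between the first and
last observed residues, and — when the file carries SEQRES and gemmi can
align it to the observed residues — from SEQRES-declared residues outside
that span.  Selenomethionine (MSE) HETATM C-alphas count as residues;
other HETATM records are ignored.  For alternate locations the highest
occupancy wins, ties broken by altloc identifier ('A' first).

Multiple chains of one protein are aligned position-wise on the union of
their author residue labels (number + insertion code); no sequence-based
realignment is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: a residue label is (author residue number, insertion code); insertion
#: codes sort alphabetically after the unlettered position of the number
ResidueLabel = tuple[int, str]


@dataclass
class CAlphaTrace:
    """One chain's ordered C-alpha positions with a presence mask."""

    chain_id: str
    residue_labels: list[ResidueLabel]
    coords: list[np.ndarray | None]
    present: np.ndarray

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if not (len(self.residue_labels) == len(self.coords) == self.present.size):
            raise ValueError("residue_labels, coords and present must have equal length")
        labels = self.residue_labels
        if any(labels[i] >= labels[i + 1] for i in range(len(labels) - 1)):
            raise ValueError("residue_labels must be strictly increasing")
        for i, ok in enumerate(self.present):
            if ok != (self.coords[i] is not None):
                raise ValueError(f"position {i}: coords defined iff present")

    @property
    def length(self) -> int:
        return len(self.residue_labels)

    @property
    def n_missing(self) -> int:
        return int((~self.present).sum())

    def coord_array(self) -> np.ndarray:
        """(length, 3) array with NaN rows at missing positions."""
        out = np.full((self.length, 3), np.nan)
        for i, c in enumerate(self.coords):
            if c is not None:
                out[i] = c
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        xyz = self.coord_array()
        pd.DataFrame(
            {
                "chain": self.chain_id,
                "residue_number": [num for num, _ in self.residue_labels],
                "insertion_code": [ic for _, ic in self.residue_labels],
                "present": self.present,
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
            }
        ).to_csv(path, index=False)


@dataclass
class ChainAlignment:
    """Label-based alignment of several chains onto a common reference index.

    ``per_chain_map[c][r]`` is the position in chain ``c``'s trace serving
    reference position ``r``, or None when that chain has no such label.
    """

    reference_labels: list[ResidueLabel]
    per_chain_map: list[list[int | None]]

    @property
    def n_ref(self) -> int:
        return len(self.reference_labels)


class ChainNotFoundError(KeyError):
    pass


def _pick_calpha(residue: gemmi.Residue) -> np.ndarray | None:
    """C-alpha coordinate of a residue under the altloc rule, or None."""
    candidates = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
    if not candidates:
        return None
    best = min(candidates, key=lambda a: (-a.occ, a.altloc or "A"))
    return np.array([best.pos.x, best.pos.y, best.pos.z])


def _is_amino(residue: gemmi.Residue) -> bool:
    if residue.het_flag == "A":
        return True
    # MSE is routinely deposited as HETATM but is a backbone residue
    return residue.name == "MSE"


def read_calpha_trace(path: str | Path, chain: str, model: int | None = None) -> CAlphaTrace:
    """Read one chain of a PDB (or mmCIF) file as a C-alpha trace.

    ``model`` is a 0-based model index; by default the first model is used
    (multi-conformation NMR ensembles are not modelled).  Raises
    :class:`ChainNotFoundError` listing the available chains when ``chain``
    is absent.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    mdl = st[model if model is not None else 0]
    names = [ch.name for ch in mdl]
    if chain not in names:
        raise ChainNotFoundError(f"chain {chain!r} not in {path.name}; available: {', '.join(names)}")
    ch = mdl[chain]

    observed: dict[ResidueLabel, np.ndarray | None] = {}
    for res in ch:
        if not _is_amino(res):
            continue
        label = (res.seqid.num, res.seqid.icode.strip())
        ca = _pick_calpha(res)
        if label in observed and observed[label] is not None:
            continue  # first occurrence wins among duplicated labels
        observed[label] = ca

    if not observed:
        raise ValueError(f"{path.name} chain {chain}: no amino-acid residues")

    labels = sorted(observed)
    first_num, last_num = labels[0][0], labels[-1][0]
    seen_nums = {num for num, _ in labels}
    # numbering-gap inference inside the observed span
    grid = set(labels)
    for num in range(first_num, last_num + 1):
        if num not in seen_nums:
            grid.add((num, ""))

    # SEQRES extension outside the span, via gemmi's label_seq alignment
    n_lead, n_trail = _seqres_overhang(st, mdl, chain, labels)
    for j in range(1, n_lead + 1):
        grid.add((first_num - j, ""))
    for j in range(1, n_trail + 1):
        grid.add((last_num + j, ""))

    full = sorted(grid)
    coords = [observed.get(lab) for lab in full]
    present = np.array([c is not None for c in coords])
    logger.info(
        "%s chain %s: %d positions (%d observed, %d missing)",
        path.name, chain, len(full), int(present.sum()), int((~present).sum()),
    )
    return CAlphaTrace(chain_id=chain, residue_labels=full, coords=coords, present=present)


def _seqres_overhang(st, mdl, chain: str, labels) -> tuple[int, int]:
    """Missing-residue counts before/after the observed span, from SEQRES.

    Uses gemmi's alignment of the full (SEQRES) sequence to the observed
    residues; returns (0, 0) when SEQRES is absent or alignment fails.
    """
    try:
        st.setup_entities()
        st.assign_label_seq_id()
        ch = mdl[chain]
        residues = [r for r in ch if _is_amino(r)]
        ent = st.get_entity_of(ch.subchains()[0]) if ch.subchains() else None
        if ent is None or not ent.full_sequence:
            return 0, 0
        seq_len = len(ent.full_sequence)
        lseq = [r.label_seq for r in residues if r.label_seq is not None]
        if not lseq:
            return 0, 0
        return max(min(lseq) - 1, 0), max(seq_len - max(lseq), 0)
    except Exception:  # alignment is best-effort; span inference still applies
        logger.info("chain %s: SEQRES alignment unavailable", chain)
        return 0, 0


def align_chains(traces: list[CAlphaTrace]) -> ChainAlignment:
    """Align chains position-wise on the union of their residue labels.

    A reference position is informative for a chain iff that chain has a
    present C-alpha there.  Chains sharing no labels with the others cannot
    form a homomer alignment and raise ValueError.  The result is invariant
    to input order up to relabeling.
    """
    if not traces:
        raise ValueError("need at least one trace")
    label_sets = [set(t.residue_labels) for t in traces]
    if len(traces) > 1:
        for i, s in enumerate(label_sets):
            others = set().union(*(label_sets[:i] + label_sets[i + 1:]))
            if not s & others:
                raise ValueError(
                    f"chain {traces[i].chain_id!r}: residue labels disjoint from all "
                    "other chains; cannot form a homomer alignment"
                )
    reference = sorted(set().union(*label_sets))
    per_chain = []
    for t in traces:
        pos = {lab: i for i, lab in enumerate(t.residue_labels)}
        per_chain.append([pos.get(lab) for lab in reference])
    return ChainAlignment(reference_labels=reference, per_chain_map=per_chain)


def trace_on_reference(t: CAlphaTrace, alignment: ChainAlignment, chain_index: int) -> CAlphaTrace:
    """Re-index a trace onto an alignment's reference labels.

    Reference positions the chain lacks become missing positions, so all
    chains of a homomer share one index and one fragment count.
    """
    mapping = alignment.per_chain_map[chain_index]
    coords: list[np.ndarray | None] = []
    for idx in mapping:
        if idx is None or not t.present[idx]:
            coords.append(None)
        else:
            coords.append(t.coords[idx])
    present = np.array([c is not None for c in coords])
    return CAlphaTrace(
        chain_id=t.chain_id,
        residue_labels=list(alignment.reference_labels),
        coords=coords,
        present=present,
    )


def write_calpha_pdb(traces: list[CAlphaTrace] | CAlphaTrace, path: str | Path) -> None:
    """Write traces as a minimal PDB file (CA atoms of present positions).

    Used for fixtures and round-trip tests; coordinates keep the format's
    3-decimal precision.
    """
    if isinstance(traces, CAlphaTrace):
        traces = [traces]
    lines = []
    serial = 1
    for t in traces:
        for (num, icode), coord, ok in zip(t.residue_labels, t.coords, t.present):
            if not ok:
                continue
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {t.chain_id:1s}{num:4d}{icode or ' ':1s}   "
                f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
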