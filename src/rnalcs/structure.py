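"""Reading RNA 3D structures from PDB/mmCIF into an ordered residue/atom model.

Parsing is delegated to gemmi, which auto-detects the coordinate format
(including gzipped files).  Only the first coordinate model is kept;
hydrogens, waters, ions, ligands and amino acids are discarded.  A residue
counts as a nucleotide if it carries the ribose core atoms C1', C4' and O4' —
this keeps modified nucleotides that follow standard atom naming without
requiring a chemical-component dictionary.

Residue identity is the triple (chain id, author sequence number, insertion
code), and residues keep their file order, which is taken as 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import gemmi

__all__ = [
    "Residue",
    "ResidueChain",
    "StructureModel",
    "StructureError",
    "EmptyStructureError",
    "ChainSelectionError",
    "read_structure",
    "select_chain",
    "detect_chain_breaks",
    "DEFAULT_BREAK_CUTOFF",
]

#: O3'(i)-P(i+1) distance (Angstrom) above which the backbone is considered
#: broken.  The covalent phosphodiester P-O3' bond is ~1.6 A, so 2.5 A is a
#: generous margin for poorly refined linkages.
DEFAULT_BREAK_CUTOFF = 2.5

# Atoms that must be present for a residue to count as a nucleotide.
_RIBOSE_CORE = ("C1'", "C4'", "O4'")

_PURINES = {"A", "G", "DA", "DG", "I"}
_PYRIMIDINES = {"C", "U", "T", "DC", "DT", "DU"}


class StructureError(Exception):
    """Problem reading or interpreting a structure file."""


class EmptyStructureError(StructureError):
    """No nucleotide residues remain after filtering."""


class ChainSelectionError(StructureError):
    """Requested chain missing, or chain choice ambiguous."""


@dataclass
class Residue:
    """One nucleotide: identity plus named heavy-atom coordinates (Angstrom)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    residue_name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def label(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.seq_number, self.insertion_code, self.residue_name)

    def atom(self, name: str) -> np.ndarray | None:
        return self.atoms.get(name)

    def is_purine(self) -> bool:
        if self.residue_name in _PURINES:
            return True
        if self.residue_name in _PYRIMIDINES:
            return False
        # modified residue: decide from the glycosidic nitrogen present
        return "N9" in self.atoms

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        icode = self.insertion_code.strip()
        return f"<Residue {self.residue_name} {self.chain_id}{self.seq_number}{icode}>"


@dataclass
class ResidueChain:
    """An ordered (5'->3') run of nucleotides from one chain.

    ``break_flags[i]`` is True when the backbone between residues i and i+1
    is broken; it has length ``len(residues) - 1`` once
    :func:`detect_chain_breaks` has run (empty list means "not yet analysed"
    for chains of length > 1).
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    break_flags: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass
class StructureModel:
    """A parsed coordinate file: ordered nucleotide chains."""

    identifier: str
    chains: list[ResidueChain] = field(default_factory=list)
    source_format: str = "PDB"

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


def _best_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    """Highest-occupancy conformer; ties broken by file order."""
    best = None
    for at in atoms:
        if best is None or at.occ > best.occ:
            best = at
    return best


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue | None:
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in res:
        if at.is_hydrogen():
            continue
        by_name.setdefault(at.name, []).append(at)
    if not all(n in by_name for n in _RIBOSE_CORE):
        return None
    atoms = {}
    for name, alts in by_name.items():
        at = _best_altloc(alts)
        atoms[name] = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
    return Residue(
        chain_id=chain_id,
        seq_number=res.seqid.num,
        insertion_code=(res.seqid.icode or " "),
        residue_name=res.name.strip(),
        atoms=atoms,
    )


_FORMAT_MAP = {
    "PDB": gemmi.CoorFormat.Pdb,
    "mmCIF": gemmi.CoorFormat.Mmcif,
}


def read_structure(path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file (optionally gzipped) into a StructureModel.

    Parameters
    ----------
    path:
        Coordinate file.  Format is detected from contents/extension unless
        ``format`` is explicitly ``"PDB"`` or ``"mmCIF"``.

    Only the first coordinate model is used.  Raises
    :class:`EmptyStructureError` when nothing nucleotide-like survives
    filtering and :class:`StructureError` on parse failures.
    """
    path = str(path)
    try:
        if format == "auto":
            st = gemmi.read_structure(path)
        else:
            try:
                fmt = _FORMAT_MAP[format]
            except KeyError:
                raise StructureError(f"unknown format {format!r}; use PDB, mmCIF or auto")
            st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate model found")
    model = st[0]

    src = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    out = StructureModel(identifier=st.name or path, source_format=src)
    for ch in model:
        rchain = ResidueChain(chain_id=ch.name)
        for res in ch:
            conv = _convert_residue(ch.name, res)
            if conv is not None:
                rchain.residues.append(conv)
        if rchain.residues:
            out.chains.append(rchain)
    if not out.chains:
        raise EmptyStructureError(f"{path}: no nucleotide residues after filtering")
    return out


def select_chain(s: StructureModel, chain_id: str | None = None) -> ResidueChain:
    """Pick one chain; unambiguous only when named or when a single chain exists."""
    if chain_id is not None:
        for c in s.chains:
            if c.chain_id == chain_id:
                return c
        raise ChainSelectionError(
            f"chain {chain_id!r} not found in {s.identifier}; available: {s.chain_ids()}"
        )
    if len(s.chains) == 1:
        return s.chains[0]
    raise ChainSelectionError(
        f"{s.identifier} has {len(s.chains)} chains {s.chain_ids()}; specify one"
    )


def detect_chain_breaks(
    c: ResidueChain, cutoff: float = DEFAULT_BREAK_CUTOFF
) -> ResidueChain:
    """Fill ``break_flags`` from O3'(i)-P(i+1) distances (in place; returns c).

    A missing O3' or P implies a break: continuity cannot be asserted, and the
    torsions spanning the junction would be undefined anyway.
    """
    flags = []
    for r1, r2 in zip(c.residues, c.residues[1:]):
        o3 = r1.atom("O3'")
        p = r2.atom("P")
        if o3 is None or p is None:
            flags.append(True)
        else:
            flags.append(bool(np.linalg.norm(o3 - p) > cutoff))
    c.break_flags = flags
    return c
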