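"""Protein model parsing and atom/residue classification.

Models arrive as standard PDB files (one chain of a CASP-style model).
Parsing is delegated to Bio.PDB; the result is flattened into light
dataclasses carrying only what feature extraction needs: heavy-atom
coordinates, a residue-level sequence, and two fixed classifications:

* a 6-group partition of the 20 amino acids used for residue-residue
  contact and exposure histograms:
  (1) Arg, Lys; (2) Asp, Glu; (3) His, Phe, Trp, Tyr;
  (4) Asn, Gln, Ser, Thr; (5) Ala, Ile, Leu, Met, Val, Cys; (6) Gly, Pro.

* a 13-class partition of heavy atoms by chemical character, used for
  atom-atom contact histograms.  The table below is the single source
  of truth:

  ====  =======================================================
  class  members
  ====  =======================================================
  1      backbone amide N
  2      CA
  3      backbone carbonyl C
  4      backbone carbonyl O (incl. OXT)
  5      CB
  6      aliphatic side-chain C (sp3 beyond CB)
  7      aromatic ring C (His/Phe/Trp/Tyr)
  8      polar sp2 side-chain C (carboxylate, amide, guanidinium)
  9      side-chain amine/amide/guanidinium N (Lys NZ, Arg, Asn, Gln)
  10     ring N (His ND1/NE2, Trp NE1)
  11     hydroxyl O (Ser OG, Thr OG1, Tyr OH)
  12     carboxylate/amide O (Asp, Glu, Asn, Gln side-chain O)
  13     S (Cys SG, Met SD)
  ====  =======================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "Residue",
    "ProteinModel",
    "PDBFormatError",
    "ClassificationError",
    "read_pdb",
    "write_pdb",
    "assign_residue_group",
    "assign_atom_class",
    "HEAVY_ATOMS",
    "N_ATOM_CLASSES",
    "N_RESIDUE_GROUPS",
]

N_ATOM_CLASSES = 13
N_RESIDUE_GROUPS = 6

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class PDBFormatError(ValueError):
    """Raised for malformed or empty PDB input."""


class ClassificationError(KeyError):
    """Raised when an amino acid or atom name cannot be classified."""


# 6-group residue partition
_RESIDUE_GROUP = {
    "R": 1, "K": 1,
    "D": 2, "E": 2,
    "H": 3, "F": 3, "W": 3, "Y": 3,
    "N": 4, "Q": 4, "S": 4, "T": 4,
    "A": 5, "I": 5, "L": 5, "M": 5, "V": 5, "C": 5,
    "G": 6, "P": 6,
}


def assign_residue_group(aa: str) -> int:
    """Map a one-letter amino-acid code to its contact group (1-6)."""
    try:
        return _RESIDUE_GROUP[aa.upper()]
    except KeyError:
        raise ClassificationError(f"no residue group for amino acid {aa!r}")


# Heavy atoms of the 20 standard residues (PDB v3 names), side chains only;
# every residue additionally has the backbone set N/CA/C/O (+OXT at C-term).
_SIDECHAIN_ATOMS = {
    "A": ["CB"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "N": ["CB", "CG", "OD1", "ND2"],
    "D": ["CB", "CG", "OD1", "OD2"],
    "C": ["CB", "SG"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"],
    "G": [],
    "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["CB", "CG1", "CG2", "CD1"],
    "L": ["CB", "CG", "CD1", "CD2"],
    "K": ["CB", "CG", "CD", "CE", "NZ"],
    "M": ["CB", "CG", "SD", "CE"],
    "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "P": ["CB", "CG", "CD"],
    "S": ["CB", "OG"],
    "T": ["CB", "OG1", "CG2"],
    "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "V": ["CB", "CG1", "CG2"],
}

HEAVY_ATOMS = {
    aa: ["N", "CA", "C", "O"] + sc for aa, sc in _SIDECHAIN_ATOMS.items()
}

# Atom-class table (see module docstring).  Backbone handled generically.
_BACKBONE_CLASS = {"N": 1, "CA": 2, "C": 3, "O": 4, "OXT": 4}

_POLAR_SP2_C = {  # carboxylate / amide / guanidinium carbons
    ("D", "CG"), ("E", "CD"), ("N", "CG"), ("Q", "CD"), ("R", "CZ"),
}
_AROMATIC_RES = {"H", "F", "W", "Y"}
_SIDECHAIN_CLASS_OVERRIDES = {
    ("K", "NZ"): 9,
    ("R", "NE"): 9, ("R", "NH1"): 9, ("R", "NH2"): 9,
    ("N", "ND2"): 9, ("Q", "NE2"): 9,
    ("H", "ND1"): 10, ("H", "NE2"): 10, ("W", "NE1"): 10,
    ("S", "OG"): 11, ("T", "OG1"): 11, ("Y", "OH"): 11,
    ("D", "OD1"): 12, ("D", "OD2"): 12, ("E", "OE1"): 12, ("E", "OE2"): 12,
    ("N", "OD1"): 12, ("Q", "OE1"): 12,
    ("C", "SG"): 13, ("M", "SD"): 13,
}


def assign_atom_class(residue_aa: str, atom_name: str) -> int:
    """Classify a heavy atom of a standard residue into one of 13 types.

    Backbone atoms are classed identically regardless of residue type.
    """
    aa = residue_aa.upper()
    name = atom_name.upper()
    if name in _BACKBONE_CLASS:
        return _BACKBONE_CLASS[name]
    if aa not in _SIDECHAIN_ATOMS:
        raise ClassificationError(f"unknown residue {residue_aa!r}")
    if name not in _SIDECHAIN_ATOMS[aa]:
        raise ClassificationError(f"unknown atom {atom_name!r} in residue {residue_aa!r}")
    key = (aa, name)
    if key in _SIDECHAIN_CLASS_OVERRIDES:
        return _SIDECHAIN_CLASS_OVERRIDES[key]
    if key in _POLAR_SP2_C:
        return 8
    if name == "CB":
        return 5
    # remaining side-chain carbons: aromatic ring vs aliphatic
    if aa in _AROMATIC_RES and name != "CB":
        return 7
    return 6


@dataclass
class Atom:
    """A heavy atom with its 13-type contact class."""

    name: str
    element: str
    residue_index: int
    coords: np.ndarray
    atom_class: int
    is_sidechain: bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 1 <= self.atom_class <= N_ATOM_CLASSES:
            raise ValueError(f"atom class {self.atom_class} out of range 1-13")


@dataclass
class Residue:
    """One modeled residue: amino acid, contact group, and its atoms."""

    aa: str
    residue_index: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        self.group = assign_residue_group(self.aa)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class ProteinModel:
    """A parsed model: ordered residues mapped onto the target sequence.

    ``target_length`` may exceed ``len(residues)`` for partial models;
    ``residues[i].residue_index`` is the 0-based target position of the
    i-th modeled residue.
    """

    model_id: str
    residues: list[Residue]
    target_length: int | None = None

    def __post_init__(self):
        if self.target_length is None:
            self.target_length = (
                self.residues[-1].residue_index + 1 if self.residues else 0
            )
        idx = [r.residue_index for r in self.residues]
        if idx != sorted(idx):
            raise ValueError("residues must be ordered by target position")
        if self.target_length < len(self.residues):
            raise ValueError("target_length smaller than number of modeled residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self) -> np.ndarray:
        """All heavy-atom coordinates, (n_atoms, 3)."""
        return np.array([a.coords for r in self.residues for a in r.atoms])

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates for residues that have one, (n, 3), with indices."""
        return np.array([r.ca.coords for r in self.residues if r.ca is not None])

    def translated(self, shift) -> "ProteinModel":
        return self.transformed(np.eye(3), np.asarray(shift, float))

    def transformed(self, rotation, translation) -> "ProteinModel":
        """Rigid-body copy: x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_res = []
        for r in self.residues:
            atoms = [
                Atom(a.name, a.element, a.residue_index, R @ a.coords + t,
                     a.atom_class, a.is_sidechain)
                for a in r.atoms
            ]
            new_res.append(Residue(r.aa, r.residue_index, atoms))
        return ProteinModel(self.model_id, new_res, self.target_length)


def _three_to_one(resname: str) -> str | None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        code = seq1(resname.capitalize())
    return code if code != "X" else None


def read_pdb(
    path,
    model_id: str | None = None,
    target_length: int | None = None,
    target_alignment: dict | None = None,
    chain: str | None = None,
) -> ProteinModel:
    """Parse a PDB file into a :class:`ProteinModel`.

    Heteroatoms and hydrogens are dropped; alternate locations resolve to
    the highest-occupancy conformer (Bio.PDB default).  By default the
    first chain is used.  Residue indices come from ``target_alignment``
    (author residue number -> 0-based target position) when given, else
    sequentially from 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(model_id or path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises on malformed records
        raise PDBFormatError(f"{path}: {exc}") from exc
    try:
        bio_model = next(structure.get_models())
    except StopIteration:
        raise PDBFormatError(f"{path}: no ATOM records")
    chains = list(bio_model.get_chains())
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise PDBFormatError(f"{path}: chain {chain!r} not found")
    bio_chain = chains[0]

    residues: list[Residue] = []
    seq_pos = 0
    for res in bio_chain.get_residues():
        if not is_aa(res, standard=True):
            continue
        aa = _three_to_one(res.get_resname())
        if aa is None:
            continue
        if target_alignment is not None:
            key = res.get_id()[1]
            if key not in target_alignment:
                continue
            ridx = target_alignment[key]
        else:
            ridx = seq_pos
        atoms = []
        for at in res.get_atoms():
            # disordered atoms already resolved to highest occupancy child
            name = at.get_name()
            if at.element == "H" or name.startswith("H"):
                continue
            try:
                cls = assign_atom_class(aa, name)
            except ClassificationError:
                continue  # nonstandard adducts are skipped, not fatal
            atoms.append(
                Atom(name, at.element or name[0], ridx, at.get_coord(),
                     cls, name not in BACKBONE_NAMES)
            )
        if atoms:
            residues.append(Residue(aa, ridx, atoms))
            seq_pos += 1
    if not residues:
        raise PDBFormatError(f"{path}: zero standard residues parsed")
    residues.sort(key=lambda r: r.residue_index)
    return ProteinModel(model_id or path.stem, residues, target_length)


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_pdb(model: ProteinModel, path) -> None:
    """Write a model as a single-chain PDB file (1-based residue numbers)."""
    lines = []
    serial = 1
    for res in model.residues:
        res3 = _ONE_TO_THREE[res.aa]
        for a in res.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res3} A{res.residue_index + 1:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
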