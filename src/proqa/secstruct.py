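"""Three-state secondary-structure assignment from model coordinates.

The internal assigner is dihedral-based: backbone phi/psi torsions place
each residue in the helical or extended region of the Ramachandran map,
and runs shorter than a minimum length (4 for helix, 3 for strand) decay
to coil.  Termini, lacking one torsion, default to coil.  Readers for
STRIDE (-f) and DSSP output files are provided for users who prefer an
external assignment; their one-letter codes map {H,G,I}->H, {E,B,b}->E,
everything else ->C.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .structure_io import ProteinModel

__all__ = [
    "assign_secondary_structure",
    "dihedral",
    "read_stride",
    "read_dssp",
    "map_ss_code",
]

MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    return float(((ang + 180.0) % 360.0) - 180.0)


def _phi_psi(model: ProteinModel):
    """Per-residue (phi, psi) in degrees; NaN where undefined."""
    n = len(model.residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    bb = []
    for r in model.residues:
        bb.append({nm: (r.atom(nm).coords if r.atom(nm) else None)
                   for nm in ("N", "CA", "C")})
    for i in range(n):
        cur = bb[i]
        if any(cur[k] is None for k in ("N", "CA", "C")):
            continue
        if i > 0 and bb[i - 1]["C"] is not None and \
                model.residues[i].residue_index - model.residues[i - 1].residue_index == 1:
            phi[i] = dihedral(bb[i - 1]["C"], cur["N"], cur["CA"], cur["C"])
        if i < n - 1 and bb[i + 1]["N"] is not None and \
                model.residues[i + 1].residue_index - model.residues[i].residue_index == 1:
            psi[i] = dihedral(cur["N"], cur["CA"], cur["C"], bb[i + 1]["N"])
    return phi, psi


def _in_helix_region(phi, psi):
    return -100.0 <= phi <= -30.0 and -80.0 <= psi <= -4.0


def _in_strand_region(phi, psi):
    return -180.0 <= phi <= -45.0 and (psi >= 90.0 or psi <= -150.0)


def assign_secondary_structure(model: ProteinModel) -> str:
    """Assign H/E/C per modeled residue from backbone dihedrals."""
    phi, psi = _phi_psi(model)
    n = len(model.residues)
    raw = []
    for i in range(n):
        if np.isnan(phi[i]) or np.isnan(psi[i]):
            raw.append("C")
        elif _in_helix_region(phi[i], psi[i]):
            raw.append("H")
        elif _in_strand_region(phi[i], psi[i]):
            raw.append("E")
        else:
            raw.append("C")
    # suppress runs below the minimum length
    out = list(raw)
    i = 0
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        run = j - i
        if raw[i] == "H" and run < MIN_HELIX_RUN:
            out[i:j] = ["C"] * run
        elif raw[i] == "E" and run < MIN_STRAND_RUN:
            out[i:j] = ["C"] * run
        i = j
    return "".join(out)


def map_ss_code(code: str) -> str:
    """Collapse a STRIDE/DSSP one-letter code to H/E/C."""
    c = code.upper()
    if c in ("H", "G", "I"):
        return "H"
    if c in ("E", "B"):
        return "E"
    return "C"


def read_stride(path) -> str:
    """Read a STRIDE -f output file; returns the H/E/C string (ASG lines)."""
    classes = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("ASG"):
            parts = line.split()
            classes.append(map_ss_code(parts[5]))
    if not classes:
        raise ValueError(f"{path}: no ASG records found")
    return "".join(classes)


def read_dssp(path) -> str:
    """Read a classic DSSP file; returns the H/E/C string."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise ValueError(f"{path}: DSSP header not found")
    classes = []
    for ln in lines[start + 1:]:
        if len(ln) < 17 or ln[13] == "!":
            continue
        classes.append(map_ss_code(ln[16]))
    if not classes:
        raise ValueError(f"{path}: no residue records")
    return "".join(classes)
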