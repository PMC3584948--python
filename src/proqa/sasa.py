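"""Solvent-accessible surface area by the Shrake-Rupley method.

Numerical SASA with a rolling probe of 1.4 Angstrom: each heavy atom is
covered with quasi-uniform test points on its solvent-expanded sphere
(golden-spiral layout, 960 points by default) and the accessible area is
the fraction of points not buried inside any neighbour's expanded sphere.

Per-residue relative side-chain exposure divides the side-chain SASA by a
residue-type maximum reference area (Miller et al. Gly-X-Gly side-chain
values; glycine, having no side chain, uses its backbone-inclusive total
area).  The table is module-level data and can be swapped.
"""

from __future__ import annotations

import numpy as np

from .structure_io import ProteinModel

__all__ = ["shrake_rupley", "compute_sasa", "VDW_RADII", "MAX_SIDECHAIN_AREA"]

PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# Maximum observed side-chain ASA (Angstrom^2) in extended Gly-X-Gly
# tripeptides; Gly entry is the total residue area.
MAX_SIDECHAIN_AREA = {
    "A": 67.0, "R": 196.0, "N": 113.0, "D": 106.0, "C": 104.0,
    "Q": 144.0, "E": 138.0, "G": 85.0, "H": 151.0, "I": 140.0,
    "L": 137.0, "K": 167.0, "M": 160.0, "F": 175.0, "P": 105.0,
    "S": 80.0, "T": 102.0, "W": 217.0, "Y": 187.0, "V": 117.0,
}


def _sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (Angstrom^2) for atoms at ``coords`` with ``radii``."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = len(coords)
    sphere = _sphere_points(n_points)
    expanded = radii + probe
    out = np.empty(n)
    # neighbour lists from one pairwise distance matrix; models here are
    # small enough (<1e4 atoms) that this is the fast path
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    cut2 = (expanded[:, None] + expanded[None, :]) ** 2
    for i in range(n):
        neigh = np.where((d2[i] < cut2[i]) & (np.arange(n) != i))[0]
        pts = coords[i] + expanded[i] * sphere
        if len(neigh):
            dd = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(-1)
            free = np.all(dd > expanded[neigh] ** 2, axis=1)
            frac = free.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return out


def compute_sasa(
    model: ProteinModel,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Relative side-chain exposure per modeled residue, clipped to [0, 1].

    Glycine (and any residue whose side chain is absent from the model)
    falls back to the backbone-inclusive area against the total reference.
    A residue with no occluding neighbours saturates at 1.
    """
    atoms = [a for r in model.residues for a in r.atoms]
    coords = np.array([a.coords for a in atoms])
    radii = np.array([VDW_RADII.get(a.element.upper(), 1.70) for a in atoms])
    areas = shrake_rupley(coords, radii, probe=probe, n_points=n_points)

    rel = np.zeros(len(model.residues))
    k = 0
    for i, res in enumerate(model.residues):
        n_at = len(res.atoms)
        res_areas = areas[k:k + n_at]
        side = np.array([a.is_sidechain for a in res.atoms])
        if res.aa == "G" or not side.any():
            used = np.ones(n_at, bool)
        else:
            used = side
        area = res_areas[used].sum()
        # tabulated maximum, capped by the isolated-sphere area of the
        # atoms actually present so partial side chains (e.g. CB-only
        # models) still saturate at 1 when unoccluded
        iso = sum(
            4.0 * np.pi * (VDW_RADII.get(a.element.upper(), 1.70) + probe) ** 2
            for a, u in zip(res.atoms, used) if u
        )
        ref = min(MAX_SIDECHAIN_AREA[res.aa], iso)
        rel[i] = min(area / ref, 1.0)
        k += n_at
    return rel
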