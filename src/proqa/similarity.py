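"""Structural similarity scoring between a model and a reference.

The per-residue correctness measure is the S-score

    S_i = 1 / (1 + (d_i / d0)^2),      d0 = 3 Angstrom by default,

where d_i is the Calpha deviation of residue i under the rigid-body
superposition that maximizes the sum of S_i over the whole model.  That
superposition is found with a MaxSub-style seed-and-extend search: every
contiguous 7-residue window seeds a Kabsch fit, well-fitting residues are
iteratively re-included, and the best-scoring superposition wins.  An
all-residue Kabsch fit is always included among the candidates, so the
result never scores below a plain least-squares superposition.

GDT_TS is computed with the same heuristic: for each distance threshold
in {1, 2, 4, 8} Angstrom the maximal fraction of Calpha atoms within the
threshold is sought, and the four fractions are averaged (reported x100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ProteinModel

__all__ = [
    "Superposition",
    "LocalQuality",
    "s_score",
    "s_to_distance",
    "kabsch",
    "optimal_s_superposition",
    "gdt_ts",
    "DEFAULT_D0",
]

DEFAULT_D0 = 3.0
SEED_LENGTH = 7
EXTENSION_FACTOR = 3.5  # inclusion threshold = EXTENSION_FACTOR * d0
MAX_EXTENSION_ITERATIONS = 10
GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)


class SuperpositionError(ValueError):
    """Raised when a least-squares superposition cannot be computed."""


@dataclass
class Superposition:
    """Rigid transform x -> R x + t fit on ``matched`` residue indices."""

    rotation: np.ndarray
    translation: np.ndarray
    matched: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class LocalQuality:
    """Per-target-position S-scores and Calpha deviations.

    Positions not modeled carry s = 0 and d = inf.
    """

    s: np.ndarray
    d: np.ndarray

    @property
    def total(self) -> float:
        return float(self.s.sum())


def s_score(d, d0: float = DEFAULT_D0):
    """S-score of a deviation d: 1 / (1 + (d/d0)^2); 1 at d=0, 0.5 at d=d0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    out = 1.0 / (1.0 + (d / d0) ** 2)
    return float(out) if out.ndim == 0 else out


def s_to_distance(s, d0: float = DEFAULT_D0):
    """Deviation corresponding to an S-score: d = d0 * sqrt(1/s - 1)."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("s must lie in (0, 1]")
    out = d0 * np.sqrt(1.0 / s - 1.0)
    return float(out) if out.ndim == 0 else out


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Proper rotation enforced (det = +1).  Requires >= 3 non-degenerate
    point pairs.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("coordinate sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 matched pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:  # rank < 2: collinear points, rotation ill-defined
        raise SuperpositionError("degenerate (collinear) point set")
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return Superposition(R, t, np.arange(n))


def _paired_ca(model: ProteinModel, native: ProteinModel):
    """Calpha pairs at common target positions: (positions, model xyz, native xyz)."""
    nat = {r.residue_index: r.ca.coords for r in native.residues if r.ca is not None}
    pos, mc, nc = [], [], []
    for r in model.residues:
        if r.ca is not None and r.residue_index in nat:
            pos.append(r.residue_index)
            mc.append(r.ca.coords)
            nc.append(nat[r.residue_index])
    return np.array(pos, dtype=int), np.array(mc, float), np.array(nc, float)


def _extend(mob, ref, seed_mask, include_dist, score_dist=None):
    """Seed-and-extend one seed: returns (superposition, distances) or None.

    Iteratively refit on residues within ``include_dist`` until the inlier
    set is stable (or the iteration cap is hit).
    """
    mask = seed_mask.copy()
    sup = None
    for _ in range(MAX_EXTENSION_ITERATIONS):
        if mask.sum() < 3:
            return None
        try:
            sup = kabsch(mob[mask], ref[mask])
        except SuperpositionError:
            return None
        d = np.linalg.norm(sup.apply(mob) - ref, axis=1)
        new_mask = d <= include_dist
        if new_mask.sum() < 3 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    if sup is None:
        return None
    d = np.linalg.norm(sup.apply(mob) - ref, axis=1)
    return sup, d


def _seed_masks(n: int, seed_len: int):
    seed_len = min(seed_len, n)
    for start in range(0, n - seed_len + 1):
        mask = np.zeros(n, bool)
        mask[start:start + seed_len] = True
        yield mask


def optimal_s_superposition(
    model: ProteinModel,
    native: ProteinModel,
    d0: float = DEFAULT_D0,
) -> tuple[Superposition, LocalQuality]:
    """Superposition maximizing the model's total S-score, MaxSub style.

    Falls back to a plain all-residue Kabsch fit when fewer than 7
    residues are matched.  The returned :class:`LocalQuality` spans the
    full target length; unmodeled positions get s = 0, d = inf.
    """
    pos, mob, ref = _paired_ca(model, native)
    n = len(pos)
    if n == 0:
        raise SuperpositionError("no matched residues between model and native")
    if n < 3:
        raise SuperpositionError("need at least 3 matched residues")

    # seed-and-extend at several inclusion thresholds: the tight ones lock
    # onto well-modeled cores, the wide one tolerates moderate global error
    include_dists = (d0, 2.0 * d0, EXTENSION_FACTOR * d0)
    best_sup, best_d, best_score = None, None, -1.0

    candidates = []
    try:
        sup_all = kabsch(mob, ref)
        d_all = np.linalg.norm(sup_all.apply(mob) - ref, axis=1)
        candidates.append((sup_all, d_all))
    except SuperpositionError:
        pass
    for include_dist in include_dists:
        full = _extend(mob, ref, np.ones(n, bool), include_dist)
        if full is not None:
            candidates.append(full)
        if n >= SEED_LENGTH:
            for mask in _seed_masks(n, SEED_LENGTH):
                res = _extend(mob, ref, mask, include_dist)
                if res is not None:
                    candidates.append(res)
    if not candidates:
        raise SuperpositionError("no valid superposition found")

    for sup, d in candidates:
        score = s_score(d, d0).sum()
        if score > best_score:
            best_sup, best_d, best_score = sup, d, score

    L = max(model.target_length, native.target_length, int(pos.max()) + 1)
    s_full = np.zeros(L)
    d_full = np.full(L, np.inf)
    s_full[pos] = s_score(best_d, d0)
    d_full[pos] = best_d
    best_sup.matched = pos
    return best_sup, LocalQuality(s_full, d_full)


def gdt_ts(model: ProteinModel, native: ProteinModel) -> float:
    """GDT_TS in [0, 100]: mean maximal Calpha fraction under 1/2/4/8 A.

    The fraction denominator is the number of native Calpha positions, so
    unmodeled residues count against the score.
    """
    pos, mob, ref = _paired_ca(model, native)
    if len(pos) == 0:
        raise SuperpositionError("no matched residues between model and native")
    n_ref = sum(1 for r in native.residues if r.ca is not None)
    n = len(pos)
    fractions = []
    for thr in GDT_THRESHOLDS:
        best = 0
        candidates = []
        try:
            sup = kabsch(mob, ref)
            candidates.append(np.linalg.norm(sup.apply(mob) - ref, axis=1))
        except SuperpositionError:
            pass
        if n >= SEED_LENGTH:
            for mask in _seed_masks(n, SEED_LENGTH):
                res = _extend(mob, ref, mask, thr)
                if res is not None:
                    candidates.append(res[1])
        else:
            res = _extend(mob, ref, np.ones(n, bool), thr)
            if res is not None:
                candidates.append(res[1])
        for d in candidates:
            best = max(best, int((d <= thr).sum()))
        fractions.append(best / n_ref)
    return 100.0 * float(np.mean(fractions))
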