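"""Per-residue feature vectors describing a model's local environment.

Each residue of a model is described by a fixed-length vector built from
windowed structural features and sequence-prediction agreement features:

* atom-atom contact histogram over the 13 atom classes (contacts within
  4 A, sequence-adjacent pairs excluded, normalized within the window);
* residue-residue contact histogram over the 6 residue groups (contact =
  any Calpha/side-chain atom pair within 6 A and more than five residues
  apart in sequence), optionally profile-weighted;
* side-chain exposure histogram: 6 residue groups x 4 exposure bins
  ([0,25], (25,50], (50,75], (75,100] percent), optionally
  profile-weighted;
* predicted secondary-structure probabilities at the central residue,
  predicted/assigned agreement over a 21-window, and the assigned class
  one-hot encoded over a 5-window;
* predicted/actual burial agreement over a 21-window and the mean
  relative side-chain exposure over a 13-window;
* mean information-per-position over a 3-window;
* two whole-model averages (global secondary-structure agreement and
  global burial agreement), identical for every residue of one model.

Contacts involving window residues count even when the partner lies
outside the window; truncated windows at the termini are divided by the
actual residue count, never the nominal window length.  Profile
weighting distributes each residue's contribution across the six groups
according to its per-position amino-acid frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sasa import compute_sasa
from .secstruct import assign_secondary_structure, read_stride, read_dssp
from .sequence_inputs import (
    AA_ORDER,
    ExposurePrediction,
    SequenceProfile,
    SSPrediction,
)
from .structure_io import (
    N_ATOM_CLASSES,
    N_RESIDUE_GROUPS,
    ProteinModel,
    assign_residue_group,
)

__all__ = [
    "FeatureConfig",
    "compute_sasa",
    "assign_secondary_structure",
    "read_stride",
    "read_dssp",
    "atom_contact_features",
    "residue_contact_features",
    "exposure_features",
    "ss_agreement_features",
    "surface_agreement_features",
    "ipp_feature",
    "global_features",
    "build_feature_vector",
    "build_feature_matrix",
    "feature_names",
    "BURIAL_THRESHOLD",
]

ATOM_CONTACT_CUTOFF = 4.0
RESIDUE_CONTACT_CUTOFF = 6.0
RESIDUE_MIN_SEPARATION = 5   # contact requires |i - j| > 5
ATOM_ADJACENCY_EXCLUSION = 1  # atom contact requires |i - j| > 1
BURIAL_THRESHOLD = 0.25       # exposed side chain iff relative area >= 25%

EXPOSURE_BIN_EDGES = (0.25, 0.50, 0.75)  # boundary values go to the lower bin

# group -> 6-vector projection of a 20-vector of amino-acid frequencies
_GROUP_OF_AA = np.array([assign_residue_group(a) - 1 for a in AA_ORDER])
_GROUP_PROJECTION = np.zeros((20, N_RESIDUE_GROUPS))
_GROUP_PROJECTION[np.arange(20), _GROUP_OF_AA] = 1.0

_TRI13 = [(i, j) for i in range(N_ATOM_CLASSES) for j in range(i, N_ATOM_CLASSES)]
_TRI6 = [(i, j) for i in range(N_RESIDUE_GROUPS) for j in range(i, N_RESIDUE_GROUPS)]


@dataclass
class FeatureConfig:
    """Window sizes and cutoffs; defaults are the published constants."""

    window: int = 21          # base window for contact/exposure histograms
    ss_window: int = 21
    stride_window: int = 5
    surf_window: int = 21
    area_window: int = 13
    ipp_window: int = 3
    atom_cutoff: float = ATOM_CONTACT_CUTOFF
    residue_cutoff: float = RESIDUE_CONTACT_CUTOFF
    min_separation: int = RESIDUE_MIN_SEPARATION
    profile_weighting: bool = True
    sasa_points: int = 960

    def __post_init__(self):
        for w in (self.window, self.ss_window, self.stride_window,
                  self.surf_window, self.area_window, self.ipp_window):
            if w % 2 == 0 or w < 1:
                raise ValueError("window sizes must be odd and positive")


def _half(width: int) -> int:
    return width // 2


def _window_members(positions: np.ndarray, center_pos: int, width: int) -> np.ndarray:
    """Indices of model residues whose target position lies in the window."""
    h = _half(width)
    return np.where(np.abs(positions - center_pos) <= h)[0]


def _positions(model: ProteinModel) -> np.ndarray:
    return np.array([r.residue_index for r in model.residues], dtype=int)


def _exposure_bin(rel: float) -> int:
    """Four exposure bins; values exactly on an edge fall to the lower bin."""
    for b, edge in enumerate(EXPOSURE_BIN_EDGES):
        if rel <= edge:
            return b
    return 3


def _atom_contact_pairs(model: ProteinModel, cutoff: float):
    """All atom-atom contacts as (res_i, res_j, class_i, class_j) arrays.

    Pairs of atoms from residues adjacent in sequence (|pos diff| <= 1,
    which includes intra-residue pairs) are excluded.
    """
    atoms = [a for r in model.residues for a in r.atoms]
    if not atoms:
        return np.empty((0, 4), dtype=int)
    coords = np.array([a.coords for a in atoms])
    res = np.array([a.residue_index for a in atoms])
    cls = np.array([a.atom_class for a in atoms])
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    ii, jj = np.where(
        (d2 <= cutoff ** 2)
        & (np.abs(res[:, None] - res[None, :]) > ATOM_ADJACENCY_EXCLUSION)
    )
    keep = ii < jj
    ii, jj = ii[keep], jj[keep]
    return np.column_stack((res[ii], res[jj], cls[ii], cls[jj]))


def _residue_contact_pairs(model: ProteinModel, cutoff: float, min_sep: int):
    """Residue-residue contacts as (i, j) model-residue index pairs.

    Contact = any {Calpha + side chain} x {Calpha + side chain} atom pair
    within ``cutoff`` with target-position separation > ``min_sep``.
    """
    groups = []
    for r in model.residues:
        sel = [a.coords for a in r.atoms if a.is_sidechain or a.name == "CA"]
        groups.append(np.array(sel) if sel else np.empty((0, 3)))
    pos = _positions(model)
    n = len(model.residues)
    pairs = []
    for i in range(n):
        if not len(groups[i]):
            continue
        for j in range(i + 1, n):
            if abs(pos[i] - pos[j]) <= min_sep or not len(groups[j]):
                continue
            d2 = ((groups[i][:, None, :] - groups[j][None, :, :]) ** 2).sum(-1)
            if d2.min() <= cutoff ** 2:
                pairs.append((i, j))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _group_mass(model: ProteinModel, profile: SequenceProfile | None) -> np.ndarray:
    """(n_res, 6) group membership; profile-weighted when profile given."""
    n = len(model.residues)
    mass = np.zeros((n, N_RESIDUE_GROUPS))
    for i, r in enumerate(model.residues):
        if profile is not None and r.residue_index < len(profile):
            mass[i] = profile.freqs[r.residue_index] @ _GROUP_PROJECTION
        else:
            mass[i, r.group - 1] = 1.0
    return mass


def _upper_triangle(mat: np.ndarray, pairs) -> np.ndarray:
    sym = mat + mat.T - np.diag(np.diag(mat))
    return np.array([sym[i, j] for i, j in pairs])


def atom_contact_features(
    model: ProteinModel,
    center: int,
    config: FeatureConfig | None = None,
    _pairs: np.ndarray | None = None,
) -> np.ndarray:
    """13x13 upper-triangle contact histogram around residue ``center``.

    A contact counts when at least one of its atoms belongs to a window
    residue; the block is normalized by the window's total contact count
    (all-zero when the window has no contacts).
    """
    config = config or FeatureConfig()
    pos = _positions(model)
    cpos = pos[center]
    h = _half(config.window)
    pairs = _pairs if _pairs is not None else _atom_contact_pairs(model, config.atom_cutoff)
    block = np.zeros((N_ATOM_CLASSES, N_ATOM_CLASSES))
    if len(pairs):
        in_win = (np.abs(pairs[:, 0] - cpos) <= h) | (np.abs(pairs[:, 1] - cpos) <= h)
        for ri, rj, ci, cj in pairs[in_win]:
            a, b = sorted((ci - 1, cj - 1))
            block[a, b] += 1.0
    vec = np.array([block[i, j] for i, j in _TRI13])
    total = vec.sum()
    return vec / total if total > 0 else vec


def residue_contact_features(
    model: ProteinModel,
    center: int,
    profile: SequenceProfile | None = None,
    config: FeatureConfig | None = None,
    _pairs: np.ndarray | None = None,
) -> np.ndarray:
    """6x6 upper-triangle residue-contact histogram around ``center``.

    With a profile, each endpoint spreads its contribution over the six
    groups by its amino-acid frequencies (profile weighting).
    """
    config = config or FeatureConfig()
    pos = _positions(model)
    cpos = pos[center]
    h = _half(config.window)
    pairs = (_pairs if _pairs is not None
             else _residue_contact_pairs(model, config.residue_cutoff, config.min_separation))
    mass = _group_mass(model, profile if config.profile_weighting else None)
    block = np.zeros((N_RESIDUE_GROUPS, N_RESIDUE_GROUPS))
    for i, j in pairs:
        if abs(pos[i] - cpos) <= h or abs(pos[j] - cpos) <= h:
            outer = np.outer(mass[i], mass[j])
            block += np.triu(outer + outer.T) - np.diag(np.diag(outer))
    vec = np.array([block[i, j] for i, j in _TRI6])
    total = vec.sum()
    return vec / total if total > 0 else vec


def exposure_features(
    model: ProteinModel,
    center: int,
    exposures: np.ndarray,
    profile: SequenceProfile | None = None,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """6 groups x 4 exposure bins, normalized by window residue count."""
    config = config or FeatureConfig()
    pos = _positions(model)
    members = _window_members(pos, pos[center], config.window)
    mass = _group_mass(model, profile if config.profile_weighting else None)
    block = np.zeros((N_RESIDUE_GROUPS, 4))
    for i in members:
        block[:, _exposure_bin(float(exposures[i]))] += mass[i]
    return block.ravel() / len(members)


def ss_agreement_features(
    assigned: str,
    predicted: SSPrediction,
    center: int,
    positions: np.ndarray,
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Secondary-structure features at ``center``.

    Returns (central predicted probabilities [H, E, C], fraction of the
    truncated 21-window where the predicted class matches the assigned
    one, and the assigned classes one-hot over the truncated 5-window).
    """
    config = config or FeatureConfig()
    cpos = int(positions[center])
    pred_classes = predicted.classes
    central = (predicted.probs[cpos] if cpos < len(predicted)
               else np.array([0.0, 0.0, 1.0]))

    members = _window_members(positions, cpos, config.ss_window)
    hits = [assigned[i] == pred_classes[positions[i]]
            for i in members if positions[i] < len(predicted)]
    frac = float(np.mean(hits)) if hits else 0.0

    h = _half(config.stride_window)
    onehot = np.zeros((config.stride_window, 3))
    idx_of_pos = {int(positions[i]): i for i in range(len(positions))}
    for k, p in enumerate(range(cpos - h, cpos + h + 1)):
        if p in idx_of_pos:
            onehot[k, "HEC".index(assigned[idx_of_pos[p]])] = 1.0
    return central, frac, onehot.ravel()


def surface_agreement_features(
    exposures: np.ndarray,
    predicted: ExposurePrediction,
    center: int,
    positions: np.ndarray,
    config: FeatureConfig | None = None,
) -> tuple[float, float]:
    """(burial-agreement fraction over 21-window, mean exposure over 13-window).

    The actual class is exposed iff relative side-chain area >= 25%.
    """
    config = config or FeatureConfig()
    cpos = int(positions[center])
    members = _window_members(positions, cpos, config.surf_window)
    hits = [(exposures[i] >= BURIAL_THRESHOLD) == bool(predicted.exposed[positions[i]])
            for i in members if positions[i] < len(predicted)]
    frac = float(np.mean(hits)) if hits else 0.0
    area_members = _window_members(positions, cpos, config.area_window)
    mean_area = float(np.mean(exposures[area_members]))
    return frac, mean_area


def ipp_feature(
    profile: SequenceProfile,
    center_pos: int,
    config: FeatureConfig | None = None,
) -> float:
    """Mean information-per-position over the truncated 3-window."""
    config = config or FeatureConfig()
    h = _half(config.ipp_window)
    lo = max(0, center_pos - h)
    hi = min(len(profile), center_pos + h + 1)
    return float(np.mean(profile.ipp[lo:hi]))


def global_features(
    assigned: str,
    exposures: np.ndarray,
    ss_pred: SSPrediction,
    exp_pred: ExposurePrediction,
    positions: np.ndarray,
) -> tuple[float, float]:
    """Whole-model agreement fractions (secondary structure, burial)."""
    pred_classes = ss_pred.classes
    ss_hits, surf_hits = [], []
    for i, p in enumerate(positions):
        p = int(p)
        if p < len(ss_pred):
            ss_hits.append(assigned[i] == pred_classes[p])
        if p < len(exp_pred):
            surf_hits.append((exposures[i] >= BURIAL_THRESHOLD) == bool(exp_pred.exposed[p]))
    g_ss = float(np.mean(ss_hits)) if ss_hits else 0.0
    g_surf = float(np.mean(surf_hits)) if surf_hits else 0.0
    return g_ss, g_surf


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """Column names in the fixed layout order of the feature vector."""
    names = [f"atom_contact_{i + 1}_{j + 1}" for i, j in _TRI13]
    names += [f"res_contact_{i + 1}_{j + 1}" for i, j in _TRI6]
    names += [f"exposure_g{g + 1}_b{b + 1}"
              for g in range(N_RESIDUE_GROUPS) for b in range(4)]
    names += ["ss_pred_H", "ss_pred_E", "ss_pred_C"]
    names += ["ss_agreement_w21"]
    cfg = config or FeatureConfig()
    names += [f"ss_w5_p{k}_{c}" for k in range(cfg.stride_window) for c in "HEC"]
    names += ["surf_agreement_w21", "surf_area_w13", "ipp_w3",
              "global_ss_agreement", "global_surf_agreement"]
    return names


@dataclass
class ModelInputs:
    """Everything per-model that feature extraction needs, computed once."""

    model: ProteinModel
    profile: SequenceProfile | None
    ss_pred: SSPrediction
    exp_pred: ExposurePrediction
    config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self):
        self.positions = _positions(self.model)
        self.assigned = assign_secondary_structure(self.model)
        self.exposures = compute_sasa(self.model, n_points=self.config.sasa_points)
        self._atom_pairs = _atom_contact_pairs(self.model, self.config.atom_cutoff)
        self._res_pairs = _residue_contact_pairs(
            self.model, self.config.residue_cutoff, self.config.min_separation
        )
        self._global = global_features(
            self.assigned, self.exposures, self.ss_pred, self.exp_pred, self.positions
        )


def build_feature_vector(inputs: ModelInputs, center: int) -> np.ndarray:
    """Assemble the full feature vector for one residue."""
    cfg = inputs.config
    atom = atom_contact_features(inputs.model, center, cfg, _pairs=inputs._atom_pairs)
    res = residue_contact_features(
        inputs.model, center, inputs.profile, cfg, _pairs=inputs._res_pairs
    )
    expo = exposure_features(inputs.model, center, inputs.exposures, inputs.profile, cfg)
    central, ss_frac, ss5 = ss_agreement_features(
        inputs.assigned, inputs.ss_pred, center, inputs.positions, cfg
    )
    surf_frac, mean_area = surface_agreement_features(
        inputs.exposures, inputs.exp_pred, center, inputs.positions, cfg
    )
    ipp = (ipp_feature(inputs.profile, int(inputs.positions[center]), cfg)
           if inputs.profile is not None else 0.0)
    g_ss, g_surf = inputs._global
    return np.concatenate([
        atom, res, expo, central, [ss_frac], ss5,
        [surf_frac, mean_area, ipp, g_ss, g_surf],
    ])


def build_feature_matrix(
    model: ProteinModel,
    profile: SequenceProfile | None,
    ss_pred: SSPrediction,
    exp_pred: ExposurePrediction,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Feature matrix (n_modeled_residues, n_features) for one model."""
    inputs = ModelInputs(model, profile, ss_pred, exp_pred, config or FeatureConfig())
    return np.array([build_feature_vector(inputs, i) for i in range(len(model.residues))])
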