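"""Synthetic structures and sequence inputs with known ground truth.

Everything the scoring pipeline consumes can be generated here: ideal
geometry backbones (helix, extended strand, coil, or two rigid domains
joined by a linker) with CB side-chain placeholders, perturbed model
ensembles whose true per-residue deviations are computed with the same
superposition machinery used for scoring, and matching sequence-derived
prediction files (PSSM, ss2, burial) written in the dialects the readers
parse.

The generator emulates the quality spread of a model ensemble for one
target: per-residue Gaussian displacement fields of increasing scale,
smoothed along the chain so that errors are locally correlated (as they
are in real models), optionally with one segment rigidly rotated away to
mimic a mis-oriented domain.  All randomness flows through one seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import BURIAL_THRESHOLD, FeatureConfig, ModelInputs, build_feature_vector
from .qa_model import TrainingSet
from .sasa import compute_sasa
from .secstruct import assign_secondary_structure
from .sequence_inputs import (
    AA_ORDER,
    ExposurePrediction,
    SequenceProfile,
    SSPrediction,
)
from .similarity import LocalQuality, gdt_ts, optimal_s_superposition
from .structure_io import Atom, ProteinModel, Residue, write_pdb

__all__ = [
    "PerturbationSpec",
    "make_native",
    "make_ensemble",
    "make_sequence_inputs",
    "write_pssm",
    "write_ss2",
    "write_exposure",
    "generate_dataset",
    "write_benchmark_dir",
    "DEFAULT_SIGMAS",
]

# Ideal backbone internal coordinates (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_C_CA_CB = 120.8, 110.1
_OMEGA = 180.0

TORSIONS = {"helix": (-57.0, -47.0), "sheet": (-120.0, 130.0)}

# sigma ladder covering near-native to essentially random models
DEFAULT_SIGMAS = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 9.0)


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three reference atoms and internal coordinates."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phis, psis):
    """Backbone N/CA/C coordinates from per-residue torsions (omega trans)."""
    n_res = len(phis)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_B_N_CA, 0.0, 0.0]
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psis[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phis[i])
    return N, CA, C


def _assemble(model_id, sequence, N, CA, C, psis):
    residues = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        psi = psis[i] if i < n - 1 else 180.0
        O = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        atoms = [
            Atom("N", "N", i, N[i], 1, False),
            Atom("CA", "C", i, CA[i], 2, False),
            Atom("C", "C", i, C[i], 3, False),
            Atom("O", "O", i, O, 4, False),
        ]
        if aa != "G":
            CB = _nerf(N[i], C[i], CA[i], _B_CA_CB, _A_C_CA_CB, 122.6)
            atoms.append(Atom("CB", "C", i, CB, 5, True))
        residues.append(Residue(aa, i, atoms))
    return ProteinModel(model_id, residues)


def make_native(
    n_residues: int,
    fold: str = "helix",
    sequence: str | None = None,
    seed: int = 0,
    path=None,
) -> ProteinModel:
    """Build an ideal-geometry native structure (CB side-chain placeholders).

    fold: 'helix', 'sheet' (extended strand), 'coil' (seeded random
    torsions), or 'two_domain' (two helices rotated apart by an extended
    linker).  Deterministic given (fold, sequence, seed).
    """
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AA_ORDER), size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")

    if fold in TORSIONS:
        phi, psi = TORSIONS[fold]
        phis = np.full(n_residues, phi)
        psis = np.full(n_residues, psi)
    elif fold == "coil":
        phis = rng.uniform(-160.0, -50.0, n_residues)
        psis = rng.uniform(-60.0, 170.0, n_residues)
    elif fold == "two_domain":
        half = n_residues // 2
        linker = range(half - 2, min(half + 3, n_residues))
        phis = np.full(n_residues, TORSIONS["helix"][0])
        psis = np.full(n_residues, TORSIONS["helix"][1])
        for i in linker:
            phis[i], psis[i] = -120.0, 130.0
    else:
        raise ValueError(f"unknown fold {fold!r}")

    N, CA, C = _build_backbone(phis, psis)
    model = _assemble(f"native_{fold}_{n_residues}", sequence, N, CA, C, psis)
    if path is not None:
        write_pdb(model, path)
    return model


@dataclass
class PerturbationSpec:
    """How to derail one model: smoothed Gaussian displacement of scale
    ``sigma`` (Angstrom per residue), optionally a rigid rotation of the
    residue range ``segment`` by ``segment_angle_deg`` about a random axis.
    The seed fully determines the output."""

    sigma: float
    seed: int
    segment: tuple[int, int] | None = None
    segment_angle_deg: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _smooth(noise: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing along the chain, re-scaled to unit variance."""
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(noise[:, k], kernel, mode="same") for k in range(3)]
    )
    sd = out.std()
    return out / sd if sd > 0 else out


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def perturb(native: ProteinModel, spec: PerturbationSpec) -> ProteinModel:
    """Apply a perturbation spec to a native, returning a new model."""
    rng = np.random.default_rng(spec.seed)
    n = len(native.residues)
    disp = spec.sigma * _smooth(rng.standard_normal((n, 3)))
    residues = []
    for i, r in enumerate(native.residues):
        atoms = [
            Atom(a.name, a.element, a.residue_index, a.coords + disp[i],
                 a.atom_class, a.is_sidechain)
            for a in r.atoms
        ]
        residues.append(Residue(r.aa, r.residue_index, atoms))
    model = ProteinModel(f"{native.model_id}_s{spec.sigma}_{spec.seed}",
                         residues, native.target_length)
    if spec.segment is not None and spec.segment_angle_deg != 0.0:
        lo, hi = spec.segment
        R = _rotation_about_axis(rng.standard_normal(3), spec.segment_angle_deg)
        seg_atoms = [a for r in model.residues[lo:hi] for a in r.atoms]
        center = np.mean([a.coords for a in seg_atoms], axis=0)
        for a in seg_atoms:
            a.coords = R @ (a.coords - center) + center
    return model


def make_ensemble(
    native: ProteinModel,
    specs: list[PerturbationSpec],
) -> list[tuple[ProteinModel, LocalQuality, float]]:
    """Perturbed models with their true local quality and true GDT_TS."""
    out = []
    for spec in specs:
        model = perturb(native, spec)
        _, quality = optimal_s_superposition(model, native)
        out.append((model, quality, gdt_ts(model, native)))
    return out


def make_sequence_inputs(
    native: ProteinModel,
    accuracy: float = 0.85,
    seed: int = 0,
    profile_mix: float = 0.3,
    sasa_points: int = 960,
) -> tuple[SequenceProfile, SSPrediction, ExposurePrediction]:
    """Sequence-derived predictions consistent with the native at a given
    accuracy.

    Predicted classes agree with the native's assigned secondary structure
    / burial with probability ``accuracy``; disagreements are uniform over
    the remaining classes.  The profile is the one-hot native sequence
    blended with the uniform distribution at rate ``profile_mix``.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = native.sequence
    L = len(seq)

    assigned = assign_secondary_structure(native)
    probs = np.zeros((L, 3))
    for i in range(L):
        true_idx = "HEC".index(assigned[i])
        if rng.random() < accuracy:
            pred_idx = true_idx
        else:
            pred_idx = rng.choice([k for k in range(3) if k != true_idx])
        probs[i] = 0.1
        probs[i, pred_idx] = 0.8
    ss_pred = SSPrediction(seq, probs)

    exposures = compute_sasa(native, n_points=sasa_points)
    exposed = exposures >= BURIAL_THRESHOLD
    flip = rng.random(L) >= accuracy
    exp_pred = ExposurePrediction(seq, np.where(flip, ~exposed, exposed))

    onehot = np.zeros((L, 20))
    for i, aa in enumerate(seq):
        onehot[i, AA_ORDER.index(aa)] = 1.0
    freqs = (1.0 - profile_mix) * onehot + profile_mix / 20.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(freqs > 0, freqs / 0.05, 1.0)
        pssm = np.where(freqs > 0, 2.0 * np.log2(ratio), -6.0)
        ipp = np.sum(np.where(freqs > 0, freqs * np.log2(ratio), 0.0), axis=1)
    profile = SequenceProfile(seq, freqs, pssm, np.maximum(ipp, 0.0))
    return profile, ss_pred, exp_pred


def write_pssm(profile: SequenceProfile, path) -> None:
    """Write a PSI-BLAST ASCII PSSM dialect file the reader can parse."""
    lines = ["", "Last position-specific scoring matrix computed",
             "            " + "   ".join(AA_ORDER) + "    " + "   ".join(AA_ORDER)]
    for i, aa in enumerate(profile.sequence):
        scores = " ".join(f"{v:6.2f}" for v in profile.pssm[i])
        pcts = " ".join(f"{100.0 * v:7.3f}" for v in profile.freqs[i])
        lines.append(f"{i + 1:5d} {aa} {scores} {pcts} {profile.ipp[i]:6.3f} 1.00")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ss2(ss_pred: SSPrediction, path) -> None:
    """Write a PSIPRED .ss2 file."""
    lines = ["# PSIPRED VFORMAT", ""]
    classes = ss_pred.classes
    for i, aa in enumerate(ss_pred.sequence):
        ph, pe, pc = ss_pred.probs[i]
        lines.append(f"{i + 1:4d} {aa} {classes[i]}  {pc:6.3f} {ph:6.3f} {pe:6.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_exposure(exp_pred: ExposurePrediction, path) -> None:
    """Write the two-line burial/exposure prediction file."""
    classes = "".join("e" if x else "b" for x in exp_pred.exposed)
    Path(path).write_text(f"{exp_pred.sequence}\n{classes}\n")


FOLD_CYCLE = ("helix", "two_domain", "coil", "helix", "coil")


def generate_dataset(
    n_targets: int = 20,
    models_per_target: int = 10,
    n_residues: int = 60,
    seed: int = 0,
    accuracy: float = 0.85,
    sigmas=DEFAULT_SIGMAS,
    config: FeatureConfig | None = None,
):
    """Full synthetic benchmark: features + true local quality per residue.

    Returns (TrainingSet, records) where records is a list of dicts with
    per-model metadata (target, model, true local s/d arrays, true GDT_TS,
    global true S).  Sized by default at 20 targets x 10 models x 60
    residues, the scale used throughout the package's own validation.
    """
    from .features import feature_names  # local import to avoid cycle at module load

    config = config or FeatureConfig()
    rng = np.random.default_rng(seed)
    X_rows, y_rows, group_rows, records = [], [], [], []
    for t in range(n_targets):
        fold = FOLD_CYCLE[t % len(FOLD_CYCLE)]
        native = make_native(n_residues, fold, seed=int(rng.integers(2 ** 31)))
        profile, ss_pred, exp_pred = make_sequence_inputs(
            native, accuracy=accuracy, seed=int(rng.integers(2 ** 31)),
            sasa_points=config.sasa_points,
        )
        specs = [
            PerturbationSpec(sigmas[m % len(sigmas)], seed=int(rng.integers(2 ** 31)))
            for m in range(models_per_target)
        ]
        for model, quality, gdt in make_ensemble(native, specs):
            inputs = ModelInputs(model, profile, ss_pred, exp_pred, config)
            pos = [r.residue_index for r in model.residues]
            for i in range(len(model.residues)):
                X_rows.append(build_feature_vector(inputs, i))
                y_rows.append(quality.s[pos[i]])
                group_rows.append(f"target{t}")
            records.append({
                "target": f"target{t}",
                "model": model.model_id,
                "fold": fold,
                "true_s": quality.s,
                "true_d": quality.d,
                "gdt_ts": gdt,
                "global_s": quality.total / native.target_length,
                "n_residues": len(model.residues),
            })
    train_set = TrainingSet(
        np.array(X_rows), np.array(y_rows), np.array(group_rows),
        feature_names=feature_names(config),
    )
    return train_set, records


def write_benchmark_dir(
    out_dir,
    n_targets: int = 3,
    models_per_target: int = 5,
    n_residues: int = 40,
    seed: int = 0,
    accuracy: float = 0.85,
) -> None:
    """Write a self-contained benchmark directory:
    natives/, models/, seqinputs/, truth.tsv."""
    out = Path(out_dir)
    for sub in ("natives", "models", "seqinputs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth_lines = ["target\tmodel\tresidue\ttrue_d\ttrue_s\tgdt_ts"]
    for t in range(n_targets):
        tid = f"target{t}"
        fold = FOLD_CYCLE[t % len(FOLD_CYCLE)]
        native = make_native(n_residues, fold, seed=int(rng.integers(2 ** 31)))
        write_pdb(native, out / "natives" / f"{tid}.pdb")
        profile, ss_pred, exp_pred = make_sequence_inputs(
            native, accuracy=accuracy, seed=int(rng.integers(2 ** 31))
        )
        write_pssm(profile, out / "seqinputs" / f"{tid}.pssm")
        write_ss2(ss_pred, out / "seqinputs" / f"{tid}.ss2")
        write_exposure(exp_pred, out / "seqinputs" / f"{tid}.acc")
        (out / "seqinputs" / f"{tid}.fasta").write_text(
            f">{tid}\n{native.sequence}\n"
        )
        specs = [
            PerturbationSpec(DEFAULT_SIGMAS[m % len(DEFAULT_SIGMAS)],
                             seed=int(rng.integers(2 ** 31)))
            for m in range(models_per_target)
        ]
        for m, (model, quality, gdt) in enumerate(make_ensemble(native, specs)):
            mid = f"{tid}_model{m}"
            write_pdb(model, out / "models" / f"{mid}.pdb")
            for r in model.residues:
                p = r.residue_index
                truth_lines.append(
                    f"{tid}\t{mid}\t{p + 1}\t{quality.d[p]:.4f}\t{quality.s[p]:.6f}\t{gdt:.2f}"
                )
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
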