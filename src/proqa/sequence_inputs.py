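"""Readers for sequence-derived prediction files.

Three per-target inputs accompany each model:

* a PSI-BLAST ASCII PSSM (the ``-Q`` output dialect) giving per-position
  log-odds scores, weighted observed percentages, and information per
  position (IPP);
* a PSIPRED ``.ss2`` three-state secondary-structure prediction;
* a two-line burial/exposure prediction (sequence line + b/e line).

Profile weighting of structural features uses the weighted-percentage
columns of the PSSM (per-position amino-acid frequencies), not the
log-odds scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AA_ORDER",
    "SequenceProfile",
    "SSPrediction",
    "ExposurePrediction",
    "SequenceInputError",
    "read_pssm",
    "read_ss2",
    "read_exposure_prediction",
    "read_fasta",
]

# Column order of amino acids in PSI-BLAST ASCII PSSMs.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

SS_CLASSES = "HEC"


class SequenceInputError(ValueError):
    """Malformed or inconsistent sequence-derived input file."""


@dataclass
class SequenceProfile:
    """Per-position profile: frequencies, log-odds PSSM, and IPP.

    ``freqs`` rows sum to 1; ``ipp`` is conservation in bits (>= 0).
    """

    sequence: str
    freqs: np.ndarray   # (L, 20) rows on the probability simplex
    pssm: np.ndarray    # (L, 20) log-odds
    ipp: np.ndarray     # (L,) bits

    def __post_init__(self):
        L = len(self.sequence)
        self.freqs = np.asarray(self.freqs, float)
        self.pssm = np.asarray(self.pssm, float)
        self.ipp = np.asarray(self.ipp, float)
        if self.freqs.shape != (L, 20) or self.pssm.shape != (L, 20):
            raise SequenceInputError("profile matrices must be (L, 20)")
        if self.ipp.shape != (L,) or np.any(self.ipp < 0):
            raise SequenceInputError("IPP must be length L and non-negative")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise SequenceInputError("frequency rows must sum to 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SSPrediction:
    """Three-state secondary-structure probabilities per target position."""

    sequence: str
    probs: np.ndarray  # (L, 3) columns H, E, C; rows sum to 1

    def __post_init__(self):
        self.probs = np.asarray(self.probs, float)
        if self.probs.shape != (len(self.sequence), 3):
            raise SequenceInputError("ss probabilities must be (L, 3)")
        self.probs = self.probs / self.probs.sum(axis=1, keepdims=True)

    @property
    def classes(self) -> str:
        return "".join(SS_CLASSES[i] for i in np.argmax(self.probs, axis=1))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExposurePrediction:
    """Two-class burial prediction: True where exposed."""

    sequence: str
    exposed: np.ndarray  # (L,) bool

    def __post_init__(self):
        self.exposed = np.asarray(self.exposed, bool)
        if self.exposed.shape != (len(self.sequence),):
            raise SequenceInputError("exposure must have one class per position")

    def __len__(self) -> int:
        return len(self.sequence)


def read_pssm(path) -> SequenceProfile:
    """Read a PSI-BLAST ASCII PSSM.

    Frequencies come from the weighted-percentage block rescaled to sum
    to 1; an all-zero percentage row falls back to one-hot on the query
    residue.  IPP comes from the information column.
    """
    rows = []
    seq = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = raw.split()
        if len(parts) < 42 or not parts[0].isdigit():
            continue  # header / footer / blank
        if len(parts) < 43:
            raise SequenceInputError(f"{path}:{lineno}: expected >= 43 columns, got {len(parts)}")
        aa = parts[1]
        try:
            scores = np.array(parts[2:22], dtype=float)
            pcts = np.array(parts[22:42], dtype=float)
            info = float(parts[42])
        except ValueError as exc:
            raise SequenceInputError(f"{path}:{lineno}: {exc}") from exc
        seq.append(aa)
        rows.append((scores, pcts, info))
    if not rows:
        raise SequenceInputError(f"{path}: no PSSM rows found")
    L = len(rows)
    pssm = np.array([r[0] for r in rows])
    freqs = np.array([r[1] for r in rows])
    ipp = np.array([max(r[2], 0.0) for r in rows])
    for i in range(L):
        tot = freqs[i].sum()
        if tot <= 0:
            freqs[i] = 0.0
            freqs[i, _AA_INDEX.get(seq[i], 0)] = 1.0
        else:
            freqs[i] /= tot
    return SequenceProfile("".join(seq), freqs, pssm, ipp)


def read_ss2(path) -> SSPrediction:
    """Read a PSIPRED .ss2 file (index, residue, class, pC, pH, pE)."""
    seq = []
    probs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise SequenceInputError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
        try:
            pc, ph, pe = float(parts[3]), float(parts[4]), float(parts[5])
        except ValueError as exc:
            raise SequenceInputError(f"{path}:{lineno}: {exc}") from exc
        seq.append(parts[1])
        probs.append([ph, pe, pc])  # stored H, E, C
    if not seq:
        raise SequenceInputError(f"{path}: no prediction lines")
    return SSPrediction("".join(seq), np.array(probs))


def read_exposure_prediction(path) -> ExposurePrediction:
    """Read a two-line burial/exposure file: sequence line then b/e line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith(">")]
    if len(lines) < 2:
        raise SequenceInputError(f"{path}: need a sequence line and a class line")
    seq, classes = lines[0], lines[1]
    if len(seq) != len(classes):
        raise SequenceInputError(
            f"{path}: sequence length {len(seq)} != class line length {len(classes)}"
        )
    bad = set(classes.lower()) - {"b", "e"}
    if bad:
        raise SequenceInputError(f"{path}: unknown exposure classes {sorted(bad)}")
    exposed = np.array([c == "e" for c in classes.lower()])
    return ExposurePrediction(seq, exposed)


def read_fasta(path) -> str:
    """Read the (single) target sequence from a FASTA file."""
    seq = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        seq.append(line)
    if not seq:
        raise SequenceInputError(f"{path}: empty FASTA")
    return "".join(seq).upper()
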