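"""Consensus scoring over a model ensemble and the hybrid combination.

The consensus (Pcons-style) local score of residue r in model m is the
mean, over all other models of the same target, of the S-score similarity
at r under the superposition maximizing the summed S-score between the
pair.  The consensus global score sums the local scores over the target
length.  A structurally average model therefore scores high, an outlier
low — regardless of whether either is actually correct.

The hybrid score mixes the single-model prediction with the consensus:

    S_combined = (1 - k) * S_single + k * S_consensus,   k in [0, 1]

with k = 0.8 by default.
"""

from __future__ import annotations

import numpy as np

from .qa_model import predict_global
from .similarity import DEFAULT_D0, optimal_s_superposition
from .structure_io import ProteinModel

__all__ = ["pcons_score", "pcons_score_all", "combine", "DEFAULT_K"]

DEFAULT_K = 0.8


def _pairwise_local_s(a: ProteinModel, b: ProteinModel, d0: float) -> np.ndarray:
    _, quality = optimal_s_superposition(a, b, d0=d0)
    return quality.s


def pcons_score(
    ensemble: list[ProteinModel],
    model_index: int,
    d0: float = DEFAULT_D0,
) -> tuple[np.ndarray, float]:
    """Consensus local S per target position and global score for one model.

    Requires an ensemble of at least two models mapped to the same target.
    """
    if len(ensemble) < 2:
        raise ValueError("consensus undefined for an ensemble of size 1")
    model = ensemble[model_index]
    L = max(m.target_length for m in ensemble)
    acc = np.zeros(L)
    n_other = 0
    for j, other in enumerate(ensemble):
        if j == model_index:
            continue
        s = _pairwise_local_s(model, other, d0)
        acc[: len(s)] += s
        n_other += 1
    local = acc / n_other
    return local, predict_global(local, L)


def pcons_score_all(
    ensemble: list[ProteinModel],
    d0: float = DEFAULT_D0,
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus (local, global) for every ensemble member.

    Computes each unordered pair's similarity once.  Returns an
    (n_models, target_length) local matrix and an (n_models,) global
    vector.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("consensus undefined for an ensemble of size 1")
    L = max(m.target_length for m in ensemble)
    acc = np.zeros((n, L))
    for i in range(n):
        for j in range(i + 1, n):
            # similarity is computed in both orientations: each model is
            # scored under its own best superposition onto the other
            s_ij = _pairwise_local_s(ensemble[i], ensemble[j], d0)
            s_ji = _pairwise_local_s(ensemble[j], ensemble[i], d0)
            acc[i, : len(s_ij)] += s_ij
            acc[j, : len(s_ji)] += s_ji
    local = acc / (n - 1)
    global_scores = local.sum(axis=1) / L
    return local, global_scores


def combine(s_single, s_consensus, k: float = DEFAULT_K):
    """Hybrid score (1 - k) * single + k * consensus, elementwise."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    a = np.asarray(s_single, float)
    b = np.asarray(s_consensus, float)
    if np.any(a < 0) or np.any(a > 1) or np.any(b < 0) or np.any(b > 1):
        raise ValueError("scores must lie in [0, 1]")
    out = (1.0 - k) * a + k * b
    return float(out) if out.ndim == 0 else out
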