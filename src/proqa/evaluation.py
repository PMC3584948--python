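"""Benchmark statistics for quality-assessment predictions.

Covers correlation at three levels (pooled, per-target, per-model),
Fisher r-to-z significance tests between correlations, model-selection
measures (GDT1 sums and per-target selection Z-scores), residue-level
classification (ROC/AUC for correct <3 A vs incorrect >5 A residues),
top-fraction deviation curves, and bootstrap support for pairwise method
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "pearson",
    "fisher_z",
    "fisher_z_test",
    "grouped_correlations",
    "gdt1",
    "selection_zscore",
    "roc_correct_incorrect",
    "top_fraction_deviation",
    "bootstrap_support",
    "EvaluationReport",
    "evaluate_local",
]

CORRECT_CUTOFF = 3.0    # residues deviating < 3 A are correct
INCORRECT_CUTOFF = 5.0  # residues deviating > 5 A are incorrect


def pearson(x, y) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float) -> float:
    """Fisher transform z = 0.5 * [ln(1 + R) - ln(1 - R)] = arctanh(R)."""
    if not -1.0 < r < 1.0:
        raise ValueError("|R| must be < 1")
    return 0.5 * (np.log1p(r) - np.log1p(-r))


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided test for the difference of two correlations.

    z_i are Fisher transforms with variance 1/(n_i - 3); returns the
    standardized difference and its normal two-sided P-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 observations per correlation")
    z1, z2 = fisher_z(r1), fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def grouped_correlations(pred, true, groups) -> tuple[float, float, int]:
    """(mean within-group R, pooled R, groups skipped as constant)."""
    pred = np.asarray(pred, float)
    true = np.asarray(true, float)
    groups = np.asarray(groups)
    rs, skipped = [], 0
    for g in np.unique(groups):
        m = groups == g
        if pred[m].std() == 0 or true[m].std() == 0 or m.sum() < 2:
            skipped += 1
            continue
        rs.append(pearson(pred[m], true[m]))
    mean_r = float(np.mean(rs)) if rs else float("nan")
    return mean_r, pearson(pred, true), skipped


def gdt1(selections: dict[str, float]) -> float:
    """Sum over targets of the GDT_TS of each first-ranked model."""
    return float(sum(selections.values()))


def selection_zscore(selected_quality: float, target_qualities) -> float:
    """(selected - mean) / std within one target; 0 when the spread is zero."""
    q = np.asarray(target_qualities, float)
    sd = q.std()
    if sd == 0:
        warnings.warn("zero quality variance for target; Z-score reported as 0")
        return 0.0
    return float((selected_quality - q.mean()) / sd)


def roc_correct_incorrect(predicted_s, true_d):
    """ROC for separating correct (<3 A) from incorrect (>5 A) residues.

    Residues with 3 <= d <= 5 are excluded.  Returns (fpr, tpr,
    thresholds, auc).
    """
    s = np.asarray(predicted_s, float)
    d = np.asarray(true_d, float)
    keep = (d < CORRECT_CUTOFF) | (d > INCORRECT_CUTOFF)
    s, d = s[keep], d[keep]
    labels = (d < CORRECT_CUTOFF).astype(int)
    if labels.min() == labels.max():
        raise ValueError("need both correct and incorrect residues for a ROC")
    fpr, tpr, thr = roc_curve(labels, s)
    return fpr, tpr, thr, float(roc_auc_score(labels, s))


def top_fraction_deviation(predicted_s, true_d, fractions=(0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)):
    """Mean true deviation among the top-ranked fraction of residues.

    Residues are ranked by predicted score descending; for each fraction f
    the mean of the true deviations of the first ceil(f * n) residues is
    reported.
    """
    s = np.asarray(predicted_s, float)
    d = np.asarray(true_d, float)
    order = np.argsort(-s, kind="stable")
    d_sorted = d[order]
    out = []
    n = len(d)
    for f in fractions:
        top = max(1, int(np.ceil(f * n)))
        out.append(float(d_sorted[:top].mean()))
    return np.array(out)


def bootstrap_support(
    gdt_a: dict[str, float],
    gdt_b: dict[str, float],
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of bootstrap target resamples where method A's GDT1 beats B's.

    Targets are resampled with replacement; ties count 0.5.
    """
    targets = sorted(set(gdt_a) & set(gdt_b))
    if not targets:
        raise ValueError("no common targets")
    a = np.array([gdt_a[t] for t in targets])
    b = np.array([gdt_b[t] for t in targets])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(targets), size=(n_boot, len(targets)))
    sa = a[idx].sum(axis=1)
    sb = b[idx].sum(axis=1)
    return float(np.mean(np.where(sa > sb, 1.0, np.where(sa == sb, 0.5, 0.0))))


@dataclass
class EvaluationReport:
    """Local-quality benchmark summary over a prediction table."""

    R: float
    R_target: float
    R_model: float
    n: int
    auc: float | None = None
    skipped_targets: int = 0
    skipped_models: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "R": self.R, "R_target": self.R_target, "R_model": self.R_model,
            "n": self.n, "auc": self.auc,
            "skipped_targets": self.skipped_targets,
            "skipped_models": self.skipped_models,
        }
        d.update(self.extras)
        return d


def evaluate_local(pred_s, true_s, true_d, target_ids, model_ids) -> EvaluationReport:
    """Pooled/per-target/per-model correlations plus residue ROC AUC."""
    pred_s = np.asarray(pred_s, float)
    true_s = np.asarray(true_s, float)
    true_d = np.asarray(true_d, float)
    r_target, r_pooled, skip_t = grouped_correlations(pred_s, true_s, target_ids)
    model_key = np.array([f"{t}|{m}" for t, m in zip(target_ids, model_ids)])
    r_model, _, skip_m = grouped_correlations(pred_s, true_s, model_key)
    try:
        _, _, _, auc = roc_correct_incorrect(pred_s, true_d)
    except ValueError:
        auc = None
    return EvaluationReport(
        R=r_pooled, R_target=r_target, R_model=r_model, n=len(pred_s),
        auc=auc, skipped_targets=skip_t, skipped_models=skip_m,
    )
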