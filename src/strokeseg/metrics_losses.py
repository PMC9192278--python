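"""Scoring layer: Dice family, texture statistics, image-quality metrics,
lesion-detection reports, group statistics and the bias-variance
decomposition of generalization error.

The Dice family compares a predicted voxel set E against truth F:

    dice      = 2|E∩F| / (|E| + |F|)
    new_dice  = 2(|E∩F| - |¬E∩F| - |E∩¬F|) / (|E| + |F|)

new_dice subtracts false negatives and false positives in the numerator,
so it penalizes over-segmentation explicitly; it ranges in [-2, 1] and
never exceeds dice.  Soft (probability-valued) relaxations with the
squared-sum denominator sum(e^2) + sum(f^2) serve as training losses and
coincide with the set form on binary inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import ImageVolume, SegmentationMask, ValidationError

__all__ = [
    "DiceScores", "TextureFeatures", "QualityReport", "EvalReport",
    "BiasVarianceReport", "GroupComparison",
    "dice_scores", "soft_dice_loss", "soft_new_dice_loss",
    "texture_features", "image_quality", "detection_report",
    "compare_groups", "chi_square_2x2", "bias_variance",
    "render_quality_table", "render_efficacy_table",
]


# ---------------------------------------------------------------------------
# Dice family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiceScores:
    dice: float
    dice_distance: float
    new_dice: float
    tp: int = 0
    fp: int = 0
    fn: int = 0


def _as_binary(mask) -> np.ndarray:
    arr = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError("masks must be binary {0, 1}")
    return arr.astype(np.int64)


def dice_scores(pred, truth) -> DiceScores:
    """Set-cardinality Dice and New-Dice from integer voxel counts."""
    e, f = _as_binary(pred), _as_binary(truth)
    if e.shape != f.shape:
        raise ValidationError("masks must share a grid")
    ne, nf = int(e.sum()), int(f.sum())
    if ne + nf == 0:
        raise ValidationError("both masks empty: Dice is 0/0 (invalid case)")
    tp = int((e & f).sum())
    fn = int(((1 - e) & f).sum())
    fp = int((e & (1 - f)).sum())
    dice = 2 * tp / (ne + nf)
    new = 2 * (tp - fn - fp) / (ne + nf)
    return DiceScores(dice, 1.0 - dice, new, tp=tp, fp=fp, fn=fn)


def _is_tensor(x) -> bool:
    from .nn.autodiff import Tensor
    return isinstance(x, Tensor)


def _soft_terms(probabilities, truth):
    """Shared plumbing for the soft losses; works on plain arrays and on
    autodiff tensors (so the same expressions are the training gradients)."""
    if _is_tensor(probabilities):
        e = probabilities
        raw = e.data
    else:
        e = np.asarray(probabilities, dtype=np.float64)
        raw = e
    if raw.min() < -1e-9 or raw.max() > 1 + 1e-9:
        raise ValidationError("probabilities must lie in [0, 1]")
    f = truth.data if isinstance(truth, SegmentationMask) else np.asarray(truth)
    f = f.astype(np.float64)
    if raw.shape != f.shape:
        raise ValidationError("probabilities and truth must share a grid")
    inter = (e * f).sum()
    fn = ((1.0 - e) * f).sum()
    fp = (e * (1.0 - f)).sum()
    den = (e * e).sum() + float((f * f).sum())
    return inter, fn, fp, den


def soft_dice_loss(probabilities, truth):
    """1 - soft Dice; differentiable when given an autodiff tensor."""
    inter, _fn, _fp, den = _soft_terms(probabilities, truth)
    return 1.0 - (2.0 * inter) / den


def soft_new_dice_loss(probabilities, truth):
    """1 - soft New-Dice; equals 1 - new_dice on hard {0,1} inputs."""
    inter, fn, fp, den = _soft_terms(probabilities, truth)
    return 1.0 - 2.0 * (inter - fn - fp) / den


# ---------------------------------------------------------------------------
# texture statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureFeatures:
    """First, third and fourth standardized moments of an intensity sample.

    Population convention: skewness = m3 / m2^(3/2), kurtosis (excess)
    = m4 / m2^2 - 3 with m_k the k-th central moment.  A zero-variance
    sample sets ``degenerate`` and reports skewness = kurtosis = 0.
    """

    mean: float
    skewness: float
    kurtosis: float
    degenerate: bool = False


def texture_features(values) -> TextureFeatures:
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValidationError("texture_features needs at least one sample")
    mean = float(x.mean())
    c = x - mean
    m2 = float((c ** 2).mean())
    # relative degeneracy floor: numerically constant samples leave only
    # rounding residue in the central moments
    scale = max(1.0, float(np.abs(x).max()))
    if m2 <= (1e-12 * scale) ** 2:
        return TextureFeatures(mean, 0.0, 0.0, degenerate=True)
    m3 = float((c ** 3).mean())
    m4 = float((c ** 4).mean())
    return TextureFeatures(mean, m3 / m2 ** 1.5, m4 / m2 ** 2 - 3.0)


# ---------------------------------------------------------------------------
# image quality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityReport:
    psnr: float  # dB; +inf for identical images
    rmse: float
    ssim: float
    max_value: float


def image_quality(ref: ImageVolume, test: ImageVolume,
                  max_value: float | None = None) -> QualityReport:
    """RMSE, PSNR = 20*log10(MAX/RMSE) and windowed SSIM.

    MAX defaults to the reference's declared dynamic range rather than a
    hard-coded 255.  SSIM uses the standard constants K1 = 0.01,
    K2 = 0.03 on a 7x7 window.
    """
    from skimage.metrics import structural_similarity

    if ref.shape != test.shape:
        raise ValidationError("images must share a grid")
    if max_value is None:
        max_value = ref.max_value
    diff = ref.data - test.data
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    psnr = float("inf") if rmse == 0 else 20.0 * np.log10(max_value / rmse)
    ssim = float(structural_similarity(
        ref.data, test.data, data_range=max_value, win_size=7,
        K1=0.01, K2=0.03, gaussian_weights=False))
    return QualityReport(psnr, rmse, ssim, float(max_value))


# ---------------------------------------------------------------------------
# detection / efficacy reporting
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-group detection metrics: lesion-level sensitivity, voxel-level
    specificity/accuracy (all percentages in [0, 100]), detected-lesion
    counts per case as mean +/- sd, and the full per-case table."""

    sensitivity: float
    specificity: float
    accuracy: float
    lesions_detected_mean: float
    lesions_detected_sd: float
    per_case: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> dict:
        return {"sensitivity_pct": round(self.sensitivity, 1),
                "specificity_pct": round(self.specificity, 1),
                "accuracy_pct": round(self.accuracy, 1),
                "lesions_detected": f"{self.lesions_detected_mean:.1f} "
                                    f"± {self.lesions_detected_sd:.1f}"}


def detection_report(pred_masks: Sequence, truth_masks: Sequence) -> EvalReport:
    """Score predictions case by case.

    A true lesion (connected component of the truth mask) counts as
    detected when it overlaps the predicted mask in at least one voxel.
    Sensitivity is lesion-level (detected / present); specificity and
    accuracy are voxel-level over all cases.
    """
    if len(pred_masks) == 0 or len(pred_masks) != len(truth_masks):
        raise ValidationError("need matched, non-empty prediction/truth lists")
    rows = []
    for case, (pred, truth) in enumerate(zip(pred_masks, truth_masks)):
        e, f = _as_binary(pred), _as_binary(truth)
        if e.shape != f.shape:
            raise ValidationError(f"case {case}: grids differ")
        labels, n_lesions = ndimage.label(f)
        detected = 0
        for lab in range(1, n_lesions + 1):
            if np.any(e[labels == lab]):
                detected += 1
        tp = int((e & f).sum())
        fp = int((e & (1 - f)).sum())
        fn = int(((1 - e) & f).sum())
        tn = int(((1 - e) & (1 - f)).sum())
        rows.append({"case": case, "true_lesions": n_lesions,
                     "detected_lesions": detected, "tp": tp, "fp": fp,
                     "fn": fn, "tn": tn})
    table = pd.DataFrame(rows)
    tot = table[["tp", "fp", "fn", "tn"]].sum()
    lesions = table["true_lesions"].sum()
    detected = table["detected_lesions"].sum()
    sens = 100.0 * detected / lesions if lesions else 100.0
    spec = 100.0 * tot.tn / (tot.tn + tot.fp) if (tot.tn + tot.fp) else 100.0
    acc = 100.0 * (tot.tp + tot.tn) / tot[["tp", "fp", "fn", "tn"]].sum()
    counts = table["detected_lesions"].to_numpy(dtype=float)
    return EvalReport(sens, spec, acc, float(counts.mean()),
                      float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                      per_case=table)


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    t_pvalue: float
    chi2_statistic: float
    chi2_pvalue: float


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction: sum (O - E)^2 / E with expectations from the margins."""
    obs = np.asarray(table, dtype=np.float64)
    if obs.shape != (2, 2) or obs.min() < 0:
        raise ValidationError("need a non-negative 2x2 table")
    n = obs.sum()
    if n == 0:
        raise ValidationError("empty contingency table")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if np.any(exp == 0):
        raise ValidationError("degenerate margins in contingency table")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def compare_groups(a: EvalReport, b: EvalReport) -> GroupComparison:
    """Welch t-test on per-case detected-lesion counts and a 2x2
    chi-square on pooled voxel classification (correct vs incorrect)."""
    xa = a.per_case["detected_lesions"].to_numpy(dtype=float)
    xb = b.per_case["detected_lesions"].to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValidationError("t-test needs at least 2 cases per group")
    if np.array_equal(np.sort(xa), np.sort(xb)) and xa.std() == 0:
        t, tp = 0.0, 1.0  # degenerate zero-variance identical groups
    else:
        t, tp = stats.ttest_ind(xa, xb, equal_var=False)
        if np.isnan(t):
            t, tp = 0.0, 1.0
    tab = []
    for rep in (a, b):
        tot = rep.per_case[["tp", "fp", "fn", "tn"]].sum()
        tab.append([tot.tp + tot.tn, tot.fp + tot.fn])
    chi2, cp = chi_square_2x2(tab)
    return GroupComparison(float(t), float(tp), chi2, cp)


# ---------------------------------------------------------------------------
# bias-variance decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasVarianceReport:
    """MSE(Q) = (E[Q*] - Q)^2 + VAR(Q*), spatial means over the grid."""

    bias_sq: float
    variance: float
    mse: float


def bias_variance(predictions: Sequence, reference: ImageVolume) -> BiasVarianceReport:
    """Decompose replicate-averaged squared error into bias^2 + variance.

    ``predictions`` are >= 2 replicate outputs (e.g. the same denoiser
    trained under different seeds) on the reference grid; the identity
    mse = bias^2 + variance holds voxelwise with the population variance.
    """
    arrs = [p.data if isinstance(p, ImageVolume) else np.asarray(p, dtype=np.float64)
            for p in predictions]
    if len(arrs) < 2:
        raise ValidationError("need at least 2 prediction replicates")
    ref = reference.data if isinstance(reference, ImageVolume) else np.asarray(reference)
    stack = np.stack(arrs)
    if stack.shape[1:] != ref.shape:
        raise ValidationError("replicates must share the reference grid")
    mean_pred = stack.mean(axis=0)
    bias_sq = (mean_pred - ref) ** 2
    var = stack.var(axis=0)  # population variance
    mse = ((stack - ref) ** 2).mean(axis=0)
    return BiasVarianceReport(float(bias_sq.mean()), float(var.mean()),
                              float(mse.mean()))


# ---------------------------------------------------------------------------
# table renderers (clinical-style layouts)
# ---------------------------------------------------------------------------

def render_quality_table(entries: Sequence[tuple[str, QualityReport]]) -> pd.DataFrame:
    """Columns: Method, PSNR, RMSE, SSIM."""
    return pd.DataFrame([
        {"Method": name, "PSNR": round(q.psnr, 2), "RMSE": round(q.rmse, 3),
         "SSIM": round(q.ssim, 3)} for name, q in entries])


def render_efficacy_table(entries: Sequence[tuple[str, EvalReport]]) -> pd.DataFrame:
    """Columns: group, Sensitivity (%), Number of lesions detected,
    Accuracy (%); percentages to one decimal."""
    return pd.DataFrame([
        {"Group": name,
         "Sensitivity (%)": round(r.sensitivity, 1),
         "Number of lesions detected":
             f"{r.lesions_detected_mean:.1f} ± {r.lesions_detected_sd:.1f}",
         "Accuracy (%)": round(r.accuracy, 1)} for name, r in entries])
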