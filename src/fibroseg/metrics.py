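"""Tversky index/loss and the volumetric evaluation suite.

The Tversky index generalizes Dice with asymmetric penalties: for predicted
set P and ground truth G,

    S(P, G; alpha, beta) = |P∩G| / (|P∩G| + alpha·|P\\G| + beta·|G\\P|)

with alpha weighting false positives and beta false negatives; alpha = beta =
0.5 recovers the Dice similarity coefficient. The soft (probabilistic) form
replaces set cardinalities with sums over per-pixel class probabilities, and
the training loss is its complement, 1 − S.

Segmentations are scored with six volumetric indicators: sensitivity, positive
predictive value (PPV), Dice similarity coefficient (DSC), volume overlap
error (VOE = 1 − Jaccard), signed volumetric difference (VD) and average
symmetric surface distance (ASSD, in mm using the voxel spacing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .nn.autodiff import Var, narrow
from .volume import MaskVolume


@dataclass
class TverskyParams:
    """False-positive (alpha) and false-negative (beta) penalty weights."""

    alpha: float = 0.3
    beta: float = 0.7

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("require alpha >= 0, beta >= 0, alpha + beta > 0")


def tversky_index(pred, truth, params: TverskyParams = TverskyParams(),
                  smooth: float = 0.0) -> float:
    """Tversky index of a prediction against a binary truth.

    `pred` may be a binary mask (crisp sets) or per-pixel lung probabilities
    (soft form); `truth` is binary. Both-empty inputs score 1 by convention
    (perfect agreement on absence) when `smooth` is 0.
    """
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    tp = float((p * g).sum())
    fp = float((p * (1 - g)).sum())
    fn = float(((1 - p) * g).sum())
    denom = tp + params.alpha * fp + params.beta * fn + smooth
    if denom == 0.0:
        return 1.0  # P and G both empty
    return (tp + smooth) / denom


def tversky_loss(p0, g0, params: TverskyParams = TverskyParams(),
                 smooth: float = 1e-6):
    """Tversky loss 1 − S on soft lung probabilities.

    When `p0` is an autodiff `Var` the result is a differentiable `Var`
    (used as the training objective); with plain arrays a float is returned.
    The smoothing constant guards the 0/0 case of empty-lung slices.
    """
    if isinstance(p0, Var):
        g = Var(np.asarray(g0, dtype=p0.data.dtype))
        tp = (p0 * g).sum()
        fp = (p0 * (1.0 - g)).sum()
        fn = ((1.0 - p0) * g).sum()
        t = (tp + smooth) / (tp + params.alpha * fp + params.beta * fn + smooth)
        return 1.0 - t
    p = np.asarray(p0, dtype=np.float64)
    g = np.asarray(g0, dtype=np.float64)
    tp = float((p * g).sum())
    fp = float((p * (1 - g)).sum())
    fn = float(((1 - p) * g).sum())
    return 1.0 - (tp + smooth) / (tp + params.alpha * fp + params.beta * fn + smooth)


def tversky_loss_from_probs(probs: Var, lung_mask: np.ndarray,
                            params: TverskyParams = TverskyParams(),
                            smooth: float = 1e-6) -> Var:
    """Loss on a (N, 2, H, W) soft-max output; channel 0 is the lung class."""
    p0 = narrow(probs, 1, 0, 1)
    return tversky_loss(p0, lung_mask.reshape(p0.shape), params, smooth)


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """Exhaustive voxel tally (TP, FP, FN, TN) of two aligned binary grids."""
    p = _as_binary(pred)
    g = _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return tp, fp, fn, tn


def _as_binary(m) -> np.ndarray:
    a = m.labels if isinstance(m, MaskVolume) else np.asarray(m)
    return a.astype(bool)


@dataclass
class MetricsReport:
    """Per-study volumetric scores; ratios in percent, ASSD in mm.

    Undefined entries (e.g. sensitivity with an empty truth) are NaN.
    """

    sensitivity: float
    ppv: float
    dsc: float
    voe: float
    vd: float
    assd: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("sensitivity", "ppv", "dsc", "voe", "vd", "assd")}


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary of a binary grid: mask voxels with a face-adjacent background voxel."""
    m = mask.astype(bool)
    structure = ndimage.generate_binary_structure(m.ndim, 1)  # 6-connectivity in 3D
    eroded = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return m & ~eroded


def assd(pred: np.ndarray, truth: np.ndarray,
         spacing: tuple[float, ...] = (1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm.

    Mean of nearest-surface Euclidean distances taken in both directions,
    averaged over all surface voxels of both masks. Zero iff the surfaces
    coincide; NaN if exactly one mask is empty; 0 if both are empty.
    """
    sp = surface_voxels(pred)
    sg = surface_voxels(truth)
    np_, ng = int(sp.sum()), int(sg.sum())
    if np_ == 0 and ng == 0:
        return 0.0
    if np_ == 0 or ng == 0:
        return float("nan")
    dt_g = ndimage.distance_transform_edt(~sg, sampling=spacing)
    dt_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    return float((dt_g[sp].sum() + dt_p[sg].sum()) / (np_ + ng))


def compute_metrics(pred: MaskVolume, truth: MaskVolume) -> MetricsReport:
    """Six-indicator volumetric comparison of a predicted mask against truth."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp, fp, fn, _ = confusion_counts(pred, truth)
    n_p, n_g = tp + fp, tp + fn
    sens = 100.0 * tp / n_g if n_g else float("nan")
    ppv = 100.0 * tp / n_p if n_p else float("nan")
    dsc = 100.0 * 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 100.0
    voe = 100.0 * (1 - tp / (tp + fp + fn)) if (tp + fp + fn) else 0.0
    vd = 100.0 * (n_p - n_g) / n_g if n_g else float("nan")
    d = assd(pred.labels, truth.labels, spacing=pred.spacing)
    return MetricsReport(sens, ppv, dsc, voe, vd, d)


@dataclass
class SummaryStats:
    """Mean, sample std (n−1), normal-approximation 95% CI half-width, n."""

    mean: float
    std: float
    ci95: float
    n: int


def summarize(values) -> SummaryStats:
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("summarize requires at least one value")
    mean = float(v.mean())
    std = float(v.std(ddof=1)) if v.size > 1 else 0.0
    ci95 = 1.96 * std / math.sqrt(v.size)
    return SummaryStats(mean, std, ci95, int(v.size))


@dataclass
class AnovaResult:
    F: float
    F_crit: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def anova_dsc(group_a, group_b, alpha: float = 0.05) -> AnovaResult:
    """Two-group one-way ANOVA (per-study DSC comparison of two methods).

    F = between-group mean square / within-group mean square, with
    (1, nA + nB − 2) degrees of freedom; equals the square of the pooled
    two-sample t statistic. Identical groups give F = 0, p = 1.
    """
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    grand = (a.sum() + b.sum()) / (na + nb)
    ss_between = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, na + nb - 2
    f_crit = float(stats.f.ppf(1 - alpha, df1, df2))
    if ss_between <= 0:
        return AnovaResult(0.0, f_crit, 1.0)
    if ss_within == 0:
        return AnovaResult(float("inf"), f_crit, 0.0)
    f_val = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f_val, df1, df2))
    return AnovaResult(float(f_val), f_crit, p)
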