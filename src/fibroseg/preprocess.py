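"""Geometry resampling, slice extraction and per-fold standardization.

Mixed-resolution HRCT studies (720×720 and 672×672 in-plane matrices from
different scanners) are brought to a common geometry: resample to isotropic
1×1×1 mm with linear interpolation (nearest-neighbour for masks), then
center-crop or pad the axial plane to a fixed matrix (512×512 by default),
padding with air. Training inputs are standardized pixel-wise with a 2D
mean/std image computed over all training slices of a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import HU_PAD, CTVolume, MaskVolume, SlicePair, check_aligned

#: guards division at zero-variance pixels (e.g. padded corners)
STD_EPS = 1e-7


def _resample_grid(arr: np.ndarray, spacing, target_spacing, order: int) -> np.ndarray:
    """Resample a 3D grid to new spacing with endpoint-aligned interpolation.

    The output grid covers the same physical extent: axis length becomes
    floor((n-1) * old / new) + 1 so the first and last samples stay on the
    original end planes.
    """
    coords = []
    for ax in range(3):
        n_out = int(np.floor((arr.shape[ax] - 1) * spacing[ax] / target_spacing[ax])) + 1
        # physical positions of output samples, expressed in input index units
        coords.append(np.arange(n_out) * (target_spacing[ax] / spacing[ax]))
    grid = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(arr.astype(np.float64), np.stack(grid), order=order,
                                   mode="nearest")


def _crop_pad_inplane(arr: np.ndarray, target: int, fill: float) -> np.ndarray:
    """Center-crop or pad the first two axes to target×target."""
    out = arr
    for ax in (0, 1):
        n = out.shape[ax]
        if n > target:
            start = (n - target) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(start, start + target)
            out = out[tuple(sl)]
        elif n < target:
            before = (target - n) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (before, target - n - before)
            out = np.pad(out, pad, constant_values=fill)
    return out


def resample_volume(vol: CTVolume, target_spacing=(1.0, 1.0, 1.0),
                    target_inplane: int = 512,
                    interpolation: str = "linear") -> CTVolume:
    """Resample a CT volume to a common spacing and in-plane matrix size.

    Linear interpolation never produces values outside the input min/max;
    in-plane crop/pad fills with air (−1000 HU).
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing components must be positive")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    res = _resample_grid(vol.voxels, vol.spacing, target_spacing, order)
    res = _crop_pad_inplane(res, target_inplane, HU_PAD)
    return CTVolume(res, tuple(target_spacing), vol.study_id, vol.scanner_tag)


def resample_mask(mask: MaskVolume, target_spacing=(1.0, 1.0, 1.0),
                  target_inplane: int = 512) -> MaskVolume:
    """Resample a binary mask with nearest-neighbour interpolation (stays binary)."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing components must be positive")
    res = _resample_grid(mask.labels, mask.spacing, target_spacing, order=0)
    res = _crop_pad_inplane(res, target_inplane, 0)
    return MaskVolume(np.rint(res).astype(np.uint8), tuple(target_spacing), mask.study_id)


def extract_slices(vol: CTVolume, mask: MaskVolume) -> list[SlicePair]:
    """Split a study into its axial planes, in ascending z order."""
    check_aligned(vol, mask)
    return [SlicePair(vol.voxels[:, :, k], mask.labels[:, :, k], vol.study_id, k)
            for k in range(vol.shape[2])]


def stack_slices(pairs: list[SlicePair], spacing=(1.0, 1.0, 1.0)) -> tuple[CTVolume, MaskVolume]:
    """Inverse of `extract_slices`: reassemble planes into a study."""
    if not pairs:
        raise ValueError("no slices to stack")
    img = np.stack([p.image for p in pairs], axis=2)
    msk = np.stack([p.mask for p in pairs], axis=2)
    return (CTVolume(img, spacing, pairs[0].study_id),
            MaskVolume(msk, spacing, pairs[0].study_id))


@dataclass
class StandardizationStats:
    """Pixel-wise mean/std images aggregated over the training slices of a fold."""

    mean_image: np.ndarray
    std_image: np.ndarray
    fold_id: int = 0
    eps: float = STD_EPS

    def __post_init__(self) -> None:
        self.mean_image = np.asarray(self.mean_image, dtype=np.float64)
        self.std_image = np.asarray(self.std_image, dtype=np.float64)
        if self.mean_image.shape != self.std_image.shape:
            raise ValueError("mean/std image shapes differ")
        if np.any(self.std_image < 0):
            raise ValueError("std_image must be non-negative")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), mean=self.mean_image, std=self.std_image)
        sidecar = {"fold_id": self.fold_id, "shape": list(self.mean_image.shape),
                   "eps": self.eps}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "StandardizationStats":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(arrays["mean"], arrays["std"], meta["fold_id"], meta["eps"])


def compute_standardization(training_slices: list[SlicePair],
                            fold_id: int = 0) -> StandardizationStats:
    """Pixel-wise mean and population std over all training slices of a fold."""
    if not training_slices:
        raise ValueError("need at least one training slice")
    shape = training_slices[0].image.shape
    if any(p.image.shape != shape for p in training_slices):
        raise ValueError("all slices must share one shape")
    # two-pass streaming moments: bounded memory for 10^4-slice folds
    n = len(training_slices)
    acc = np.zeros(shape, dtype=np.float64)
    for p in training_slices:
        acc += p.image
    mean = acc / n
    acc[:] = 0.0
    for p in training_slices:
        acc += (p.image - mean) ** 2
    std = np.sqrt(acc / n)
    return StandardizationStats(mean, std, fold_id)


def apply_standardization(image: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """(x − mean) / max(std, eps), pixel-wise."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != stats.mean_image.shape:
        raise ValueError(f"shape mismatch {image.shape} vs {stats.mean_image.shape}")
    return (image - stats.mean_image) / np.maximum(stats.std_image, stats.eps)


def invert_standardization(std_image: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Recover raw intensities where std > eps (used for round-trip checks)."""
    return std_image * np.maximum(stats.std_image, stats.eps) + stats.mean_image
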