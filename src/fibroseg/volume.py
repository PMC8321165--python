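"""Core in-memory containers for CT volumes and binary lung masks.

All grids are numpy arrays indexed ``[x, y, z]`` (axial planes are the first
two axes; the third axis is the cranio-caudal direction, ascending z).
Intensities are Hounsfield units (HU); geometry is carried as per-axis voxel
spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: HU of air; also used as the padding fill value for in-plane crops.
HU_AIR = -1024.0
HU_PAD = -1000.0


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing!r}")
    return spacing


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU intensities; must be finite.
    spacing : (float, float, float)
        Voxel spacing (x, y, z) in mm, all positive.
    study_id : str
        Identifier of the study the volume belongs to.
    scanner_tag : str
        Free-form acquisition tag (e.g. ``"Philips-720"`` / ``"GE-672"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    study_id: str = ""
    scanner_tag: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("CTVolume requires a non-empty 3D grid")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CTVolume intensities must be finite")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class MaskVolume:
    """A binary 3D label grid (1 = lung parenchyma), geometry-aligned with a CTVolume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    study_id: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        uniq = np.unique(labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask labels must be exactly {{0,1}}, got values {uniq[:10]}")
        self.labels = labels.astype(np.uint8)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("MaskVolume requires a non-empty 3D grid")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def volume_voxels(self) -> int:
        return int(self.labels.sum())


@dataclass
class SlicePair:
    """One axial image/mask plane extracted from a study."""

    image: np.ndarray
    mask: np.ndarray
    study_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )
        if self.image.ndim != 2:
            raise ValueError("SlicePair holds 2D planes")


def check_aligned(vol: CTVolume, mask: MaskVolume) -> None:
    """Raise if a volume and mask do not share grid shape and spacing."""
    if vol.shape != mask.shape:
        raise ValueError(f"grid shape mismatch: {vol.shape} vs {mask.shape}")
    if not np.allclose(vol.spacing, mask.spacing):
        raise ValueError(f"spacing mismatch: {vol.spacing} vs {mask.spacing}")
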