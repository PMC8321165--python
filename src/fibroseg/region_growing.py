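"""HU-window seeded region growing and the unsupervised lung baseline.

Region growing isolates the connected component of voxels inside a Hounsfield
window (default −1024 to +200 HU) that contains a seed. The same primitive
also removes the trachea (grown from a seed in the airway and subtracted).
`segment_lungs_rg` wires these into a fully automatic baseline: threshold,
drop components touching the in-plane border (external air), keep the two
largest remaining components (the lungs) and subtract the trachea. Regions of
severe fibrosis exceed the window's upper bound, so this baseline misses them
— the deficit that motivates the learned models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTVolume, MaskVolume


@dataclass
class RegionGrowingConfig:
    """HU window and neighbourhood for seeded growing."""

    hu_low: float = -1024.0
    hu_high: float = 200.0
    connectivity: int = 6  # face (6) or face+edge+corner (26) neighbours

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise ValueError("hu_low must be below hu_high")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)


SeedPoint = tuple[int, int, int]


def _check_seed(seed: SeedPoint, shape: tuple[int, int, int]) -> SeedPoint:
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(not 0 <= s < n for s, n in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside grid of shape {shape}")
    return seed


def grow_region(vol: CTVolume, seed: SeedPoint,
                cfg: RegionGrowingConfig = RegionGrowingConfig()) -> MaskVolume:
    """Connected component of in-window voxels containing the seed.

    Returns an empty mask if the seed voxel itself is out of the HU window.
    """
    seed = _check_seed(seed, vol.shape)
    in_range = (vol.voxels >= cfg.hu_low) & (vol.voxels <= cfg.hu_high)
    out = np.zeros(vol.shape, dtype=np.uint8)
    if in_range[seed]:
        labels, _ = ndimage.label(in_range, structure=cfg.structure)
        out[labels == labels[seed]] = 1
    return MaskVolume(out, vol.spacing, vol.study_id)


def remove_trachea(lung_mask: MaskVolume, vol: CTVolume, trachea_seed: SeedPoint,
                   cfg: RegionGrowingConfig = RegionGrowingConfig()) -> MaskVolume:
    """Subtract the region grown from a tracheal seed; never adds voxels."""
    trachea = grow_region(vol, trachea_seed, cfg)
    out = lung_mask.labels & ~trachea.labels.astype(bool)
    return MaskVolume(out.astype(np.uint8), lung_mask.spacing, lung_mask.study_id)


def _border_touching(labels: np.ndarray) -> set[int]:
    """Component ids touching the in-plane (x/y) border on any axial plane."""
    edges = np.concatenate([
        labels[0, :, :].ravel(), labels[-1, :, :].ravel(),
        labels[:, 0, :].ravel(), labels[:, -1, :].ravel(),
    ])
    return set(np.unique(edges)) - {0}


def segment_lungs_rg(vol: CTVolume,
                     cfg: RegionGrowingConfig = RegionGrowingConfig()) -> MaskVolume:
    """Fully automatic region-growing lung segmentation.

    Threshold to the HU window; discard components touching the in-plane
    border (external air and anything connected to it, e.g. an open airway);
    keep the two largest remaining components; remove the trachea grown from
    the most superior remaining in-window centroid. Deterministic for a fixed
    volume and config (component-size ties break on the smaller centroid
    x-index).
    """
    in_range = (vol.voxels >= cfg.hu_low) & (vol.voxels <= cfg.hu_high)
    if not in_range.any():
        warnings.warn("no voxels inside the HU window; returning an empty mask")
        return MaskVolume(np.zeros(vol.shape, dtype=np.uint8), vol.spacing, vol.study_id)
    labels, n = ndimage.label(in_range, structure=cfg.structure)
    drop = _border_touching(labels)
    ids = [i for i in range(1, n + 1) if i not in drop]
    if not ids:
        warnings.warn("only border-touching components found; returning an empty mask")
        return MaskVolume(np.zeros(vol.shape, dtype=np.uint8), vol.spacing, vol.study_id)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, ids)
    centroids = ndimage.center_of_mass(in_range, labels, ids)
    ranked = sorted(zip(ids, sizes, centroids), key=lambda t: (-t[1], t[2][0]))
    keep = [t[0] for t in ranked[:2]]
    lungs = np.isin(labels, keep)

    # trachea seed: voxel of the most superior (largest z) in-window component
    # among the non-kept interior components; skip if none remains
    rest_ids = [i for i in ids if i not in keep]
    out = MaskVolume(lungs.astype(np.uint8), vol.spacing, vol.study_id)
    if rest_ids:
        rest_centroids = ndimage.center_of_mass(in_range, labels, rest_ids)
        top = max(zip(rest_ids, rest_centroids), key=lambda t: t[1][2])[0]
        coords = np.argwhere(labels == top)
        seed = tuple(coords[0])
        out = remove_trachea(out, vol, seed, cfg)
    return out
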