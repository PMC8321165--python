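"""Synthetic HRCT-like phantoms with exact ground-truth lung masks.

A phantom is a torso-like scene built from standard tissue HU levels: air
background (−1000), an ellipsoidal soft-tissue body (+40), two ellipsoidal
lungs (−800), an air-filled trachea tube (−1000) sealed by a cartilage wall,
optional mild fibrotic patches inside the lungs (in the −300…+100 range) and
optional severe peripheral fibrosis (+250, above the region-growing window).
Each lung (and the trachea) is wrapped in a thin dense rim (+300 HU, the
pleural line / tracheal cartilage), so the HU window [−1024, +200] used by
the region-growing baseline is exactly bounded: on a noise-free phantom with
no severe disease, seeded growing recovers each lung voxel-for-voxel.

The soft-tissue body is itself inside the HU window but touches the exterior
air with no high-HU barrier, so it joins the border-touching component that
the automatic baseline discards; the interior in-window components are then
exactly the two rim-sealed lungs plus the small trachea lumen. Ground truth =
the exact lung ellipsoid voxel sets (patches included, trachea excluded).
Gaussian HU noise is added last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume import CTVolume, MaskVolume


@dataclass
class PhantomConfig:
    """Geometry and HU palette of one synthetic study.

    Lengths are fractions of the half-plane (in-plane) or of the slice count
    (z), so one config scales across matrix sizes.
    """

    inplane: int = 512
    slices: int = 60
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    hu_air: float = -1000.0
    hu_body: float = 40.0
    hu_lung: float = -800.0
    hu_rim: float = 300.0       # pleural line / tracheal cartilage (out of window)
    hu_mild_patch: float = -200.0   # ground-glass-like, inside the window
    hu_severe_patch: float = 250.0  # dense fibrosis, above the window

    body_semi: tuple[float, float] = (0.93, 0.68)   # of half-plane
    body_z_semi: float = 0.98                       # of half-stack
    lung_center_x: float = 0.46
    lung_semi: tuple[float, float] = (0.38, 0.50)
    lung_z_semi: float = 0.94
    rim_voxels: float = 1.5

    trachea_radius: float = 0.05    # of half-plane
    trachea_center_y: float = -0.25

    n_mild_patches: int = 0
    mild_patch_semi: float = 0.10   # of half-plane
    severe_fraction: float = 0.0    # target fraction of lung volume, 0 disables

    noise_sd: float = 0.0           # HU

    def validate(self) -> None:
        if self.inplane < 16 or self.slices < 4:
            raise ValueError("grid too small for the phantom geometry")
        if self.lung_center_x + self.lung_semi[0] >= self.body_semi[0]:
            raise ValueError("lungs extend outside the body")
        if self.lung_semi[1] >= self.body_semi[1]:
            raise ValueError("lungs extend outside the body")
        for hu in (self.hu_air, self.hu_body, self.hu_lung, self.hu_rim,
                   self.hu_mild_patch, self.hu_severe_patch):
            if not -1024 <= hu <= 3071:
                raise ValueError(f"HU level {hu} outside [-1024, 3071]")


@dataclass
class PhantomStudy:
    volume: CTVolume
    truth: MaskVolume
    config: PhantomConfig
    seed: int
    lung_semi_axes_mm: tuple[tuple[float, float, float], tuple[float, float, float]] = field(default=None)


def _ellipsoid_sq(xx, yy, zz, cx, cy, cz, a, b, c):
    """Normalized squared radius of an axis-aligned ellipsoid (<=1 inside)."""
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 + ((zz - cz) / c) ** 2


def generate_phantom(cfg: PhantomConfig | None = None, seed: int = 0) -> PhantomStudy:
    """Render one phantom study; deterministic for a fixed config and seed."""
    cfg = cfg or PhantomConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    m, nz = cfg.inplane, cfg.slices
    h, hz = (m - 1) / 2.0, (nz - 1) / 2.0
    xx, yy, zz = np.meshgrid(np.arange(m) - h, np.arange(m) - h,
                             np.arange(nz) - hz, indexing="ij")

    vol = np.full((m, m, nz), cfg.hu_air, dtype=np.float32)

    body = _ellipsoid_sq(xx, yy, zz, 0, 0, 0, cfg.body_semi[0] * h,
                         cfg.body_semi[1] * h, cfg.body_z_semi * hz) <= 1.0
    vol[body] = cfg.hu_body

    a, b = cfg.lung_semi[0] * h, cfg.lung_semi[1] * h
    c = cfg.lung_z_semi * hz
    rim_a = cfg.rim_voxels
    truth = np.zeros((m, m, nz), dtype=np.uint8)
    lung_axes_mm = []
    for side in (-1, +1):
        cx = side * cfg.lung_center_x * h
        u = _ellipsoid_sq(xx, yy, zz, cx, 0, 0, a, b, c)
        # rim: a thin shell just outside the lung surface
        u_out = _ellipsoid_sq(xx, yy, zz, cx, 0, 0, a + rim_a, b + rim_a, c + rim_a)
        vol[(u > 1.0) & (u_out <= 1.0)] = cfg.hu_rim
        lung = u <= 1.0
        vol[lung] = cfg.hu_lung
        truth[lung] = 1

        if cfg.n_mild_patches > 0:
            for _ in range(cfg.n_mild_patches):
                # random blob well inside the lung
                pc = (cx + rng.uniform(-0.4, 0.4) * a,
                      rng.uniform(-0.4, 0.4) * b,
                      rng.uniform(-0.4, 0.4) * c)
                ps = cfg.mild_patch_semi * h
                patch = _ellipsoid_sq(xx, yy, zz, *pc, ps, ps, ps) <= 1.0
                vol[patch & lung] = cfg.hu_mild_patch

        if cfg.severe_fraction > 0:
            # peripheral posterior-basal shell wedge, the IPF-like distribution;
            # the quadrant shell of depth d holds (1-(1-d)^3)/4 of the lung
            depth = 1.0 - (1.0 - min(4.0 * cfg.severe_fraction, 0.97)) ** (1.0 / 3.0)
            wedge = lung & (u >= (1.0 - depth) ** 2) & (yy > 0) & (zz < 0)
            vol[wedge] = cfg.hu_severe_patch

        lung_axes_mm.append((a * cfg.spacing[0], b * cfg.spacing[1], c * cfg.spacing[2]))

    # sealed trachea: cartilage-walled air tube in the anterior mediastinum,
    # upper half of the stack
    tr = cfg.trachea_radius * h
    ty = cfg.trachea_center_y * h
    # keep the tube (and its wall) well inside the narrowing body ellipsoid
    z_top, z_bot = cfg.body_z_semi * hz * 0.78, 0.0
    rr = xx ** 2 + (yy - ty) ** 2
    wall_band = (rr <= (tr + rim_a) ** 2) & (zz <= z_top + rim_a) & (zz >= z_bot - rim_a)
    vol[wall_band & body & (truth == 0)] = cfg.hu_rim
    tube = (rr <= tr ** 2) & (zz <= z_top) & (zz >= z_bot) & body & (truth == 0)
    vol[tube] = cfg.hu_air
    truth[tube] = 0  # trachea is never parenchyma

    if cfg.noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd, vol.shape).astype(np.float32)
        np.clip(vol, -1024.0, 3071.0, out=vol)

    study_id = f"phantom-{seed}"
    volume = CTVolume(vol, cfg.spacing, study_id, f"synthetic-{m}")
    mask = MaskVolume(truth, cfg.spacing, study_id)
    return PhantomStudy(volume, mask, cfg, seed, tuple(lung_axes_mm))


def generate_cohort(n_studies: int, cfg_template: PhantomConfig | None = None,
                    seed: int = 0, sizes: tuple[int, ...] = (720, 672),
                    size_weights: tuple[float, ...] = (11 / 42, 31 / 42)) -> list[PhantomStudy]:
    """A cohort of phantoms with per-study randomized geometry.

    In-plane matrix sizes are drawn from `sizes` (default 720/672 in the
    11:31 ratio of the emulated two-scanner cohort); each study's lung
    geometry is jittered a few percent. The scanner tag records the size for
    stratified splitting.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    cfg_template = cfg_template or PhantomConfig()
    rng = np.random.default_rng(seed)
    studies = []
    for i in range(n_studies):
        size = int(rng.choice(sizes, p=np.asarray(size_weights) / sum(size_weights)))
        jitter = lambda v, lo=0.96, hi=1.04: v * rng.uniform(lo, hi)
        fov_mm = 360.0
        cfg = replace(
            cfg_template,
            inplane=size,
            spacing=(fov_mm / size, fov_mm / size, cfg_template.spacing[2]),
            lung_center_x=jitter(cfg_template.lung_center_x, 0.98, 1.02),
            lung_semi=(jitter(cfg_template.lung_semi[0]), jitter(cfg_template.lung_semi[1])),
            lung_z_semi=jitter(cfg_template.lung_z_semi, 0.97, 1.0),
        )
        studies.append(generate_phantom(cfg, seed=int(rng.integers(2 ** 31))))
    return studies
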