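"""Reading and writing CT volumes and masks.

NIfTI (.nii / .nii.gz) via nibabel and DICOM series (a directory of .dcm
files) via pydicom; DICOM intensities are converted to HU with the rescale
slope/intercept. Written NIfTI carries the voxel spacing on the affine
diagonal.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .volume import CTVolume, MaskVolume


def read_nifti_volume(path: str | Path, study_id: str = "",
                      scanner_tag: str = "") -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data, spacing, study_id or Path(path).stem, scanner_tag)


def read_nifti_mask(path: str | Path, study_id: str = "") -> MaskVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskVolume((data > 0).astype(np.uint8), spacing, study_id or Path(path).stem)


def write_nifti(vol: CTVolume | MaskVolume, path: str | Path) -> None:
    data = vol.voxels if isinstance(vol, CTVolume) else vol.labels
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_dicom_series(directory: str | Path, study_id: str = "",
                      scanner_tag: str = "") -> CTVolume:
    """Load a directory of .dcm axial slices, sorted by physical z position."""
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise ValueError(f"no .dcm files under {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    planes = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    vol = np.stack(planes, axis=2)
    first = datasets[0]
    px = getattr(first, "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1:
        dz = abs(z_of(datasets[1]) - z_of(datasets[0])) or 1.0
    else:
        dz = float(getattr(first, "SliceThickness", 1.0) or 1.0)
    spacing = (float(px[0]), float(px[1]), dz)
    return CTVolume(vol, spacing, study_id or directory.name, scanner_tag)
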