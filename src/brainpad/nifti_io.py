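"""NIfTI reading/writing for phantom (or real, pre-segmented) tissue maps.

Maps are stored one file per subject and tissue class as float32 NIfTI-1
images; phantom maps are 1-D voxel vectors stored with shape ``(p, 1, 1)``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["write_map", "read_map", "write_cohort_maps", "read_cohort_maps"]


def write_map(values, path) -> Path:
    """Write a voxel vector (or array) as a float32 NIfTI image."""
    arr = np.asarray(values, dtype=np.float32)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1, 1)
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_map(path) -> np.ndarray:
    """Read a NIfTI image back as a flat float32 voxel vector."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(dtype=np.float32)).ravel()


def write_cohort_maps(cohort, outdir) -> Path:
    """Write per-subject ``<id>_gm.nii.gz`` / ``<id>_wm.nii.gz`` files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = cohort.phenotypes["id"].tolist()
    for i, sid in enumerate(ids):
        write_map(cohort.gm[i], outdir / f"{sid}_gm.nii.gz")
        write_map(cohort.wm[i], outdir / f"{sid}_wm.nii.gz")
    return outdir


def read_cohort_maps(ids, imgdir) -> tuple[np.ndarray, np.ndarray]:
    """Load the per-subject maps for ``ids`` back into (gm, wm) matrices."""
    imgdir = Path(imgdir)
    gm = np.stack([read_map(imgdir / f"{sid}_gm.nii.gz") for sid in ids])
    wm = np.stack([read_map(imgdir / f"{sid}_wm.nii.gz") for sid in ids])
    return gm, wm
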