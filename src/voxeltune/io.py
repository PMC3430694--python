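"""File-format glue: events/beta TSVs and NIfTI timeseries/ROI handling.

Synthetic voxel populations have no spatial layout, so when a NIfTI
representation is requested the voxels are arranged in a compact cuboid; the
inverse mask-based extraction accepts any user-supplied geometry.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import CONDITIONS
from .glm import BetaArray

__all__ = [
    "write_tsv",
    "read_tsv",
    "save_timeseries_nifti",
    "load_roi_timeseries",
    "load_beta_volumes",
]

_FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV deterministically (fixed float formatting, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    # "null" is a trial_type level, not a missing value
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def _cuboid_shape(n_voxels: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_voxels ** (1 / 3)))
    ny = int(np.ceil(np.sqrt(n_voxels / side)))
    nz = int(np.ceil(n_voxels / (side * ny)))
    return side, ny, nz


def save_timeseries_nifti(
    path: str | Path,
    timeseries: np.ndarray,
    tr_s: float = 2.0,
    voxel_size_mm: float = 3.0,
) -> nib.Nifti1Image:
    """Store an (n_volumes, n_voxels) series as a 4-D NIfTI.

    Voxels fill a compact cuboid in C order; unused positions are zero.  A
    companion binary mask image marking the occupied voxels is written next
    to it with suffix ``_mask``.
    """
    path = Path(path)
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    n_vol, n_vox = ts.shape
    shape = _cuboid_shape(n_vox)
    vol = np.zeros((*shape, n_vol))
    flat = vol.reshape(-1, n_vol)
    flat[:n_vox] = ts.T
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((*[voxel_size_mm] * 3, tr_s))
    nib.save(img, path)
    mask = np.zeros(shape, dtype=np.uint8)
    mask.reshape(-1)[:n_vox] = 1
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    mask_path = path.with_name(stem + "_mask.nii")
    nib.save(nib.Nifti1Image(mask, affine), mask_path)
    return img


def load_roi_timeseries(
    image: str | Path | nib.Nifti1Image, mask: str | Path | nib.Nifti1Image
) -> np.ndarray:
    """Extract an (n_volumes, n_voxels) matrix from a 4-D image and ROI mask."""
    img = image if isinstance(image, nib.Nifti1Image) else nib.load(str(image))
    msk = mask if isinstance(mask, nib.Nifti1Image) else nib.load(str(mask))
    m = np.asarray(msk.dataobj) > 0
    data = np.asarray(img.dataobj)
    if data.shape[:3] != m.shape:
        raise ValueError("mask and image grids disagree")
    return data[m].T  # (n_volumes, n_voxels)


def load_beta_volumes(
    beta_images: list[list[str | Path | nib.Nifti1Image]],
    mask: str | Path | nib.Nifti1Image,
) -> BetaArray:
    """Assemble a BetaArray from per-run, per-condition beta volumes.

    ``beta_images[r][c]`` is the 3-D beta image of run ``r`` and condition
    ``CONDITIONS[c]``; voxels are read through the ROI mask.
    """
    msk = mask if isinstance(mask, nib.Nifti1Image) else nib.load(str(mask))
    m = np.asarray(msk.dataobj) > 0
    runs = []
    for row in beta_images:
        if len(row) != len(CONDITIONS):
            raise ValueError("each run needs one beta image per condition")
        vols = []
        for img in row:
            img = img if isinstance(img, nib.Nifti1Image) else nib.load(str(img))
            data = np.asarray(img.dataobj)
            if data.shape != m.shape:
                raise ValueError("mask and beta image grids disagree")
            vols.append(data[m])
        runs.append(vols)
    return BetaArray(values=np.asarray(runs, dtype=float))
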