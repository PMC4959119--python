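"""Gray-matter volume preparation: smoothing, masking, flattening.

The pipeline consumes already-modulated gray-matter maps (one 3-D volume
per subject) plus a binary mask, smooths each volume with a Gaussian
kernel specified by its full width at half maximum, and flattens the
in-mask voxels into a subjects x voxels matrix.  Voxel ordering is fixed:
lexicographic over grid coordinates with the x axis fastest (Fortran
order), recorded in ``PhenotypeMatrix.voxel_index_map``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage

from .datatypes import PhenotypeMatrix

__all__ = [
    "FWHM_TO_SIGMA",
    "gaussian_smooth",
    "mask_and_flatten",
    "unflatten_map",
    "load_nifti",
    "save_nifti",
]

# sigma = FWHM / sqrt(8 ln 2); the denominator is ~2.3548
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float = 4.0,
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D volume.

    Per-axis sigma in voxels is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size``.
    The kernel is truncated at 4 sigma and normalized to unit mass;
    boundaries are zero-padded (plain truncation, no edge renormalization).
    ``fwhm_mm = 0`` is the identity.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={volume.ndim}")
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return volume.copy()
    vs = np.asarray(voxel_size_mm, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValueError("voxel_size_mm must be 3 positive values")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vs
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="constant", cval=0.0, truncate=4.0)


def mask_and_flatten(
    volumes: Sequence[np.ndarray],
    mask: np.ndarray,
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> PhenotypeMatrix:
    """Stack per-subject volumes into a subjects x in-mask-voxels matrix."""
    mask = np.asarray(mask, dtype=bool)
    support = np.flatnonzero(mask.reshape(-1, order="F"))
    rows = []
    for i, vol in enumerate(volumes):
        vol = np.asarray(vol, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"subject {i}: volume shape {vol.shape} != mask {mask.shape}")
        rows.append(vol.reshape(-1, order="F")[support])
    return PhenotypeMatrix(
        values=np.array(rows),
        mask=mask,
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        voxel_index_map=support,
    )


def unflatten_map(row_vector: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Inverse of :func:`mask_and_flatten` for one row; zeros off-mask."""
    mask = np.asarray(mask, dtype=bool)
    row_vector = np.asarray(row_vector, dtype=float)
    support = np.flatnonzero(mask.reshape(-1, order="F"))
    if row_vector.size != support.size:
        raise ValueError(
            f"vector length {row_vector.size} != mask support {support.size}"
        )
    flat = np.zeros(mask.size)
    flat[support] = row_vector
    return flat.reshape(mask.shape, order="F")


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume; returns (data, affine, voxel sizes in mm)."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), img.affine, zooms


def save_nifti(
    volume: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a volume as NIfTI-1, defaulting to a diagonal scaling affine."""
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))
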