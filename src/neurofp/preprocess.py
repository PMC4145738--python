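"""Preprocessing: isotropic Gaussian smoothing and averaging over the
diffusion-weighted volumes.

Inputs are assumed already co-registered to a symmetric template space;
spatial normalization itself is outside this package's scope.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io import DwiImage

__all__ = ["fwhm_to_sigma", "gaussian_smooth", "mean_over_gradients"]

_FWHM_FACTOR = np.sqrt(8.0 * np.log(2.0))  # fwhm = sigma * 2 sqrt(2 ln 2)


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / _FWHM_FACTOR


def gaussian_smooth(image: DwiImage, fwhm_mm: float) -> DwiImage:
    """Smooth each 3D volume with an isotropic Gaussian of the given FWHM
    (mm), converted per-axis to voxel units.  Reflective boundaries keep
    the grid-wide mean intensity conserved."""
    if fwhm_mm < 0:
        raise ValidationError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return image
    sigma_vox = fwhm_to_sigma(fwhm_mm) / image.voxel_size
    out = np.empty_like(image.data)
    for i in range(image.data.shape[3]):
        out[..., i] = ndimage.gaussian_filter(image.data[..., i], sigma_vox, mode="reflect")
    return DwiImage(out, image.voxel_size, image.scheme)


def mean_over_gradients(image: DwiImage, include_b0: bool = False) -> np.ndarray:
    """Voxelwise arithmetic mean over the diffusion-weighted volumes
    (b=0 excluded by default), collapsing the 4D image to one 3D image."""
    idx = (
        np.arange(len(image.scheme))
        if include_b0
        else image.scheme.dwi_indices
    )
    if idx.size == 0:
        raise ValidationError("no volumes selected for averaging")
    return image.data[..., idx].mean(axis=3)
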