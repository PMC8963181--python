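"""Spatial smoothing by Gaussian convolution restricted to a mask.

The kernel is renormalized over the in-mask neighbourhood of every voxel,
so values outside the mask never leak in and constant fields are preserved
exactly inside the mask:

    out(v) = sum_{u in mask} w(u - v) x(u) / sum_{u in mask} w(u - v)

with a per-axis sigma of ``fwhm_mm / (2 sqrt(2 ln 2)) / voxel_size`` and
truncation at 4 sigma.  Output is zero outside the mask.  The stage is
stateless, so online and offline application are identical.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .pipeline import ConfigError, Stage
from .volume import VolumeSample, voxel_sizes

__all__ = ["SmoothStage", "smooth_in_mask", "fwhm_to_sigma"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm * _FWHM_TO_SIGMA


def smooth_in_mask(vol: VolumeSample, fwhm_mm: float,
                   mask: np.ndarray) -> VolumeSample:
    if fwhm_mm < 0:
        raise ConfigError("fwhm_mm must be non-negative")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ConfigError("smoothing mask is empty")
    data = np.asarray(vol.data, dtype=np.float64)
    if fwhm_mm == 0:
        return vol.with_data(np.where(mask, data, 0.0))
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_sizes(vol.affine)
    m = mask.astype(np.float64)
    num = ndimage.gaussian_filter(data * m, sigma_vox, truncate=4.0,
                                  mode="constant")
    den = ndimage.gaussian_filter(m, sigma_vox, truncate=4.0, mode="constant")
    out = np.zeros_like(data)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return vol.with_data(out)


class SmoothStage(Stage):
    """Masked Gaussian smoothing pipeline stage."""

    name = "smooth"

    def __init__(self, fwhm_mm: float, mask: np.ndarray, **kw):
        super().__init__(**kw)
        if fwhm_mm < 0:
            raise ConfigError("fwhm_mm must be non-negative")
        self.fwhm_mm = fwhm_mm
        self.mask = np.asarray(mask).astype(bool)

    def _proc(self, vol: VolumeSample) -> list[VolumeSample]:
        return [smooth_in_mask(vol, self.fwhm_mm, self.mask)]
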