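"""Mask arithmetic for the real-time pipeline.

EPI automask, union/intersection, and iterative 6-connected binary
erosion.  The real-time processing (RTP) mask is the union of the
anatomical brain mask and the EPI automask; the global-signal (GSR) mask
is their intersection, so GSR is a subset of RTP by construction.  White
matter masks are eroded by two voxels and ventricle masks by one before
use as tissue-mean regressor supports.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume import VolumeSample

__all__ = ["epi_automask", "combine", "erode", "make_regression_masks",
           "WM_ERODE_ITERS", "VENT_ERODE_ITERS"]

WM_ERODE_ITERS = 2
VENT_ERODE_ITERS = 1

# 6-connected (face-adjacent) structuring element
_STRUCT = ndimage.generate_binary_structure(3, 1)


def epi_automask(vol: VolumeSample) -> np.ndarray:
    """Intensity-based brain mask from an EPI volume.

    Threshold at half the mean of above-global-mean voxels, keep the
    largest 6-connected component, fill enclosed holes.
    """
    data = np.asarray(vol.data, dtype=float)
    gmean = data.mean()
    bright = data[data > gmean]
    if bright.size == 0:
        raise ValueError("automask failed: no voxels above the global mean")
    mask = data >= 0.5 * bright.mean()
    labels, n = ndimage.label(mask, structure=_STRUCT)
    if n == 0:
        raise ValueError("automask failed: empty mask")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask, structure=_STRUCT)


def combine(a: np.ndarray, b: np.ndarray, op: str) -> np.ndarray:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask geometry mismatch: {a.shape} vs {b.shape}")
    if op == "union":
        return a | b
    if op == "intersect":
        return a & b
    raise ValueError(f"op must be 'union' or 'intersect', got {op!r}")


def erode(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if iterations == 0:
        return mask.copy()
    out = ndimage.binary_erosion(mask, structure=_STRUCT,
                                 iterations=iterations)
    if not out.any():
        warnings.warn("erosion produced an empty mask")
    return out


def make_regression_masks(brain: np.ndarray, epi: VolumeSample,
                          wm: np.ndarray | None = None,
                          vent: np.ndarray | None = None) -> dict:
    """RTP / GSR masks from brain + EPI automask, plus eroded WM/ventricle."""
    auto = epi_automask(epi)
    out = {
        "rtp": combine(brain, auto, "union"),
        "gsr": combine(brain, auto, "intersect"),
    }
    if wm is not None:
        out["wm"] = erode(wm, WM_ERODE_ITERS)
    if vent is not None:
        out["vent"] = erode(vent, VENT_ERODE_ITERS)
    return out
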