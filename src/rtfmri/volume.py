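"""Volume data model and NIfTI I/O.

The unit flowing through the real-time pipeline is a single 3D brain
volume (:class:`VolumeSample`) carrying its voxel grid, the voxel-to-mm
affine, the 0-based acquisition index and the onset time in seconds from
the start of the run.  Run-constant acquisition parameters (TR, slice
timing, initial volumes to discard) live in :class:`RunMeta`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeSample",
    "RunMeta",
    "FormatError",
    "read_volume",
    "write_volume",
    "write_series",
    "parse_index",
    "voxel_sizes",
]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as a single 3D NIfTI volume."""


@dataclass
class VolumeSample:
    """One 3D brain volume moving through the pipeline.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in arbitrary signal units.
    affine : ndarray, shape (4, 4)
        Voxel-index to mm coordinate map (NIfTI convention).
    index : int
        0-based acquisition index; strictly increasing along a stream.
    onset_s : float
        Seconds from run start (``index * TR``).
    """

    data: np.ndarray
    affine: np.ndarray
    index: int = 0
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"VolumeSample requires a 3D grid, got shape {self.data.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VolumeSample":
        """Copy of this sample with new voxel data on the same grid."""
        return replace(self, data=data)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asanyarray(self.data), self.affine)


@dataclass
class RunMeta:
    """Run-constant acquisition parameters.

    ``slice_times_s`` holds per-slice acquisition offsets within one TR
    (seconds); all offsets must satisfy ``0 <= t < tr_s``.  ``ignore_init``
    volumes at the start of the run are discarded before any processing.
    """

    tr_s: float
    n_slices: int
    slice_times_s: np.ndarray | None = None
    ignore_init: int = 0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.slice_times_s is None:
            # ascending-sequential acquisition by default
            self.slice_times_s = np.arange(self.n_slices) * self.tr_s / self.n_slices
        self.slice_times_s = np.asarray(self.slice_times_s, dtype=float)
        if len(self.slice_times_s) != self.n_slices:
            raise ValueError("slice_times_s length must equal n_slices")
        if np.any(self.slice_times_s < 0) or np.any(self.slice_times_s >= self.tr_s):
            raise ValueError("slice times must lie in [0, tr_s)")

    @classmethod
    def interleaved(cls, tr_s: float, n_slices: int, **kw) -> "RunMeta":
        """Odd-first interleaved slice order (0, 2, 4, ..., 1, 3, ...)."""
        order = np.concatenate(
            [np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)]
        )
        times = np.empty(n_slices)
        times[order] = np.arange(n_slices) * tr_s / n_slices
        return cls(tr_s=tr_s, n_slices=n_slices, slice_times_s=times, **kw)


_INDEX_RE = re.compile(r"(\d+)(?!.*\d)")


def parse_index(path: str | Path) -> int:
    """Acquisition index from the last integer group in the file name.

    ``vol_0007.nii`` -> 7.  Raises :class:`FormatError` when the name
    contains no digits.
    """
    m = _INDEX_RE.search(Path(path).stem.replace(".nii", ""))
    if m is None:
        raise FormatError(f"no numeric index in filename: {path}")
    return int(m.group(1))


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel sizes (mm) from the affine's linear part."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def read_volume(path: str | Path, tr_s: float | None = None) -> VolumeSample:
    """Read a single-volume NIfTI file into a :class:`VolumeSample`.

    The acquisition index is parsed from the filename's numeric suffix;
    ``onset_s`` is ``index * tr_s`` when a TR is given, else 0.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several load error types
        raise FormatError(f"cannot read NIfTI volume: {path} ({exc})") from exc
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise FormatError(
                f"{path} holds {data.shape[3]} frames; expected a single 3D volume"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path} is {data.ndim}D; expected a 3D volume")
    idx = parse_index(path)
    onset = idx * tr_s if tr_s else 0.0
    return VolumeSample(data=data, affine=img.affine, index=idx, onset_s=onset)


def write_volume(vol: VolumeSample, path: str | Path) -> Path:
    path = Path(path)
    nib.save(vol.to_nifti(), str(path))
    return path


def write_series(vols: list[VolumeSample], path: str | Path) -> Path:
    """Concatenate volumes (index order) into a 4D NIfTI file."""
    path = Path(path)
    if not vols:
        raise ValueError("no volumes to write")
    vols = sorted(vols, key=lambda v: v.index)
    data = np.stack([v.data for v in vols], axis=-1)
    nib.save(nib.Nifti1Image(data, vols[0].affine), str(path))
    return path
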