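"""Online slice-timing correction.

Every slice is resampled in time to the acquisition moment of the earliest
slice, so no extrapolation into the future is needed.  Two temporal
interpolators are available:

* ``linear`` — uses the present and one past sample; identical to offline
  processing.
* ``cubic`` (default) — a 4-point Lagrange polynomial through samples
  ``k-2, k-1, k, k+1``, where the unavailable future sample ``x[k+1]`` is
  replaced by a pseudo point with the present value ``x[k]``.

Cold start: volume 0 passes unshifted, volume 1 is shifted linearly
regardless of method, and the cubic stencil starts at index 2.
"""

from __future__ import annotations

import numpy as np

from .pipeline import ConfigError, Stage
from .volume import RunMeta, VolumeSample

__all__ = ["TshiftStage", "tshift_offline", "lagrange_weights"]


def lagrange_weights(nodes: np.ndarray, x: float) -> np.ndarray:
    """Weights of Lagrange interpolation at ``x`` through unit-spaced ``nodes``."""
    nodes = np.asarray(nodes, dtype=float)
    w = np.ones_like(nodes)
    for j in range(len(nodes)):
        for m in range(len(nodes)):
            if m != j:
                w[j] *= (x - nodes[m]) / (nodes[j] - nodes[m])
    return w


class TshiftStage(Stage):
    """Slice-timing correction pipeline stage.

    Parameters
    ----------
    meta : RunMeta
        Supplies TR and per-slice acquisition times.
    method : {"cubic", "linear"}
        Temporal interpolation scheme (cubic is the default).
    slice_axis : int
        Axis of ``VolumeSample.data`` along which slices are stacked.
    """

    name = "tshift"

    def __init__(self, meta: RunMeta, method: str = "cubic",
                 slice_axis: int = 2, **kw):
        super().__init__(**kw)
        if method not in ("linear", "cubic"):
            raise ConfigError(f"unknown tshift method: {method!r}")
        self.meta = meta
        self.method = method
        self.slice_axis = slice_axis
        # fractional shift of each slice, in TR units, relative to the
        # earliest-acquired slice: delta_s in [0, 1)
        t = np.asarray(meta.slice_times_s, dtype=float)
        self.slice_shift_frac = (t - t.min()) / meta.tr_s
        self._buffer: list[np.ndarray] = []  # last volumes, oldest first

    def _reset(self) -> None:
        self._buffer = []

    # weights for value at time k - delta given samples at k-1, k
    def _linear_shift(self, prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
        d = self._bcast(self.slice_shift_frac)
        out = cur * (1.0 - d) + prev * d
        return self._restore_unshifted(out, cur)

    # 4-point Lagrange through k-2, k-1, k, k+1 with pseudo x[k+1] := x[k]
    def _cubic_shift(self, p2: np.ndarray, p1: np.ndarray,
                     cur: np.ndarray) -> np.ndarray:
        d = self.slice_shift_frac
        nz = len(d)
        w = np.empty((4, nz))
        for s in range(nz):
            w[:, s] = lagrange_weights(np.array([-2.0, -1.0, 0.0, 1.0]), -d[s])
        w_m2 = self._bcast(w[0])
        w_m1 = self._bcast(w[1])
        w_0 = self._bcast(w[2] + w[3])  # pseudo future point folds into present
        out = p2 * w_m2 + p1 * w_m1 + cur * w_0
        return self._restore_unshifted(out, cur)

    def _bcast(self, per_slice: np.ndarray) -> np.ndarray:
        shape = [1, 1, 1]
        shape[self.slice_axis] = len(per_slice)
        return np.asarray(per_slice).reshape(shape)

    def _restore_unshifted(self, out: np.ndarray, cur: np.ndarray) -> np.ndarray:
        """Earliest-acquired slices (delta == 0) are never modified."""
        zero = self.slice_shift_frac == 0.0
        if np.any(zero):
            sl = [slice(None)] * 3
            sl[self.slice_axis] = zero
            out[tuple(sl)] = cur[tuple(sl)]
        return out

    def _proc(self, vol: VolumeSample) -> list[VolumeSample]:
        cur = np.asarray(vol.data, dtype=np.float64)
        n = len(self._buffer)
        if n == 0:
            out = cur  # cold start: first volume passes unshifted
        elif n == 1 or self.method == "linear":
            out = self._linear_shift(self._buffer[-1], cur)
        else:
            out = self._cubic_shift(self._buffer[-2], self._buffer[-1], cur)
        self._buffer.append(cur)
        if len(self._buffer) > 3:
            self._buffer.pop(0)
        return [vol.with_data(out)]


def tshift_offline(series: np.ndarray, meta: RunMeta, method: str = "cubic",
                   slice_axis: int = 2) -> np.ndarray:
    """Apply the identical per-TR shift rule to a full 4D series at once.

    Replays the online stage volume-by-volume; exists as the batch
    counterpart for the online-equals-offline checks.
    """
    stage = TshiftStage(meta, method=method, slice_axis=slice_axis)
    stage.ready()
    out = np.empty_like(series, dtype=np.float64)
    eye = np.eye(4)
    for k in range(series.shape[-1]):
        res = stage._proc(VolumeSample(series[..., k], eye, index=k))
        out[..., k] = res[0].data
    return out
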