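"""Rigid-body motion correction.

Each incoming volume is registered to a fixed reference by minimizing the
weighted sum of squared intensity differences over six rigid parameters
(three rotations in degrees, three translations in mm), using Gauss-Newton
iterations with a numerically differentiated Jacobian.  The registered
volume is then resliced with separable 1D Lagrange interpolation of order
1 (linear), 3 (cubic) or 7 (heptic, the default, matching the common
offline choice for reslicing quality).

Conventions
-----------
* Rotations are applied in the fixed order ``Rz @ Ry @ Rx`` about the
  volume center in mm space; translations follow.
* ``resample_rigid(vol, t)`` samples ``vol`` at ``T(x) = R (x - c) + c + s``
  for each output mm location ``x``.  Consequently a volume whose content
  moved by ``t`` relative to the reference is realigned by resampling it
  with the same ``t``, and :func:`apply_motion` (used by the synthetic
  phantom) applies the inverse map to *create* such a moved volume.
* Out-of-volume samples clamp to the nearest edge voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pipeline import Stage
from .volume import VolumeSample

__all__ = [
    "RigidTransform",
    "VolregStage",
    "estimate_motion",
    "resample_rigid",
    "apply_motion",
    "volreg_offline",
    "lagrange_resample",
]

_ORDER_NPTS = {1: 2, 3: 4, 7: 8}
_INTERP_ORDER = {"linear": 1, "cubic": 3, "heptic": 7}


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid motion estimate.

    ``rot_deg`` are rotations (degrees) about the x, y, z axes of the mm
    coordinate frame through the volume center, composed as Rz @ Ry @ Rx;
    ``shift_mm`` are translations in mm.  Logged column order is
    (rot_x, rot_y, rot_z, shift_x, shift_y, shift_z).
    """

    rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def params(self) -> np.ndarray:
        return np.array(self.rot_deg + self.shift_mm, dtype=float)

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]))

    def matrix(self) -> np.ndarray:
        """Rotation matrix Rz @ Ry @ Rx from the stored angles."""
        ax, ay, az = np.deg2rad(self.rot_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    @classmethod
    def from_matrix(cls, rot: np.ndarray, shift: np.ndarray) -> "RigidTransform":
        """Recover (Rz@Ry@Rx) Euler angles and shifts from a rotation matrix."""
        ay = np.arcsin(np.clip(-rot[2, 0], -1.0, 1.0))
        ax = np.arctan2(rot[2, 1], rot[2, 2])
        az = np.arctan2(rot[1, 0], rot[0, 0])
        return cls(tuple(np.rad2deg([ax, ay, az])), tuple(np.asarray(shift, float)))

    def inverse(self) -> "RigidTransform":
        r = self.matrix()
        s = np.asarray(self.shift_mm)
        return RigidTransform.from_matrix(r.T, -r.T @ s)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        ra, rb = self.matrix(), other.matrix()
        sa, sb = np.asarray(self.shift_mm), np.asarray(other.shift_mm)
        return RigidTransform.from_matrix(ra @ rb, ra @ sb + sa)


def _grid_center_mm(shape, affine) -> np.ndarray:
    center_vox = (np.asarray(shape, float) - 1.0) / 2.0
    return affine[:3, :3] @ center_vox + affine[:3, 3]


def _source_voxel_coords(shape, affine, t: RigidTransform) -> np.ndarray:
    """Voxel coordinates in the moving volume for every output voxel."""
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    mm = affine[:3, :3] @ vox + affine[:3, 3:4]
    c = _grid_center_mm(shape, affine)[:, None]
    src_mm = t.matrix() @ (mm - c) + c + np.asarray(t.shift_mm, float)[:, None]
    inv = np.linalg.inv(affine)
    return inv[:3, :3] @ src_mm + inv[:3, 3:4]


def _lagrange_axis_weights(coord: np.ndarray, npts: int):
    """Per-axis stencil base indices and Lagrange weights for unit-spaced nodes."""
    base = np.floor(coord).astype(np.int64) - (npts // 2 - 1)
    f = coord - base  # position relative to the first stencil node
    w = np.ones((coord.size, npts))
    for j in range(npts):
        for m in range(npts):
            if m != j:
                w[:, j] *= (f - m) / (j - m)
    return base, w


def lagrange_resample(data: np.ndarray, coords: np.ndarray, order: int = 7
                      ) -> np.ndarray:
    """Sample ``data`` at fractional voxel ``coords`` (3, n) with separable
    Lagrange interpolation of the given polynomial order (1, 3 or 7).

    Out-of-volume stencil points clamp to the edge voxel, so constant
    extension governs the boundary.  Exact for trivariate polynomials of
    per-axis degree <= order in the interior, and an exact copy for
    integer-voxel coordinates.
    """
    npts = _ORDER_NPTS[order]
    data = np.ascontiguousarray(data, dtype=np.float64)
    nx, ny, nz = data.shape
    flat = data.ravel()
    bases, weights, idx = [], [], []
    for axis, dim in enumerate((nx, ny, nz)):
        base, w = _lagrange_axis_weights(coords[axis], npts)
        node_idx = base[:, None] + np.arange(npts)[None, :]
        np.clip(node_idx, 0, dim - 1, out=node_idx)
        idx.append(node_idx)
        weights.append(w)
    ix, iy, iz = idx
    wx, wy, wz = weights
    out = np.zeros(coords.shape[1])
    for a in range(npts):
        fx = ix[:, a] * (ny * nz)
        for b in range(npts):
            fxy = fx + iy[:, b] * nz
            wxy = wx[:, a] * wy[:, b]
            acc = np.zeros_like(out)
            for c in range(npts):
                acc += wz[:, c] * flat[fxy + iz[:, c]]
            out += wxy * acc
    return out


def resample_rigid(vol: VolumeSample, t: RigidTransform,
                   interp: str = "heptic") -> VolumeSample:
    """Reslice ``vol`` through the rigid map ``T(x) = R(x-c) + c + s``."""
    if interp not in _INTERP_ORDER:
        raise ValueError(f"interp must be one of {sorted(_INTERP_ORDER)}, "
                         f"got {interp!r}")
    if np.allclose(t.params, 0.0):
        return vol.with_data(vol.data.copy())
    src = _source_voxel_coords(vol.shape, vol.affine, t)
    out = lagrange_resample(vol.data, src, _INTERP_ORDER[interp])
    return vol.with_data(out.reshape(vol.shape))


def apply_motion(ref: VolumeSample, t: RigidTransform,
                 interp: str = "heptic") -> VolumeSample:
    """Create a volume whose content has *moved* by ``t`` relative to ``ref``,
    so that :func:`estimate_motion` recovers ``t`` and resampling with ``t``
    realigns it."""
    return resample_rigid(ref, t.inverse(), interp=interp)


def _default_weight(ref_data: np.ndarray) -> np.ndarray:
    """Reference smoothed at 2-voxel sigma, thresholded at 10% of max.

    The outer 2-voxel shell of the grid is zeroed so clamp-to-edge
    boundary artifacts cannot bias the fit."""
    sm = ndimage.gaussian_filter(np.asarray(ref_data, float), sigma=2.0)
    w = np.where(sm >= 0.1 * sm.max(), sm, 0.0)
    w[:2, :, :] = w[-2:, :, :] = 0.0
    w[:, :2, :] = w[:, -2:, :] = 0.0
    w[:, :, :2] = w[:, :, -2:] = 0.0
    return w


def estimate_motion(ref: VolumeSample, vol: VolumeSample,
                    weight: np.ndarray | None = None,
                    max_iter: int = 19, tol: float = 1e-5,
                    init: np.ndarray | None = None) -> RigidTransform:
    """Gauss-Newton estimate of the six rigid parameters aligning ``vol``
    to ``ref``.

    Minimizes ``sum w * (vol(T(x)) - ref(x))**2`` over the weight support.
    The objective samples the moving volume with a cubic B-spline
    interpolant (prefiltered once); the Jacobian is formed by central
    differences in each parameter.  Iterations stop when the largest
    parameter update falls below ``tol`` (mm / degrees) or after
    ``max_iter`` iterations, whichever is first; non-convergence returns
    the best iterate with a warning.
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("moving volume contains non-finite intensities")
    if vol.shape != ref.shape:
        raise ValueError("volume grid does not match reference grid")
    if weight is None:
        weight = _default_weight(ref.data)
    mask = weight > 0
    sqrtw = np.sqrt(weight[mask])
    ref_vals = np.asarray(ref.data, float)[mask]

    # output-voxel mm coordinates (fixed across iterations)
    nx, ny, nz = ref.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vox = np.stack([ii[mask], jj[mask], kk[mask]]).astype(float)
    A = ref.affine
    mm = A[:3, :3] @ vox + A[:3, 3:4]
    c = _grid_center_mm(ref.shape, A)[:, None]
    inv = np.linalg.inv(A)

    coeffs = ndimage.spline_filter(np.asarray(vol.data, float), order=3)

    def sample(p: np.ndarray) -> np.ndarray:
        t = RigidTransform.from_params(p)
        src_mm = t.matrix() @ (mm - c) + c + p[3:6, None]
        src_vox = inv[:3, :3] @ src_mm + inv[:3, 3:4]
        return ndimage.map_coordinates(coeffs, src_vox, order=3,
                                       prefilter=False, mode="nearest")

    def residual(p: np.ndarray) -> np.ndarray:
        return sqrtw * (sample(p) - ref_vals)

    p = np.zeros(6) if init is None else np.asarray(init, float).copy()
    r = residual(p)
    sse = float(r @ r)
    h = 1e-3  # finite-difference step, mm / degrees
    converged = False
    for _ in range(max_iter):
        J = np.empty((r.size, 6))
        for i in range(6):
            dp = np.zeros(6)
            dp[i] = h
            J[:, i] = (residual(p + dp) - residual(p - dp)) / (2 * h)
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        # backtracking line search on the Gauss-Newton step
        scale = 1.0
        for _ in range(8):
            r_new = residual(p + scale * step)
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                break
            scale *= 0.5
        else:
            converged = True  # no descent direction left: at a minimum
            break
        p = p + scale * step
        r, sse = r_new, sse_new
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("motion estimation did not converge; "
                      "returning best iterate")
    return RigidTransform.from_params(p)


class VolregStage(Stage):
    """Motion-correction pipeline stage.

    The first volume received becomes the reference unless one is set
    beforehand.  For every volume the stage estimates the rigid motion,
    reslices with the configured interpolation, appends the parameters to
    the motion log, and pushes (transform, resliced unsmoothed volume) to
    subscribed downstream stages (the regression stage uses both).
    """

    name = "volreg"

    def __init__(self, reference: VolumeSample | None = None,
                 interp: str = "heptic", max_iter: int = 19, tol: float = 1e-5,
                 **kw):
        super().__init__(**kw)
        self.reference = reference
        self.interp = interp
        self.max_iter = max_iter
        self.tol = tol
        self._weight: np.ndarray | None = None
        self.motion_log: list[RigidTransform] = []
        self._subscribers: list = []

    def subscribe(self, stage) -> None:
        if stage not in self._subscribers:
            self._subscribers.append(stage)

    def _reset(self) -> None:
        self.motion_log = []
        self._weight = None

    def _proc(self, vol: VolumeSample) -> list[VolumeSample]:
        if self.reference is None:
            self.reference = vol
        if self._weight is None:
            self._weight = _default_weight(self.reference.data)
        t = estimate_motion(self.reference, vol, weight=self._weight,
                            max_iter=self.max_iter, tol=self.tol)
        resliced = resample_rigid(vol, t, interp=self.interp)
        self.motion_log.append(t)
        for sub in self._subscribers:
            sub.receive_motion(t, resliced)
        return [resliced]

    def _finalize(self, out_dir: Path) -> dict[str, Path]:
        path = out_dir / "motion.1D"
        with open(path, "w") as fh:
            fh.write("# rot_x(deg) rot_y(deg) rot_z(deg) "
                     "shift_x(mm) shift_y(mm) shift_z(mm)\n")
            for t in self.motion_log:
                fh.write(" ".join(f"{v: .6f}" for v in t.params) + "\n")
        return {"motion": path}


def volreg_offline(series: np.ndarray, affine: np.ndarray,
                   reference: VolumeSample | None = None,
                   interp: str = "heptic"
                   ) -> tuple[np.ndarray, list[RigidTransform]]:
    """Batch motion correction of a 4D array; the offline counterpart used
    by the online-equals-offline checks (no state carries between volumes
    beyond the fixed reference in either path)."""
    n = series.shape[-1]
    if reference is None:
        reference = VolumeSample(series[..., 0], affine, index=0)
    weight = _default_weight(reference.data)
    out = np.empty(series.shape, dtype=float)
    log: list[RigidTransform] = []
    for k in range(n):
        vol = VolumeSample(series[..., k], affine, index=k)
        t = estimate_motion(reference, vol, weight=weight)
        out[..., k] = resample_rigid(vol, t, interp=interp).data
        log.append(t)
    return out, log
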