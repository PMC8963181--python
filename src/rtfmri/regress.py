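"""Online signal scaling and cumulative-GLM noise regression.

The stage buffers incoming (smoothed, motion-corrected) volumes until
``wait_num`` volumes have arrived.  At that point the per-voxel baseline
mean over the waiting period is frozen, every buffered volume is converted
to percent signal change, the full nuisance design is built, an ordinary
least-squares fit is computed over all rows, and the residuals of *all*
buffered volumes are emitted retrospectively so the saved run contains
every volume.  On each later TR the design is rebuilt over all rows seen
so far (cumulative GLM), the model is refit, and the residual of the
newest row is emitted as the denoised volume.

Regressor families (each optional):

* Legendre polynomial drift, order ``1 + int(d / 150)`` for an elapsed
  scan duration of ``d`` seconds, evaluated on [-1, 1] over the rows
  currently in the model;
* 6 motion parameters and their 6 temporal first differences, received
  in real time from the upstream motion-correction stage;
* global-signal / white-matter / ventricle mean series, computed from the
  *unsmoothed* motion-corrected volumes;
* the 8-column RETROICOR basis, recomputed each TR from the portion of
  the physiological record available at that moment;
* arbitrary pre-defined covariate series (e.g. a task design), treated as
  regressors of no interest.

The emitted signal is the pure residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

from .physio import PhysioRecord, RETROICOR_LABELS, retroicor_regressors
from .pipeline import ConfigError, Stage
from .volreg import RigidTransform
from .volume import VolumeSample

__all__ = [
    "RegressStage",
    "BaselineMap",
    "legendre_order",
    "legendre_basis",
    "scale_to_percent",
    "mean_signal",
    "motion_columns",
]

DEFAULT_WAIT_NUM = 40  # volumes accumulated before the first regression


def legendre_order(d_s: float) -> int:
    """Drift polynomial order for an elapsed scan duration of ``d_s`` seconds:
    ``1 + int(d / 150)``."""
    if d_s < 0:
        raise ValueError("scan duration must be non-negative")
    return 1 + int(d_s // 150)


def legendre_basis(order: int, n_rows: int) -> np.ndarray:
    """Legendre polynomials P_0..P_order on ``n_rows`` points over [-1, 1]."""
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    x = np.linspace(-1.0, 1.0, n_rows)
    cols = [npleg.legval(x, [0] * k + [1]) for k in range(order + 1)]
    return np.column_stack(cols)


@dataclass
class BaselineMap:
    """Frozen per-voxel baseline mean of the pre-regression volumes."""

    mean: np.ndarray
    valid: np.ndarray

    @classmethod
    def from_volumes(cls, vols: list[np.ndarray],
                     eps_frac: float = 1e-6) -> "BaselineMap":
        mu = np.mean(np.stack(vols, axis=-1), axis=-1)
        return cls(mean=mu, valid=mu > eps_frac * mu.max())


def scale_to_percent(vol: VolumeSample, base: BaselineMap) -> VolumeSample:
    """Percent signal change, 100 (x - mu) / mu; invalid voxels -> 0."""
    out = np.zeros_like(base.mean, dtype=float)
    v = base.valid
    out[v] = 100.0 * (np.asarray(vol.data, float)[v] - base.mean[v]) / base.mean[v]
    return vol.with_data(out)


def mean_signal(vol: VolumeSample, mask: np.ndarray) -> float:
    """Arithmetic mean over in-mask voxels (for tissue-mean regressors this
    must be fed the unsmoothed motion-corrected volume)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ConfigError("mean_signal mask is empty")
    return float(np.asarray(vol.data, float)[mask].mean())


def motion_columns(log: list[RigidTransform]) -> np.ndarray:
    """6 motion-parameter series plus 6 first-difference series (12 columns);
    the derivative of row 0 is set to 0."""
    params = np.array([t.params for t in log], dtype=float)
    deriv = np.diff(params, axis=0, prepend=params[:1])
    return np.hstack([params, deriv])


class RegressStage(Stage):
    """Cumulative-GLM denoising pipeline stage.

    Parameters
    ----------
    tr_s : float
        Repetition time in seconds.
    wait_num : int
        Volumes to accumulate before the first regression; must exceed the
        regressor count at the first fit.
    mask : ndarray of bool, optional
        Processing mask; voxels outside it are passed through as zero.
    use_motion, use_motion_deriv : bool
        Include the motion parameters / their first differences.
    gs_mask, wm_mask, vent_mask : ndarray of bool, optional
        Enable the corresponding tissue-mean regressor.
    physio : PhysioRecord, optional
        Enables the 8-column RETROICOR family; set None to disable.
    extra_covariates : ndarray (n_vols, k), optional
        Pre-defined nuisance series, e.g. a task design.
    """

    name = "regress"

    def __init__(self, tr_s: float, wait_num: int = DEFAULT_WAIT_NUM,
                 mask: np.ndarray | None = None,
                 use_motion: bool = True, use_motion_deriv: bool = True,
                 gs_mask: np.ndarray | None = None,
                 wm_mask: np.ndarray | None = None,
                 vent_mask: np.ndarray | None = None,
                 physio: PhysioRecord | None = None,
                 extra_covariates: np.ndarray | None = None, **kw):
        super().__init__(**kw)
        self.tr_s = tr_s
        self.wait_num = wait_num
        self.mask = None if mask is None else np.asarray(mask).astype(bool)
        self.use_motion = use_motion
        self.use_motion_deriv = use_motion_deriv
        for nm, m in (("gs", gs_mask), ("wm", wm_mask), ("vent", vent_mask)):
            if m is not None and not np.asarray(m).any():
                raise ConfigError(f"{nm}_mask is empty")
        self.gs_mask = gs_mask
        self.wm_mask = wm_mask
        self.vent_mask = vent_mask
        self.physio = physio
        self.extra_covariates = (
            None if extra_covariates is None
            else np.atleast_2d(np.asarray(extra_covariates, float).T).T
        )
        self._reset()

    @property
    def needs_volreg(self) -> bool:
        return (self.use_motion or self.use_motion_deriv
                or any(m is not None
                       for m in (self.gs_mask, self.wm_mask, self.vent_mask)))

    def _reset(self) -> None:
        self._pending: list[VolumeSample] = []
        self._scaled_rows: list[np.ndarray] = []
        self.baseline: BaselineMap | None = None
        self.motion_log: list[RigidTransform] = []
        self._tissue: dict[str, list[float]] = {"gs": [], "wm": [], "vent": []}
        self.design_labels_: list[str] = []
        self.design_: np.ndarray | None = None
        self._warned_overfit = False

    # called by the upstream motion-correction stage for every volume
    def receive_motion(self, t: RigidTransform, unsmoothed: VolumeSample) -> None:
        self.motion_log.append(t)
        for key, m in (("gs", self.gs_mask), ("wm", self.wm_mask),
                       ("vent", self.vent_mask)):
            if m is not None:
                self._tissue[key].append(mean_signal(unsmoothed, m))

    # -- design construction ------------------------------------------
    def _build_design(self, n_rows: int) -> tuple[np.ndarray, list[str]]:
        d_s = n_rows * self.tr_s
        order = legendre_order(d_s)
        cols = [legendre_basis(order, n_rows)]
        labels = [f"drift_P{k}" for k in range(order + 1)]
        if self.use_motion or self.use_motion_deriv:
            if len(self.motion_log) < n_rows:
                raise ConfigError(
                    "motion parameters unavailable; an enabled motion-"
                    "correction stage must precede regression"
                )
            mc = motion_columns(self.motion_log[:n_rows])
            mlab = ["mot_rx", "mot_ry", "mot_rz", "mot_tx", "mot_ty", "mot_tz"]
            if self.use_motion:
                cols.append(mc[:, :6])
                labels += mlab
            if self.use_motion_deriv:
                cols.append(mc[:, 6:])
                labels += ["d" + m for m in mlab]
        for key in ("gs", "wm", "vent"):
            series = self._tissue[key]
            if getattr(self, f"{key}_mask") is not None:
                s = np.asarray(series[:n_rows], float)
                cols.append((s - s.mean())[:, None])
                labels.append(f"{key}_mean")
        if self.physio is not None:
            rec = self.physio.truncated(n_rows * self.tr_s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # leading-edge extrapolation
                basis = retroicor_regressors(rec, self.tr_s, n_rows)
            cols.append(basis.matrix)
            labels += list(RETROICOR_LABELS)
        if self.extra_covariates is not None:
            ex = self.extra_covariates[:n_rows]
            ex = ex - ex.mean(axis=0)
            cols.append(ex)
            labels += [f"extra_{j}" for j in range(ex.shape[1])]
        X = np.hstack(cols)
        # drop zero-variance columns (keep the constant drift P0)
        keep = np.ones(X.shape[1], dtype=bool)
        sd = X.std(axis=0)
        keep[1:] = sd[1:] > 1e-12 * max(1.0, np.abs(X).max())
        if not keep.all():
            dropped = [l for l, k in zip(labels, keep) if not k]
            warnings.warn(f"dropping zero-variance regressors: {dropped}")
        return X[:, keep], [l for l, k in zip(labels, keep) if k]

    def _fit_residual(self, n_rows: int, rows_needed: slice) -> np.ndarray:
        """Fit the cumulative GLM over all rows and return residual rows."""
        X, labels = self._build_design(n_rows)
        self.design_labels_ = labels
        self.design_ = X
        Y = np.stack(self._scaled_rows[:n_rows])  # (n_rows, n_voxels)
        if n_rows <= X.shape[1]:
            raise ConfigError(
                f"first regression needs more rows than regressors: "
                f"{n_rows} rows vs {X.shape[1]} columns; increase wait_num"
            )
        if n_rows < 2 * X.shape[1] and not self._warned_overfit:
            warnings.warn(
                f"only {n_rows} samples for {X.shape[1]} regressors; "
                "barely-determined fits risk overfitting the signal"
            )
            self._warned_overfit = True
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        return resid[rows_needed]

    def _emit(self, resid_row: np.ndarray, template: VolumeSample
              ) -> VolumeSample:
        if self.mask is None:
            data = resid_row.reshape(template.shape)
        else:
            data = np.zeros(template.shape, dtype=float)
            data[self.mask] = resid_row
        return template.with_data(data)

    def _flatten(self, vol: VolumeSample) -> np.ndarray:
        d = np.asarray(vol.data, float)
        return d[self.mask] if self.mask is not None else d.ravel()

    def _proc(self, vol: VolumeSample) -> list[VolumeSample]:
        self._pending.append(vol)
        n = len(self._pending)
        if self.baseline is None:
            if n < self.wait_num:
                return []  # still accumulating
            # freeze the baseline and retrospectively process the burn-in
            self.baseline = BaselineMap.from_volumes(
                [np.asarray(v.data, float) for v in self._pending]
            )
            if self.mask is not None:
                self.baseline.valid &= self.mask
            for v in self._pending:
                self._scaled_rows.append(
                    self._flatten(scale_to_percent(v, self.baseline)))
            resid = self._fit_residual(n, slice(0, n))
            return [self._emit(resid[k], self._pending[k]) for k in range(n)]
        self._scaled_rows.append(
            self._flatten(scale_to_percent(vol, self.baseline)))
        resid = self._fit_residual(n, slice(n - 1, n))
        return [self._emit(resid[0], vol)]

    def _finalize(self, out_dir):
        if getattr(self, "design_", None) is None or not self.design_labels_:
            return {}
        path = out_dir / "design_matrix.csv"
        header = ",".join(self.design_labels_)
        np.savetxt(path, self.design_, delimiter=",", header=header,
                   comments="")
        return {"design": path}
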