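"""Config-driven pipeline construction and replay simulation.

A pipeline is described by a nested dict (typically loaded from YAML)
keyed by stage name::

    run:     {tr_s, n_slices, ignore_init, work_dir}
    tshift:  {enabled, method, slice_times_s | slice_pattern}
    volreg:  {enabled, interp}
    smooth:  {enabled, fwhm_mm, mask}
    regress: {enabled, wait_num, use_motion, use_motion_deriv,
              gs_mask, wm_mask, vent_mask, phys_reg, mask}
    app:     {roi_mask, send_host, send_port}

Mask values may be NIfTI paths or boolean arrays.  ``run_simulation``
replays a 4D series volume-by-volume through the configured chain (direct
injection), which is equivalent to copying files into a watched directory
but faster; outputs are the denoised 4D NIfTI, the motion-parameter log,
the ROI signal CSV and the per-stage timing logs.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .app import RoiFeedbackStage
from .physio import PhysioRecord
from .pipeline import Stage, chain
from .regress import RegressStage
from .smooth import SmoothStage
from .tshift import TshiftStage
from .volreg import VolregStage
from .volume import RunMeta, VolumeSample
from .watch import replay

__all__ = ["build_pipeline", "run_simulation", "load_mask", "load_physio"]


def load_mask(src) -> np.ndarray:
    if isinstance(src, (str, Path)):
        return np.asanyarray(nib.load(str(src)).dataobj).astype(bool)
    return np.asarray(src).astype(bool)


def load_physio(card_path, resp_path, fs_hz: float,
                t0_s: float = 0.0) -> PhysioRecord:
    return PhysioRecord(card=np.loadtxt(card_path), resp=np.loadtxt(resp_path),
                        fs_hz=fs_hz, t0_s=t0_s)


def build_pipeline(config: dict, physio: PhysioRecord | None = None
                   ) -> tuple[Stage, RunMeta]:
    """Instantiate and chain the stages described by ``config``."""
    run = config.get("run", {})
    tr_s = float(run.get("tr_s", 2.0))
    n_slices = int(run.get("n_slices", 1))
    meta = RunMeta(tr_s=tr_s, n_slices=n_slices,
                   slice_times_s=run.get("slice_times_s"),
                   ignore_init=int(run.get("ignore_init", 0)))
    work_dir = run.get("work_dir")

    stages: list[Stage] = []
    ts = config.get("tshift", {})
    if ts.get("enabled", False):
        m = meta
        if ts.get("slice_pattern") == "interleaved":
            m = RunMeta.interleaved(tr_s, n_slices,
                                    ignore_init=meta.ignore_init)
        stages.append(TshiftStage(m, method=ts.get("method", "cubic"),
                                  work_dir=work_dir))
    vr = config.get("volreg", {})
    if vr.get("enabled", True):
        stages.append(VolregStage(interp=vr.get("interp", "heptic"),
                                  work_dir=work_dir))
    sm = config.get("smooth", {})
    if sm.get("enabled", False):
        stages.append(SmoothStage(fwhm_mm=float(sm.get("fwhm_mm", 6.0)),
                                  mask=load_mask(sm["mask"]),
                                  work_dir=work_dir))
    rg = config.get("regress", {})
    if rg.get("enabled", False):
        phys_reg = rg.get("phys_reg", "retroicor")
        use_physio = physio if phys_reg not in (None, "none", "None", False) \
            else None
        stages.append(RegressStage(
            tr_s=tr_s,
            wait_num=int(rg.get("wait_num", 40)),
            mask=load_mask(rg["mask"]) if rg.get("mask") is not None else None,
            use_motion=bool(rg.get("use_motion", True)),
            use_motion_deriv=bool(rg.get("use_motion_deriv", True)),
            gs_mask=load_mask(rg["gs_mask"]) if rg.get("gs_mask") is not None
            else None,
            wm_mask=load_mask(rg["wm_mask"]) if rg.get("wm_mask") is not None
            else None,
            vent_mask=load_mask(rg["vent_mask"])
            if rg.get("vent_mask") is not None else None,
            physio=use_physio,
            extra_covariates=rg.get("extra_covariates"),
            save_proc=True, work_dir=work_dir,
        ))
    ap = config.get("app", {})
    if ap.get("roi_mask") is not None:
        send_to = None
        if ap.get("send_host"):
            send_to = (ap["send_host"], int(ap["send_port"]))
        stages.append(RoiFeedbackStage(roi=load_mask(ap["roi_mask"]),
                                       send_to=send_to, work_dir=work_dir))
    if not stages:
        raise ValueError("config enables no pipeline stage")
    return chain(stages), meta


def run_simulation(series_4d, config: dict,
                   physio: PhysioRecord | None = None,
                   affine: np.ndarray | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Replay a 4D series through the configured pipeline.

    ``series_4d`` may be a NIfTI path or an (nx, ny, nz, n) array (with
    ``affine``).  Returns the artifact path map from ``end_run``.
    """
    if isinstance(series_4d, (str, Path)):
        img = nib.load(str(series_4d))
        data = np.asanyarray(img.dataobj).astype(float)
        affine = img.affine
    else:
        data = np.asarray(series_4d, float)
        if affine is None:
            raise ValueError("affine required with an in-memory series")
    if data.ndim != 4:
        raise ValueError(f"expected a 4D series, got shape {data.shape}")
    head, meta = build_pipeline(config, physio=physio)
    head.ready()
    for vol in replay(data, affine, meta):
        head.do_proc(vol)
    out_dir = out_dir or config.get("run", {}).get("work_dir") or "."
    return head.end_run(out_dir)
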