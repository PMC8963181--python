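"""Synthetic 4D phantom and physiological traces with known ground truth.

The phantom is a desk-scale stand-in for an EPI neurofeedback run: three
concentric ellipsoidal compartments (ventricle core, white-matter shell,
gray-matter rim) with distinct baseline intensities, contaminated by

* per-tissue polynomial (Legendre) percent drift,
* quasi-periodic cardiac and respiratory amplitude modulation at the
  analytic physiological phase, strongest in the ventricle and rim,
* per-volume rigid motion (applied with 7th-order Lagrange reslicing),
* i.i.d. Gaussian noise (seeded),

plus a block-design activation of a small gray-matter ROI.  Every
injected component is returned in the truth record, so each pipeline
stage can be scored against what was actually put in.  The same spec and
seed always reproduce bit-identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .physio import PhysioRecord, cardiac_phase
from .regress import legendre_basis
from .volreg import RigidTransform, apply_motion
from .volume import VolumeSample, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "make_phantom",
    "make_physio",
    "sinusoid_motion",
    "smooth_random_motion",
    "write_fixture",
]

# baseline intensities (arbitrary scanner units)
_BASE = {"vent": 600.0, "wm": 900.0, "gm": 1000.0}


def sinusoid_motion(n_vols: int, amp_mm: float = 0.3, amp_deg: float = 0.3,
                    cycles=(1.0, 1.5, 2.0)) -> list[RigidTransform]:
    """Smooth sinusoidal motion course; volume 0 is at rest so it can act
    as the registration reference."""
    k = np.arange(n_vols)
    course = []
    for i in range(n_vols):
        rot = tuple(amp_deg * np.sin(2 * np.pi * cycles[j] * k[i] / n_vols)
                    for j in range(3))
        sh = tuple(amp_mm * np.sin(2 * np.pi * cycles[j] * k[i] / n_vols
                                   + np.pi / 5 * (j + 1))
                   for j in range(3))
        course.append(RigidTransform(rot, sh))
    # anchor the first volume at zero motion
    zero = RigidTransform()
    first_inv = course[0].inverse()
    return [zero] + [first_inv.compose(t) for t in course[1:]]


def smooth_random_motion(n_vols: int, amp_mm: float = 0.3,
                         amp_deg: float = 0.3, seed: int = 0,
                         max_cycles: int = 3) -> list[RigidTransform]:
    """Seeded slow drift-like motion course (the phantom default).

    Head motion in a compliant subject is a slow postural drift, so each
    parameter is a random-phase sum of 1..``max_cycles`` whole-run
    sinusoids (seeded amplitudes and phases), scaled so its maximum
    excursion equals the requested amplitude, with volume 0 anchored at
    rest.  Being strictly band-limited to a few cycles per run, the
    course is orthogonal to any task paradigm cycling faster than
    ``max_cycles`` blocks per run."""
    rng = np.random.default_rng(seed)
    k = np.arange(n_vols)
    p = np.zeros((6, n_vols))
    for j in range(6):
        for c in range(1, max_cycles + 1):
            a = rng.uniform(0.3, 1.0) / c
            ph = rng.uniform(0, 2 * np.pi)
            p[j] += a * np.sin(2 * np.pi * c * k / n_vols + ph)
    p -= p[:, :1]  # volume 0 at rest
    peak = np.max(np.abs(p), axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    p /= peak
    p[:3] *= amp_deg
    p[3:] *= amp_mm
    return [RigidTransform(tuple(p[:3, k]), tuple(p[3:, k]))
            for k in range(n_vols)]


@dataclass
class PhantomSpec:
    """Stated world of one synthetic run."""

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    n_vols: int = 120
    motion_truth: list[RigidTransform] | None = None  # default: gentle sinusoids
    motion_amp_mm: float = 0.3
    motion_amp_deg: float = 0.3
    # per-tissue Legendre drift coefficients, percent of baseline
    drift_coeffs: dict = field(default_factory=lambda: {
        "gm": (0.0, 0.8, 0.4), "wm": (0.0, 0.6, 0.3), "vent": (0.0, 0.5, 0.2),
    })
    # block-design activation of the ROI: 20 s on / 20 s off cycles
    act_onsets_s: tuple = (20.0, 60.0, 100.0, 140.0, 180.0, 220.0)
    act_duration_s: float = 20.0
    act_amplitude_pct: float = 2.0
    # cardiac/respiratory percent amplitude per tissue
    physio_gain: dict = field(default_factory=lambda: {
        "gm": (0.5, 0.5), "wm": (0.2, 0.2), "vent": (1.5, 1.0),
    })
    card_hz: float = 1.0
    resp_hz: float = 0.25
    physio_fs_hz: float = 50.0
    physio_jitter: float = 0.05
    # thermal noise, intensity units; 10 = 1% of gray matter baseline,
    # i.e. temporal SNR ~100, typical of 3 T EPI
    noise_sd: float = 10.0
    # optional per-tissue independent smooth drift (percent SD); 0 keeps
    # the nuisance within what the tissue-mean regressors can represent
    drift_tissue_sd_pct: float = 0.0
    seed: int = 0


@dataclass
class PhantomResult:
    series: np.ndarray           # (nx, ny, nz, n_vols)
    affine: np.ndarray
    masks: dict                  # brain, gm_roi, wm, vent (+ gm)
    physio: PhysioRecord
    truth: dict


def make_physio(duration_s: float, fs_hz: float = 50.0, card_hz: float = 1.0,
                resp_hz: float = 0.25, jitter: float = 0.05,
                seed: int = 0) -> tuple[PhysioRecord, dict]:
    """Quasi-periodic pulse and belt traces plus their ground truth.

    Beat-to-beat intervals are ``1/card_hz`` perturbed by seeded Gaussian
    jitter (fractional SD ``jitter``); the pulse waveform peaks exactly at
    the beat times.  The respiration trace is a zero-mean sinusoid with
    slow seeded amplitude variation.
    """
    rng = np.random.default_rng(seed)
    beats = [0.0]
    while beats[-1] < duration_s + 2.0:
        ibi = (1.0 / card_hz) * (1.0 + jitter * rng.standard_normal())
        beats.append(beats[-1] + max(0.3, ibi))
    beats = np.asarray(beats)
    t = np.arange(int(np.ceil(duration_s * fs_hz)) + 1) / fs_hz
    phi_c = cardiac_phase(t, beats)
    card = np.cos(phi_c) + 0.3 * np.cos(2 * phi_c)
    theta_r = 2 * np.pi * resp_hz * t + jitter * np.cumsum(
        rng.standard_normal(t.size)) / fs_hz
    amp = 1.0 + 0.1 * np.sin(2 * np.pi * 0.02 * t)
    resp = amp * np.sin(theta_r)
    resp = resp - resp.mean()
    rec = PhysioRecord(card=card, resp=resp, fs_hz=fs_hz, t0_s=0.0)
    truth = {"beat_times_s": beats, "resp_phase": theta_r}
    return rec, truth


def _compartments(shape) -> dict:
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    # unequal axes so no rigid rotation leaves the phantom invariant
    ax, ay, az = 0.44 * nx, 0.36 * ny, 0.42 * nz
    r = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                + ((z - cz) / az) ** 2)
    brain = r <= 1.0
    vent = r <= 0.25
    wm = (r > 0.25) & (r <= 0.62)
    gm = (r > 0.62) & brain
    # off-center bright inclusion: breaks residual symmetry for registration
    rb = np.sqrt(((x - (cx - 0.5 * ax)) / 2.5) ** 2
                 + ((y - (cy + 0.4 * ay)) / 2.5) ** 2
                 + ((z - cz) / 2.0) ** 2)
    blob = (rb <= 1.0) & wm
    # small spherical ROI embedded in the gray-matter rim on the +x side
    rx = np.sqrt((x - (cx + 0.8 * ax)) ** 2 + (y - cy) ** 2
                 + ((z - cz) * 1.5) ** 2)
    roi = (rx <= 3.0) & gm
    return {"brain": brain, "gm": gm, "wm": wm, "vent": vent, "gm_roi": roi,
            "blob": blob, "radius": r}


def make_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build the 4D phantom, its masks and the full ground-truth record."""
    from scipy.ndimage import gaussian_filter

    comp = _compartments(spec.shape)
    roi = comp["gm_roi"]
    if not (roi & comp["brain"]).any() or (roi & ~comp["brain"]).any():
        raise ValueError("activation ROI must lie inside the brain")
    baseline = np.zeros(spec.shape)
    for tis in ("vent", "wm", "gm"):
        baseline[comp[tis]] = _BASE[tis]
    baseline[comp["blob"]] = 1200.0
    baseline = gaussian_filter(baseline, sigma=1.0)  # soften edges

    affine = np.diag(list(spec.voxel_mm) + [1.0])
    affine[:3, 3] = -(np.asarray(spec.shape) - 1) / 2 * spec.voxel_mm

    n = spec.n_vols
    vol_t = np.arange(n) * spec.tr_s
    duration = n * spec.tr_s

    rec, phys_truth = make_physio(duration, spec.physio_fs_hz, spec.card_hz,
                                  spec.resp_hz, spec.physio_jitter, spec.seed)
    phi_c = cardiac_phase(vol_t, phys_truth["beat_times_s"])
    phi_r = np.interp(vol_t, rec.times, phys_truth["resp_phase"])

    # percent-of-baseline nuisance per tissue
    drift_pct = {}
    max_order = max(len(c) - 1 for c in spec.drift_coeffs.values())
    leg = (legendre_basis(max_order, n) if n >= 2
           else np.ones((n, max_order + 1)))
    drift_rng = np.random.default_rng(spec.seed + 3)
    for tis, coeffs in spec.drift_coeffs.items():
        drift_pct[tis] = leg[:, :len(coeffs)] @ np.asarray(coeffs, float)
        if spec.drift_tissue_sd_pct > 0 and n >= 4:
            # tissue-specific slow component: spatially varying drift
            own = gaussian_filter(drift_rng.standard_normal(n), 8.0,
                                  mode="nearest")
            own -= own[0]
            sd = own.std()
            if sd > 0:
                drift_pct[tis] = drift_pct[tis] + \
                    spec.drift_tissue_sd_pct * own / sd
    physio_pct = {}
    for tis, (gc, gr) in spec.physio_gain.items():
        physio_pct[tis] = (gc * (np.cos(phi_c) + 0.4 * np.cos(2 * phi_c))
                           + gr * (np.sin(phi_r) + 0.3 * np.sin(2 * phi_r)))

    design = np.zeros(n)
    for onset in spec.act_onsets_s:
        design[(vol_t >= onset) & (vol_t < onset + spec.act_duration_s)] = 1.0

    motion = spec.motion_truth
    if motion is None:
        motion = smooth_random_motion(n, spec.motion_amp_mm,
                                      spec.motion_amp_deg, seed=spec.seed + 2)
    if len(motion) != n:
        raise ValueError("motion_truth length must equal n_vols")

    rng = np.random.default_rng(spec.seed + 1)
    series = np.empty(spec.shape + (n,))
    for k in range(n):
        pct = np.zeros(spec.shape)
        for tis in ("gm", "wm", "vent"):
            pct[comp[tis]] = drift_pct[tis][k] + physio_pct[tis][k]
        pct[roi] += spec.act_amplitude_pct * design[k]
        vol = baseline * (1.0 + pct / 100.0)
        moved = apply_motion(
            VolumeSample(vol, affine, index=k, onset_s=vol_t[k]), motion[k],
            interp="heptic",
        ).data
        series[..., k] = moved + spec.noise_sd * rng.standard_normal(spec.shape)

    truth = {
        "activation_design": design,
        "act_amplitude_pct": spec.act_amplitude_pct,
        "motion_params": np.array([t.params for t in motion]),
        "drift_pct": drift_pct,
        "physio_pct": physio_pct,
        "nuisance_roi_pct": drift_pct["gm"] + physio_pct["gm"],
        "beat_times_s": phys_truth["beat_times_s"],
        "baseline": baseline,
    }
    masks = {k: comp[k] for k in ("brain", "gm", "gm_roi", "wm", "vent")}
    return PhantomResult(series=series, affine=affine, masks=masks,
                         physio=rec, truth=truth)


def write_fixture(out_dir: str | Path, spec: PhantomSpec) -> dict:
    """Materialize a phantom as a watch-compatible file tree.

    Writes one 3D NIfTI per volume (``vol_0000.nii`` ...), the 4D series,
    all masks, one-column physio text files and a truth JSON; returns the
    path map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = make_phantom(spec)
    paths: dict[str, Path] = {}
    vols_dir = out_dir / "vols"
    vols_dir.mkdir(exist_ok=True)
    for k in range(spec.n_vols):
        p = vols_dir / f"vol_{k:04d}.nii"
        write_volume(VolumeSample(res.series[..., k].astype(np.float32),
                                  res.affine, index=k,
                                  onset_s=k * spec.tr_s), p)
    paths["vols_dir"] = vols_dir
    paths["series_4d"] = out_dir / "phantom_4d.nii"
    nib.save(nib.Nifti1Image(res.series.astype(np.float32), res.affine),
             str(paths["series_4d"]))
    for name, mask in res.masks.items():
        p = out_dir / f"mask_{name}.nii"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), res.affine), str(p))
        paths[f"mask_{name}"] = p
    np.savetxt(out_dir / "card.txt", res.physio.card, fmt="%.8g")
    np.savetxt(out_dir / "resp.txt", res.physio.resp, fmt="%.8g")
    paths["card"] = out_dir / "card.txt"
    paths["resp"] = out_dir / "resp.txt"
    truth_json = {
        "tr_s": spec.tr_s,
        "physio_fs_hz": spec.physio_fs_hz,
        "activation_design": res.truth["activation_design"].tolist(),
        "motion_params": res.truth["motion_params"].tolist(),
        "beat_times_s": res.truth["beat_times_s"].tolist(),
        "nuisance_roi_pct": res.truth["nuisance_roi_pct"].tolist(),
    }
    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return paths
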