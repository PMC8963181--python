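"""Cardiac/respiratory trace handling and RETROICOR regressors.

The RETROICOR model expands cardiac and respiratory phase into a Fourier
basis: for each modality, sin and cos of the first two harmonics of the
phase, giving four cardiac and four respiratory columns sampled at the
volume onset times.  Cardiac phase advances linearly between detected
heartbeats; respiratory phase is the signed amplitude-histogram phase
(cumulative histogram of the smoothed belt trace, sign from its slope).

Respiration-volume-per-time (RVT) regressors are deliberately not
implemented: their online estimates are unreliable near the leading edge
of the recording and can inject artifactual fluctuations into the
regressed signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PhysioRecord",
    "RetroicorBasis",
    "RETROICOR_LABELS",
    "detect_cardiac_peaks",
    "cardiac_phase",
    "resp_phase",
    "retroicor_regressors",
]

RETROICOR_LABELS = (
    "card_sin1", "card_cos1", "card_sin2", "card_cos2",
    "resp_sin1", "resp_cos1", "resp_sin2", "resp_cos2",
)


@dataclass
class PhysioRecord:
    """Simultaneously sampled cardiac and respiration traces.

    ``t0_s`` is the time of the first sample relative to scan start; both
    traces share the sampling frequency ``fs_hz``.
    """

    card: np.ndarray
    resp: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.card = np.asarray(self.card, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        if self.card.ndim != 1 or self.resp.ndim != 1:
            raise ValueError("traces must be one-dimensional")

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.card)) / self.fs_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + (len(self.card) - 1) / self.fs_hz

    def truncated(self, t_end_s: float) -> "PhysioRecord":
        """Record restricted to samples at or before ``t_end_s`` — the data
        actually available at that moment of the scan."""
        n = int(np.floor((t_end_s - self.t0_s) * self.fs_hz)) + 1
        n = max(0, min(n, len(self.card)))
        return PhysioRecord(self.card[:n], self.resp[:n], self.fs_hz, self.t0_s)


@dataclass
class RetroicorBasis:
    """n_volumes x 8 RETROICOR regressor bank with fixed column labels."""

    matrix: np.ndarray
    labels: tuple[str, ...] = RETROICOR_LABELS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 8:
            raise ValueError("RETROICOR basis must have exactly 8 columns")


def _moving_average(x: np.ndarray, window_s: float, fs_hz: float) -> np.ndarray:
    n = max(1, int(round(window_s * fs_hz)))
    if n % 2 == 0:
        n += 1
    kernel = np.ones(n) / n
    # reflect-padded so edges keep the local mean level
    pad = n // 2
    xp = np.pad(x, pad, mode="reflect")
    return np.convolve(xp, kernel, mode="valid")


def detect_cardiac_peaks(rec: PhysioRecord, smooth_s: float = 0.1,
                         refractory_s: float = 0.25,
                         height_sd: float = 0.4) -> np.ndarray:
    """Heartbeat times (seconds, scan clock) from the cardiac trace.

    Local maxima of the moving-average-smoothed trace above
    mean + ``height_sd`` * SD, separated by at least the refractory period.
    """
    if len(rec.card) < 2 * rec.fs_hz:
        raise ValueError("cardiac trace shorter than 2 s")
    sm = _moving_average(rec.card, smooth_s, rec.fs_hz)
    thr = sm.mean() + height_sd * sm.std()
    idx, _ = find_peaks(sm, height=thr,
                        distance=max(1, int(round(refractory_s * rec.fs_hz))))
    if idx.size == 0:
        raise ValueError(
            "no cardiac peaks detected; check the trace polarity and amplitude"
        )
    return rec.t0_s + idx / rec.fs_hz


def cardiac_phase(t, peaks: np.ndarray) -> np.ndarray:
    """Phase in [0, 2*pi): linear progression between bracketing beats.

    Times outside [first, last) peak use the nearest inter-beat interval
    (constant-rate extrapolation).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("need at least two cardiac peaks")
    outside = (t < peaks[0]) | (t >= peaks[-1])
    if np.any(outside):
        warnings.warn("cardiac phase extrapolated outside the detected "
                      "peak range using the nearest inter-beat interval")
    i = np.searchsorted(peaks, t, side="right") - 1
    i = np.clip(i, 0, peaks.size - 2)
    t_prev = peaks[i]
    t_next = peaks[i + 1]
    phase = 2 * np.pi * (t - t_prev) / (t_next - t_prev)
    return np.mod(phase, 2 * np.pi)


def resp_phase(t, rec: PhysioRecord, smooth_s: float = 0.5,
               n_bins: int = 100) -> np.ndarray:
    """Signed histogram-equalized respiratory phase in (-pi, pi].

    phi(t) = pi * H(R(t)) / H_tot * sign(dR/dt), where H is the cumulative
    100-bin amplitude histogram of the smoothed trace R.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    sm = _moving_average(rec.resp, smooth_s, rec.fs_hz)
    if sm.std() == 0:
        raise ValueError("respiration trace has zero variance")
    counts, edges = np.histogram(sm, bins=n_bins)
    cum = np.concatenate([[0], np.cumsum(counts)]).astype(float)
    r_t = np.interp(t, rec.times, sm)
    drdt = np.interp(t, rec.times, np.gradient(sm, 1.0 / rec.fs_hz))
    b = np.clip(np.searchsorted(edges, r_t, side="right") - 1, 0, n_bins - 1)
    h = cum[b + 1]
    sign = np.where(drdt >= 0, 1.0, -1.0)
    return np.pi * h / cum[-1] * sign


def retroicor_regressors(rec: PhysioRecord, tr_s: float, n_vols: int,
                         peaks: np.ndarray | None = None) -> RetroicorBasis:
    """RETROICOR basis sampled at the volume onset times k * tr_s.

    Recomputing with a longer record changes already-computed rows only
    through re-detected peaks near the old leading edge, which is the
    cumulative-update semantics the online regression relies on.
    """
    vol_times = np.arange(n_vols) * tr_s
    if rec.end_s < vol_times[-1]:
        raise ValueError(
            f"physio record ends at {rec.end_s:.2f} s but the scan needs "
            f"coverage to {vol_times[-1]:.2f} s "
            f"(uncovered: {rec.end_s:.2f}-{vol_times[-1]:.2f} s)"
        )
    if peaks is None:
        peaks = detect_cardiac_peaks(rec)
    phi_c = cardiac_phase(vol_times, peaks)
    phi_r = resp_phase(vol_times, rec)
    cols = [np.sin(phi_c), np.cos(phi_c), np.sin(2 * phi_c), np.cos(2 * phi_c),
            np.sin(phi_r), np.cos(phi_r), np.sin(2 * phi_r), np.cos(2 * phi_r)]
    return RetroicorBasis(np.column_stack(cols))
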