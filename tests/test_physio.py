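import numpy as np
import pytest

from rtfmri.physio import (PhysioRecord, RETROICOR_LABELS, cardiac_phase,
                           detect_cardiac_peaks, resp_phase,
                           retroicor_regressors, _moving_average)


def _sine_record(card_hz=1.0, fs=50.0, dur=60.0, resp_hz=0.25):
    t = np.arange(int(dur * fs)) / fs
    return PhysioRecord(card=np.cos(2 * np.pi * card_hz * t),
                        resp=np.sin(2 * np.pi * resp_hz * t), fs_hz=fs), t


def test_sinusoid_peak_count_and_spacing():
    rec, _ = _sine_record(dur=60.5)
    peaks = detect_cardiac_peaks(rec)
    # beats at 1..60 s (the t=0 peak is a series endpoint, not a local max)
    assert len(peaks) == 60
    spacing = np.diff(peaks)
    assert np.all(np.abs(spacing - 1.0) <= 0.02)


def test_constant_trace_rejected():
    rec = PhysioRecord(card=np.ones(500), resp=np.ones(500), fs_hz=50.0)
    with pytest.raises(ValueError):
        detect_cardiac_peaks(rec)


def test_peak_detection_robust_to_noise(rng):
    rec, t = _sine_record(dur=60.5)
    noisy = PhysioRecord(card=rec.card + 0.1 * rng.standard_normal(t.size),
                         resp=rec.resp, fs_hz=rec.fs_hz)
    assert len(detect_cardiac_peaks(noisy)) == len(detect_cardiac_peaks(rec))


def test_cardiac_phase_closed_forms():
    peaks = np.array([0.0, 1.0, 2.0])
    assert cardiac_phase(1.0, peaks)[0] == pytest.approx(0.0)
    assert cardiac_phase(0.5, peaks)[0] == pytest.approx(np.pi)
    assert cardiac_phase(1.25, peaks)[0] == pytest.approx(np.pi / 2)


def test_cardiac_phase_extrapolates_with_warning():
    peaks = np.array([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning):
        ph = cardiac_phase(3.5, peaks)
    assert ph[0] == pytest.approx(np.pi)


def test_resp_phase_extremes():
    rec, t = _sine_record(resp_hz=0.25, dur=40.0)
    # rising through the maximum-amplitude histogram bin -> near +pi
    ph_max = resp_phase(0.9, rec)[0]   # near amplitude peak, rising side
    assert ph_max > 0.8 * np.pi
    # near the minimum amplitude the cumulative histogram is small
    ph_min = resp_phase(2.9, rec)[0]
    assert abs(ph_min) < 0.2 * np.pi


def test_resp_phase_matches_brute_force_histogram():
    fs = 25.0
    t = np.arange(int(100 * fs)) / fs
    from scipy.signal import sawtooth
    resp = sawtooth(2 * np.pi * 0.2 * t, width=0.5)  # triangular wave
    rec = PhysioRecord(card=np.cos(2 * np.pi * t), resp=resp, fs_hz=fs)
    query = np.array([10.3, 20.7, 33.1, 47.9])
    got = resp_phase(query, rec)
    # independent brute-force implementation of the signed histogram phase
    sm = _moving_average(resp, 0.5, fs)
    counts, edges = np.histogram(sm, bins=100)
    r_t = np.interp(query, t, sm)
    dr = np.interp(query, t, np.gradient(sm, 1.0 / fs))
    want = np.empty(query.size)
    for i, r in enumerate(r_t):
        h = counts[: max(0, np.searchsorted(edges, r, side="right") - 1) + 1].sum()
        want[i] = np.pi * h / counts.sum() * (1 if dr[i] >= 0 else -1)
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_zero_variance_resp_rejected():
    rec = PhysioRecord(card=np.cos(np.arange(100)), resp=np.zeros(100),
                       fs_hz=10.0)
    with pytest.raises(ValueError):
        resp_phase(1.0, rec)


class TestRetroicorBasis:
    def test_structure_four_plus_four(self):
        rec, _ = _sine_record(dur=65.0)
        basis = retroicor_regressors(rec, tr_s=2.0, n_vols=30)
        assert basis.matrix.shape == (30, 8)
        assert sum(l.startswith("card") for l in basis.labels) == 4
        assert sum(l.startswith("resp") for l in basis.labels) == 4
        assert basis.labels == RETROICOR_LABELS
        assert np.all(np.abs(basis.matrix) <= 1.0 + 1e-12)

    def test_sin_cos_identity_per_harmonic(self):
        rec, _ = _sine_record(dur=65.0)
        m = retroicor_regressors(rec, tr_s=2.0, n_vols=30).matrix
        for s, c in ((0, 1), (2, 3), (4, 5), (6, 7)):
            np.testing.assert_allclose(m[:, s] ** 2 + m[:, c] ** 2, 1.0,
                                       atol=1e-12)

    def test_cardiac_columns_match_analytic_phase(self):
        """Periodic 1 Hz cardiac trace with TR incommensurate with the beat:
        columns must equal sin/cos of the analytic phase 2*pi*t mod 2*pi."""
        rec, _ = _sine_record(card_hz=1.0, fs=100.0, dur=85.0)
        tr = 1.7
        n = 48
        m = retroicor_regressors(rec, tr_s=tr, n_vols=n).matrix
        phi = 2 * np.pi * np.mod(np.arange(n) * tr, 1.0)
        np.testing.assert_allclose(m[:, 0], np.sin(phi), atol=1e-6)
        np.testing.assert_allclose(m[:, 1], np.cos(phi), atol=1e-6)
        np.testing.assert_allclose(m[:, 2], np.sin(2 * phi), atol=1e-6)

    def test_record_shorter_than_scan_rejected(self):
        rec, _ = _sine_record(dur=30.0)
        with pytest.raises(ValueError, match="uncovered"):
            retroicor_regressors(rec, tr_s=2.0, n_vols=30)

    def test_online_rows_final_once_peaks_bracketed(self):
        """Cumulative recomputation with a longer record must leave rows
        whose bracketing peaks are final unchanged."""
        rec, _ = _sine_record(dur=80.0)
        full = retroicor_regressors(rec, tr_s=2.0, n_vols=30).matrix
        part = retroicor_regressors(rec.truncated(44.0), tr_s=2.0,
                                    n_vols=20).matrix
        # cardiac rows up to 38 s are bracketed by final peaks in both
        # records, so they agree exactly; the respiratory histogram spans
        # the whole trace, so those columns agree only statistically
        np.testing.assert_allclose(part[:19, :4], full[:19, :4], atol=1e-9)
        np.testing.assert_allclose(part[:19, 4:], full[:19, 4:], atol=0.05)

    def test_basis_removes_phase_built_series(self, rng):
        """Regressing the 8 columns out of a series constructed from the
        same phases must remove >=99% of its variance."""
        rec, _ = _sine_record(dur=130.0)
        m = retroicor_regressors(rec, tr_s=2.0, n_vols=60).matrix
        w = rng.standard_normal(8)
        y = m @ w
        beta, *_ = np.linalg.lstsq(m, y, rcond=None)
        resid = y - m @ beta
        assert resid.var() <= 0.01 * y.var()
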