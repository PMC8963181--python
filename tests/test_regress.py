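import numpy as np
import pytest

from rtfmri.pipeline import ConfigError, chain
from rtfmri.regress import (BaselineMap, RegressStage, legendre_basis,
                            legendre_order, mean_signal, motion_columns,
                            scale_to_percent)
from rtfmri.volreg import RigidTransform
from rtfmri.volume import VolumeSample


@pytest.mark.parametrize("d,expected", [(0, 1), (149, 1), (150, 2),
                                        (300, 3), (450, 4)])
def test_legendre_order_rule(d, expected):
    assert legendre_order(d) == expected


def test_legendre_basis_low_orders():
    b = legendre_basis(1, 3)
    np.testing.assert_allclose(b[:, 0], 1.0)
    np.testing.assert_allclose(b[:, 1], [-1.0, 0.0, 1.0])


def test_legendre_basis_closed_forms():
    b = legendre_basis(3, 21)
    x = np.linspace(-1, 1, 21)
    np.testing.assert_allclose(b[:, 2], (3 * x**2 - 1) / 2, atol=1e-12)
    np.testing.assert_allclose(b[:, 3], (5 * x**3 - 3 * x) / 2, atol=1e-12)


class TestScaling:
    def _base(self, mu):
        return BaselineMap(mean=mu, valid=mu > 1e-6 * mu.max())

    def test_baseline_volume_scales_to_zero(self):
        mu = np.full((3, 3, 3), 100.0)
        out = scale_to_percent(VolumeSample(mu, np.eye(4)), self._base(mu))
        np.testing.assert_allclose(out.data, 0.0)

    def test_five_percent_above_baseline(self, rng):
        mu = rng.uniform(500, 1500, (3, 3, 3))
        out = scale_to_percent(VolumeSample(1.05 * mu, np.eye(4)),
                               self._base(mu))
        np.testing.assert_allclose(out.data, 5.0, atol=1e-10)

    def test_zero_baseline_voxel_masked(self):
        mu = np.full((2, 2, 2), 100.0)
        mu[0, 0, 0] = 0.0
        base = self._base(mu)
        assert not base.valid[0, 0, 0]
        out = scale_to_percent(VolumeSample(np.ones((2, 2, 2)), np.eye(4)),
                               base)
        assert out.data[0, 0, 0] == 0.0


def test_mean_signal_examples(rng):
    vol = VolumeSample(np.full((3, 3, 3), 4.2), np.eye(4))
    mask = np.ones((3, 3, 3), bool)
    assert mean_signal(vol, mask) == pytest.approx(4.2)
    data = np.zeros((3, 3, 3))
    data[0, 0, 0], data[1, 1, 1] = 1.0, 3.0
    m2 = np.zeros((3, 3, 3), bool)
    m2[0, 0, 0] = m2[1, 1, 1] = True
    assert mean_signal(VolumeSample(data, np.eye(4)), m2) == pytest.approx(2.0)
    rand = rng.standard_normal((4, 4, 4))
    m3 = rng.random((4, 4, 4)) > 0.5
    assert mean_signal(VolumeSample(rand, np.eye(4)), m3) == pytest.approx(
        rand[m3].sum() / m3.sum(), abs=1e-12)
    with pytest.raises(ConfigError):
        mean_signal(vol, np.zeros((3, 3, 3), bool))


class TestMotionColumns:
    def test_zero_motion_gives_zero_columns(self):
        cols = motion_columns([RigidTransform()] * 5)
        assert cols.shape == (5, 12)
        np.testing.assert_array_equal(cols, 0.0)

    def test_step_motion_derivative_spike(self):
        log = [RigidTransform()] * 3 + [RigidTransform(shift_mm=(1, 0, 0))] * 3
        cols = motion_columns(log)
        d_tx = cols[:, 9]  # derivative of shift_x
        np.testing.assert_array_equal(d_tx, [0, 0, 0, 1, 0, 0])


def _feed_stage(stage, series, affine, motion=None):
    """Drive a regression stage directly, supplying motion as volreg would."""
    out = []
    stage.ready()
    n = series.shape[-1]
    for k in range(n):
        vol = VolumeSample(series[..., k], affine, index=k, onset_s=2.0 * k)
        if stage.needs_volreg:
            t = motion[k] if motion is not None else RigidTransform()
            stage.receive_motion(t, vol)
        out.extend(stage._proc(vol))
    return out


def test_retrospective_burn_in_count(rng):
    """Emitted volume count equals input count despite the waiting period."""
    series = rng.uniform(900, 1100, (4, 4, 4, 30))
    stage = RegressStage(tr_s=2.0, wait_num=12, use_motion=True,
                         use_motion_deriv=False)
    out = _feed_stage(stage, series, np.eye(4))
    assert len(out) == 30
    assert [v.index for v in out] == list(range(30))


def test_perfect_fit_leaves_tiny_residual(rng):
    """A series that is exactly a drift polynomial (plus baseline) must be
    regressed to ~zero."""
    n = 24
    x = np.linspace(-1, 1, n)
    drift = 3.0 * x  # linear: inside the drift span at every cumulative fit
    series = np.empty((3, 3, 3, n))
    base = rng.uniform(800, 1200, (3, 3, 3))
    for k in range(n):
        series[..., k] = base * (1 + drift[k] / 100)
    stage = RegressStage(tr_s=2.0, wait_num=10, use_motion=False,
                         use_motion_deriv=False)
    out = _feed_stage(stage, series, np.eye(4))
    resid = np.stack([v.data for v in out], -1)
    assert np.max(np.abs(resid)) <= 1e-6


def test_residuals_orthogonal_to_design(rng):
    series = rng.uniform(900, 1100, (3, 3, 3, 25))
    stage = RegressStage(tr_s=2.0, wait_num=25, use_motion=False,
                         use_motion_deriv=False)
    out = _feed_stage(stage, series, np.eye(4))
    R = np.stack([v.data.ravel() for v in out])  # rows x voxels
    X = stage.design_
    dots = X.T @ R
    bound = 1e-6 * np.linalg.norm(X, axis=0)[:, None] * \
        np.linalg.norm(R, axis=0)[None, :]
    assert np.all(np.abs(dots) <= bound + 1e-9)


def test_quadratic_drift_captured_once_order_reaches_two(rng):
    """A pure quadratic drift voxel is absorbed once d >= 150 s (order 2)."""
    n = 100  # 200 s at TR 2 -> final order 2
    x = np.linspace(-1, 1, n)
    quad = 4.0 * (3 * x**2 - 1) / 2
    base = np.full((2, 2, 2), 1000.0)
    series = np.stack([base * (1 + quad[k] / 100) for k in range(n)], -1)
    stage = RegressStage(tr_s=2.0, wait_num=20, use_motion=False,
                         use_motion_deriv=False)
    out = _feed_stage(stage, series, np.eye(4))
    final = out[-1].data
    scaled_sd = quad.std()
    assert np.abs(final).max() <= 0.1 * scaled_sd


def _random_motion(rng, n):
    return [RigidTransform(tuple(0.1 * rng.standard_normal(3)),
                           tuple(0.1 * rng.standard_normal(3)))
            for _ in range(n)]


def test_wait_num_guard_refuses_underdetermined_fit(rng):
    series = rng.uniform(900, 1100, (3, 3, 3, 30))
    motion = _random_motion(rng, 30)
    stage = RegressStage(tr_s=2.0, wait_num=10, use_motion=True,
                         use_motion_deriv=True)
    with pytest.raises(ConfigError, match="wait_num"):
        _feed_stage(stage, series, np.eye(4), motion=motion)


def test_overfit_warning_when_rows_below_twice_columns(rng):
    series = rng.uniform(900, 1100, (3, 3, 3, 30))
    motion = _random_motion(rng, 30)
    stage = RegressStage(tr_s=2.0, wait_num=20, use_motion=True,
                         use_motion_deriv=True)
    with pytest.warns(UserWarning, match="overfit"):
        _feed_stage(stage, series, np.eye(4), motion=motion)


def test_motion_family_contributes_12_columns(rng):
    series = rng.uniform(900, 1100, (3, 3, 3, 40))
    motion = _random_motion(rng, 40)
    stage = RegressStage(tr_s=2.0, wait_num=35, use_motion=True,
                         use_motion_deriv=True)
    _feed_stage(stage, series, np.eye(4), motion=motion)
    mot_labels = [l for l in stage.design_labels_
                  if l.startswith(("mot_", "dmot_"))]
    assert len(mot_labels) == 12


def test_final_residual_matches_one_shot_batch_ols(rng):
    """The cumulative fit at the last TR must equal batch OLS on the full
    run with the final design (the cGLM uses all samples)."""
    n = 40
    series = rng.uniform(900, 1100, (4, 4, 4, n))
    stage = RegressStage(tr_s=2.0, wait_num=15, use_motion=False,
                         use_motion_deriv=False)
    out = _feed_stage(stage, series, np.eye(4))
    # independent batch solve with the stage's final design
    X = stage.design_
    Y = np.stack(stage._scaled_rows)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_last = (Y - X @ beta)[-1].reshape(4, 4, 4)
    np.testing.assert_allclose(out[-1].data, batch_last, atol=1e-6)


def test_empty_tissue_mask_rejected():
    with pytest.raises(ConfigError):
        RegressStage(tr_s=2.0, gs_mask=np.zeros((2, 2, 2), bool))
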