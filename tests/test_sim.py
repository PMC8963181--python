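import shutil
import threading
import time

import numpy as np
import nibabel as nib
import pytest

from rtfmri.sim import build_pipeline, run_simulation
from rtfmri.synthetic import PhantomSpec, write_fixture
from rtfmri.volume import VolumeSample, write_volume
from rtfmri.watch import watch_volumes


def _write_vols(dir_path, n, shape=(4, 4, 4), seed=0):
    rng = np.random.default_rng(seed)
    for i in range(n):
        write_volume(VolumeSample(rng.standard_normal(shape).astype(np.float32),
                                  np.eye(4), index=i),
                     dir_path / f"vol_{i:04d}.nii")


class TestWatch:
    def test_sequential_files_emitted_in_order(self, tmp_path):
        _write_vols(tmp_path, 5)
        vols = list(watch_volumes(tmp_path, n_expected=5, timeout_s=5))
        assert [v.index for v in vols] == [0, 1, 2, 3, 4]

    def test_out_of_order_creation_keeps_filename_index(self, tmp_path):
        rng = np.random.default_rng(1)
        for i in (2, 1):
            write_volume(VolumeSample(rng.standard_normal((3, 3, 3)),
                                      np.eye(4), index=i),
                         tmp_path / f"vol_{i:04d}.nii")
            time.sleep(0.02)
        with pytest.warns(UserWarning):
            vols = list(watch_volumes(tmp_path, n_expected=2, timeout_s=5))
        # emitted in creation order, indexed from the filename
        assert [v.index for v in vols] == [2, 1]

    def test_non_matching_files_ignored(self, tmp_path):
        _write_vols(tmp_path, 2)
        (tmp_path / "notes.txt").write_text("not a volume")
        vols = list(watch_volumes(tmp_path, pattern=r"vol_.*\.nii$",
                                  n_expected=2, timeout_s=5))
        assert len(vols) == 2

    def test_each_file_read_once_while_streaming(self, tmp_path):
        """Files appearing while the watcher runs are emitted exactly once."""
        rng = np.random.default_rng(2)

        def producer():
            for i in range(4):
                write_volume(
                    VolumeSample(rng.standard_normal((3, 3, 3)), np.eye(4),
                                 index=i), tmp_path / f"vol_{i:04d}.nii")
                time.sleep(0.08)

        t = threading.Thread(target=producer)
        t.start()
        vols = list(watch_volumes(tmp_path, n_expected=4, timeout_s=10))
        t.join()
        assert [v.index for v in vols] == [0, 1, 2, 3]

    def test_ignore_init_discards_initial_volumes(self, tmp_path):
        _write_vols(tmp_path, 5)
        vols = list(watch_volumes(tmp_path, n_expected=3, timeout_s=5,
                                  ignore_init=2))
        assert [v.index for v in vols] == [2, 3, 4]


@pytest.fixture(scope="module")
def small_fixture(tmp_path_factory):
    """A small phantom written to disk for replay tests."""
    out = tmp_path_factory.mktemp("fix")
    spec = PhantomSpec(shape=(16, 16, 8), n_vols=10, seed=7)
    paths = write_fixture(out, spec)
    return spec, paths


def _config(spec, work_dir, masks):
    return {
        "run": {"tr_s": spec.tr_s, "n_slices": spec.shape[2],
                "work_dir": str(work_dir)},
        "tshift": {"enabled": True, "method": "cubic"},
        "volreg": {"enabled": True, "interp": "heptic"},
        "smooth": {"enabled": True, "fwhm_mm": 6.0,
                   "mask": masks["mask_brain"]},
        "app": {"roi_mask": masks["mask_gm_roi"]},
    }


def test_simulation_outputs_and_determinism(small_fixture, tmp_path):
    spec, paths = small_fixture
    outs = []
    for run in ("a", "b"):
        d = tmp_path / run
        arts = run_simulation(paths["series_4d"],
                              _config(spec, d, paths), out_dir=d)
        roi = (d / "roi_signal.csv").read_text()
        outs.append((roi, np.loadtxt(arts["motion"].as_posix())))
    assert outs[0][0] == outs[1][0]
    np.testing.assert_array_equal(outs[0][1], outs[1][1])
    rows = outs[0][0].strip().splitlines()
    assert len(rows) == 11  # header + one row per volume


def test_direct_injection_equals_file_watch_replay(small_fixture, tmp_path):
    """Streaming files through the watcher and injecting the 4D series
    directly must produce bitwise-identical outputs."""
    spec, paths = small_fixture
    inj_dir = tmp_path / "inject"
    arts = run_simulation(paths["series_4d"],
                          _config(spec, inj_dir, paths), out_dir=inj_dir)
    inj_motion = np.loadtxt(arts["motion"].as_posix())
    inj_roi = (inj_dir / "roi_signal.csv").read_text()

    watch_dir = tmp_path / "incoming"
    watch_dir.mkdir()
    head, meta = build_pipeline(_config(spec, tmp_path / "watch", paths))
    head.ready()

    def producer():
        for p in sorted(paths["vols_dir"].glob("vol_*.nii")):
            shutil.copy(p, watch_dir / p.name)
            time.sleep(0.05)

    t = threading.Thread(target=producer)
    t.start()
    for vol in watch_volumes(watch_dir, n_expected=10, timeout_s=20,
                             tr_s=meta.tr_s):
        head.do_proc(vol)
    t.join()
    arts_w = head.end_run(tmp_path / "watch")
    np.testing.assert_array_equal(np.loadtxt(arts_w["motion"].as_posix()),
                                  inj_motion)
    assert (tmp_path / "watch" / "roi_signal.csv").read_text() == inj_roi


def test_build_pipeline_requires_a_stage():
    with pytest.raises(ValueError):
        build_pipeline({"run": {"tr_s": 2.0}, "volreg": {"enabled": False}})
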