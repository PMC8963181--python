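import numpy as np
import pytest

from rtfmri.synthetic import PhantomSpec, make_phantom
from rtfmri.volume import VolumeSample


@pytest.fixture(scope="session")
def still_phantom():
    """Single noiseless, motionless phantom volume (registration reference)."""
    from rtfmri.volreg import RigidTransform

    spec = PhantomSpec(n_vols=1, noise_sd=0.0,
                       motion_truth=[RigidTransform()],
                       drift_tissue_sd_pct=0.0)
    res = make_phantom(spec)
    return VolumeSample(res.series[..., 0], res.affine, index=0), res


@pytest.fixture(scope="session")
def phantom120():
    """The default 32x32x16x120 phantom with full contamination (seed 1)."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.corrcoef(a, b)[0, 1])
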