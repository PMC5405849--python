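import numpy as np
import pytest

import surseg as ss


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 cellular phantom at SNR 5 with 1% stroke annotations."""
    v, gt = ss.make_phantom((64, 64, 64), snr=5.0, seed=0)
    ann = ss.sparse_annotations(gt, fraction=0.01, seed=0)
    return v, gt, ann


@pytest.fixture(scope="session")
def two_phase():
    """Noiseless two-phase phantom (bright ellipsoid in dark background)."""
    return ss.make_two_phase((40, 40, 40), seed=0)


@pytest.fixture(scope="session")
def two_phase_partition(two_phase):
    v, gt = two_phase
    return ss.slic_supervoxels(ss.gaussian(v, 1.0))


@pytest.fixture(scope="session")
def toy_stack():
    """Tiny feature stack with two known channels on a 6x5x4 grid."""
    rng = np.random.default_rng(42)
    shape = (6, 5, 4)
    fs = ss.FeatureStack(shape=shape)
    fs.add("a", rng.normal(size=shape).astype(np.float32), {"filter": "none"})
    fs.add("b", rng.uniform(size=shape).astype(np.float32), {"filter": "none"})
    return fs


@pytest.fixture()
def block_partition():
    """Deterministic 2-supervoxel partition of a 4x4x4 grid (split at z=2)."""
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[2:] = 1
    return ss.SupervoxelPartition(labels=labels, K=2, seed_spacing=(2, 4, 4),
                                  compactness=30.0)
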