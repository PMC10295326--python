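import numpy as np
import pytest

from trabeculagen.core import VoxelVolume
from trabeculagen.phantom import PhantomSpec, generate_trabecular_volume, render_mdct, render_micro_ct

# a small phantom geometry shared by many tests: ~10 mm vertebra at native
# 52 um resolution, 30 micro-CT slices
SMALL = dict(
    extent_mm=(1.56, 10.0, 10.0),
    body_semiaxes_mm=(4.4, 4.6),
    canal_radius_mm=1.2,
    gt_region_mm=(1.2, 4.0, 4.0),
)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_gt(small_spec):
    return generate_trabecular_volume(small_spec)


@pytest.fixture(scope="session")
def small_micro(small_gt):
    return render_micro_ct(small_gt)


@pytest.fixture(scope="session")
def small_mdct(small_gt):
    return render_mdct(small_gt)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_thickness(fg: np.ndarray) -> np.ndarray:
    """Independent largest-inscribed-sphere oracle.

    For every candidate centre c (all foreground voxels) the largest digital
    sphere radius is found by direct pairwise distance to background voxels;
    each voxel then takes the diameter of the largest sphere covering it.
    Out-of-array space behaves as if the phase continued.
    """
    from scipy.spatial import cKDTree

    fg = fg.astype(bool)
    pts = np.argwhere(fg)
    bg = np.argwhere(~fg)
    out = np.zeros(fg.shape)
    if bg.size:
        r2 = np.rint(cKDTree(bg).query(pts)[0] ** 2).astype(np.int64)
    else:
        r2 = np.full(len(pts), int(np.sum(np.array(fg.shape) ** 2)))
    diam = 2.0 * np.sqrt(r2.astype(float)) - 1.0
    for v in pts:
        dd2 = ((pts - v) ** 2).sum(axis=1)
        cover = dd2 <= r2 - 1
        out[tuple(v)] = diam[cover].max()
    return out


def volume(data, voxel=1.0):
    return VoxelVolume(np.asarray(data), (voxel, voxel, voxel))
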