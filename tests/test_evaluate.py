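"""Similarity metrics and statistics, checked against closed forms and
independent reimplementations."""

import numpy as np
import pytest
from scipy import linalg, ndimage

from trabeculagen.core import VoxelVolume
from trabeculagen.evaluate import (RandomConvProjector, cancellous_crop,
                                   compare_correlations, compare_methods,
                                   embed, fid, full_report, icc,
                                   regress_metrics, ssim, SimilarityReport)


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def windowed_ssim_oracle(a, b, L=255.0, sigma=1.5, win=11):
    """Independent reimplementation: per-window Gaussian-weighted SSIM over
    all fully valid window positions, averaged."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    r = win // 2
    g = np.exp(-(np.arange(win) - r) ** 2 / (2 * sigma ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    C1, C2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    vals = []
    for i in range(a.shape[0] - win + 1):
        for j in range(a.shape[1] - win + 1):
            wa = a[i:i + win, j:j + win]
            wb = b[i:i + win, j:j + win]
            mua, mub = (w * wa).sum(), (w * wb).sum()
            va = (w * wa * wa).sum() - mua ** 2
            vb = (w * wb * wb).sum() - mub ** 2
            cov = (w * wa * wb).sum() - mua * mub
            vals.append(((2 * mua * mub + C1) * (2 * cov + C2))
                        / ((mua ** 2 + mub ** 2 + C1) * (va + vb + C2)))
    return float(np.mean(vals))


def test_ssim_identity_exact(rng):
    a = rng.integers(0, 255, (32, 32)).astype(np.uint8)
    assert ssim(a, a) == 1.0


def test_ssim_symmetry(rng):
    a = rng.integers(0, 255, (32, 32)).astype(np.uint8)
    b = rng.integers(0, 255, (32, 32)).astype(np.uint8)
    assert ssim(a, b) == ssim(b, a)


def test_ssim_constant_images_closed_form():
    a = np.full((16, 16), 100.0)
    b = np.full((16, 16), 140.0)
    C1 = (0.01 * 255) ** 2
    expected = (2 * 100 * 140 + C1) / (100 ** 2 + 140 ** 2 + C1)
    assert ssim(a, b) == pytest.approx(expected, rel=1e-9)


def test_ssim_matches_windowed_oracle(rng):
    a = ndimage.gaussian_filter(rng.normal(128, 40, (16, 16)), 1.0)
    b = a + rng.normal(0, 20, a.shape)
    a, b = np.clip(a, 0, 255), np.clip(b, 0, 255)
    assert ssim(a, b) == pytest.approx(windowed_ssim_oracle(a, b), abs=1e-7)


def test_ssim_shape_mismatch():
    with pytest.raises(ValueError):
        ssim(np.zeros((8, 8)), np.zeros((9, 9)))


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

def test_fid_identical_sets_zero(rng):
    f = rng.normal(0, 1, (20, 6))
    assert fid(f, f) <= 1e-6


def test_fid_1d_closed_form():
    # sample moments (0,1) and (1,1) exactly (ddof=1): FID = 1
    s = np.sqrt(0.5)
    a = np.array([[-s], [s]])
    b = a + 1.0
    assert fid(a, b) == pytest.approx(1.0, abs=1e-9)


def test_fid_matches_sqrtm_oracle(rng):
    fa = rng.normal(0, 1, (30, 5))
    fb = rng.normal(0.3, 1.4, (25, 5))
    mine = fid(fa, fb)
    mu1, mu2 = fa.mean(0), fb.mean(0)
    s1, s2 = np.cov(fa, rowvar=False), np.cov(fb, rowvar=False)
    covmean = linalg.sqrtm(s1 @ s2)
    ref = float(((mu1 - mu2) ** 2).sum() + np.trace(s1 + s2 - 2 * covmean.real))
    assert mine == pytest.approx(ref, rel=1e-6)


def test_fid_symmetry_and_nonneg(rng):
    fa = rng.normal(0, 1, (12, 4))
    fb = rng.normal(1, 2, (15, 4))
    assert fid(fa, fb) == pytest.approx(fid(fb, fa), rel=1e-8)
    assert fid(fa, fb) >= 0


def test_fid_input_validation(rng):
    with pytest.raises(ValueError):
        fid(rng.normal(0, 1, (5, 3)), rng.normal(0, 1, (5, 4)))
    with pytest.raises(ValueError):
        fid(rng.normal(0, 1, (1, 3)), rng.normal(0, 1, (5, 3)))


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def test_embed_deterministic_per_seed(rng):
    imgs = rng.integers(0, 255, (4, 48, 48)).astype(np.uint8)
    f1 = embed(imgs, RandomConvProjector(seed=5))
    f2 = embed(imgs, RandomConvProjector(seed=5))
    f3 = embed(imgs, RandomConvProjector(seed=6))
    assert np.array_equal(f1, f2)
    assert not np.allclose(f1, f3)
    assert np.allclose(f1[0], embed(imgs[0], RandomConvProjector(seed=5))[0], atol=1e-6)


def test_embed_separates_texture_classes(rng):
    """Smooth blobby textures vs fine-grained noise should separate in the
    random projector's feature space (positive silhouette)."""
    from sklearn.metrics import silhouette_score
    smooth = np.stack([
        np.clip(ndimage.gaussian_filter(rng.normal(128, 120, (48, 48)), 3.0), 0, 255)
        for _ in range(8)
    ]).astype(np.uint8)
    grain = rng.integers(0, 255, (8, 48, 48)).astype(np.uint8)
    f = embed(np.concatenate([smooth, grain]))
    labels = np.array([0] * 8 + [1] * 8)
    assert silhouette_score(f, labels) > 0


# ---------------------------------------------------------------------------
# cancellous crop
# ---------------------------------------------------------------------------

def disk_volume(r_mm=8.0, voxel=0.25, nz=12):
    n = int(2 * (r_mm + 2) / voxel)
    c = n * voxel / 2
    yy, xx = np.meshgrid(*((np.arange(n) + 0.5) * voxel - c,) * 2, indexing="ij")
    disk = (yy ** 2 + xx ** 2) <= r_mm ** 2
    mask = np.broadcast_to(disk, (nz, n, n)).astype(np.uint8)
    vol = VoxelVolume(np.full(mask.shape, 90, np.uint8), (voxel,) * 3)
    return vol, VoxelVolume(mask, (voxel,) * 3)


def test_cancellous_crop_erosion_matches_distance_oracle():
    vol, body = disk_volume()
    _, eroded = cancellous_crop(vol, body, cortical_thickness_mm=1.0, margin_mm=0.5)
    # oracle: voxels farther than 1.5 mm from the boundary, by direct distance
    dist = ndimage.distance_transform_edt(body.data.astype(bool),
                                          sampling=body.voxel_size)
    ref = dist > 1.5
    idx = np.nonzero(ref)
    sl = tuple(slice(i.min(), i.max() + 1) for i in idx)
    assert np.array_equal(eroded, ref[sl])


def test_cancellous_crop_idempotent():
    vol, body = disk_volume()
    c1, m1 = cancellous_crop(vol, body, cortical_thickness_mm=1.0)
    body2 = VoxelVolume(m1.astype(np.uint8), vol.voxel_size)
    c2, m2 = cancellous_crop(c1, body2, cortical_thickness_mm=0.0)
    assert c2.data.shape == c1.data.shape
    assert np.array_equal(m2, m1)


def test_cancellous_crop_empty_errors():
    vol, body = disk_volume(r_mm=2.0)
    with pytest.raises(ValueError):
        cancellous_crop(vol, body, cortical_thickness_mm=5.0)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_compare_methods_identical_groups():
    ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    reports = compare_methods(ref, {"m1": ref.copy(), "m2": ref.copy()})
    fr = next(r for r in reports if r.test == "friedman")
    assert fr.statistic == pytest.approx(0.0)
    t = next(r for r in reports if r.test == "paired-t")
    assert t.p_value == pytest.approx(1.0)


def test_mann_whitney_disjoint_support():
    ref = np.array([10.0, 11.0, 12.0])
    low = np.array([1.0, 2.0, 3.0])
    reports = compare_methods(ref, {"low": low})
    u = next(r for r in reports if r.test == "mann-whitney-u")
    assert u.statistic == 0.0  # every low value below every reference value


def test_compare_methods_requires_pairing():
    with pytest.raises(ValueError):
        compare_methods(np.arange(5.0), {"m": np.arange(4.0)})


def test_regression_perfect_line():
    x = np.array([0.1, 0.2, 0.3, 0.4])
    r = regress_metrics(x, x)
    assert r.effect["slope"] == pytest.approx(1.0)
    assert r.effect["r2"] == pytest.approx(1.0)


def test_regression_hand_computed_four_points():
    # x=[0,1,2,3], y=[1,3,2,6]: Sxy=7, Sxx=5 -> slope 1.4, intercept 0.9,
    # Syy=14 -> R^2 = 1.4*7/14 = 0.7, F = 0.7*2/0.3 = 14/3
    r = regress_metrics([0, 1, 2, 3], [1, 3, 2, 6])
    assert r.effect["slope"] == pytest.approx(1.4)
    assert r.effect["intercept"] == pytest.approx(0.9)
    assert r.effect["r2"] == pytest.approx(0.7)
    assert r.effect["f"] == pytest.approx(14 / 3)


def test_regression_orthogonal_noise_r2_near_zero(rng):
    x = np.linspace(0, 1, 200)
    y = rng.normal(0, 1, 200)
    r = regress_metrics(x, y)
    assert r.effect["r2"] < 0.05


def test_regression_validation():
    with pytest.raises(ValueError):
        regress_metrics([1.0, 1.0, 1.0], [1, 2, 3])


def test_fisher_z_identities_and_plugin():
    z, p = compare_correlations(0.6, 30, 0.6, 50)
    assert z == 0.0 and p == 1.0
    z1, _ = compare_correlations(0.8, 50, 0.5, 50)
    # (atanh(.8)-atanh(.5)) / sqrt(2/47), evaluated independently
    expected = (np.arctanh(0.8) - np.arctanh(0.5)) / np.sqrt(2 / 47)
    assert z1 == pytest.approx(expected, rel=1e-12)
    assert z1 == pytest.approx(2.66284, abs=1e-4)
    z2, _ = compare_correlations(0.5, 50, 0.8, 50)
    assert z2 == pytest.approx(-z1)
    with pytest.raises(ValueError):
        compare_correlations(1.0, 10, 0.5, 10)


def icc21_oracle(a):
    """ICC(2,1) from two-way ANOVA variance components, by hand."""
    a = np.asarray(a, float)
    n, k = a.shape
    grand = a.mean()
    msr = k * ((a.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((a.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sst = ((a - grand) ** 2).sum()
    sse = sst - (msr * (n - 1) + msc * (k - 1))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_identical_columns_is_one():
    col = np.array([1.0, 2, 3, 4, 5, 6])
    r = icc(np.column_stack([col, col]))
    assert r.statistic == pytest.approx(1.0)


def test_icc_matches_anova_oracle():
    table = np.array([[9.0, 2.0], [6.0, 1.0], [8.0, 4.0],
                      [7.0, 1.0], [10.0, 5.0], [6.0, 2.0]])
    r = icc(table)
    assert r.statistic == pytest.approx(icc21_oracle(table), abs=1e-9)
    lo, hi = r.effect["ci95"]
    assert lo <= r.statistic <= hi


def test_icc_independent_noise_near_zero(rng):
    a = rng.normal(0, 1, (100, 2))
    r = icc(a)
    assert abs(r.statistic) < 0.25


def test_icc_validation():
    with pytest.raises(ValueError):
        icc(np.zeros((3, 2)))
    with pytest.raises(ValueError):
        icc(np.ones((6, 2)))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def test_full_report_writes_files(tmp_path, rng):
    rep = SimilarityReport(scope="overall",
                           ssim_values=rng.random(5),
                           fid_value=1.23)
    stats = compare_methods(np.arange(5.0), {"m": np.arange(5.0) + rng.random(5)})
    paths = full_report({"m": rep}, stats, tmp_path / "report")
    for p in paths.values():
        assert p.exists()
    text = (tmp_path / "report" / "summary.txt").read_text()
    assert "random" in text  # extractor caveat stated in the header


def test_full_report_empty_errors(tmp_path):
    with pytest.raises(ValueError):
        full_report({}, [], tmp_path)
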