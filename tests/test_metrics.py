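"""Metric suite: closed-form oracles, perfect-match identities, decompositions."""

import warnings

import numpy as np
import pytest

from vstain import metrics as mx


# ------------------------------------------------------------- partitioning
def test_canonical_25_cube_layout():
    vol = np.zeros((128, 640, 640), np.uint8)
    part = mx.partition_cubes(vol, edge=128)
    assert part.count == 25


def test_exact_and_remainder_partitions():
    assert mx.partition_cubes(np.zeros((128,) * 3, np.uint8), 128).count == 1
    part = mx.partition_cubes(np.zeros((130,) * 3, np.uint8), 128)
    assert part.count == 1 and part.origins == [(0, 0, 0)]
    with pytest.raises(ValueError):
        mx.partition_cubes(np.zeros((64, 64, 64), np.uint8), 128)


# ------------------------------------------------------------- pixel metrics
def test_identical_images_have_zero_errors_and_inf_psnr(rng):
    img = rng.uniform(0, 1, (16, 16))
    vals = mx.pixel_metrics(img, img)
    assert vals["MSE"] == vals["MAE"] == vals["MSLE"] == vals["RMSE"] == 0.0
    assert vals["PSNR"] == np.inf


def test_psnr_closed_form():
    # peak 255, MSE 25 -> 10 log10(255^2/25) = 34.1514 dB
    gt = np.full((10, 10), 255.0)
    pred = gt - 5.0
    vals = mx.pixel_metrics(pred, gt)
    assert vals["MSE"] == pytest.approx(25.0)
    assert vals["PSNR"] == pytest.approx(10 * np.log10(255 ** 2 / 25), abs=1e-6)
    assert vals["PSNR"] == pytest.approx(34.15, abs=0.01)


def test_two_pixel_hand_arithmetic():
    vals = mx.pixel_metrics(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
    assert vals["MSE"] == pytest.approx(0.5)
    assert vals["MAE"] == pytest.approx(0.5)
    assert vals["RMSE"] == pytest.approx(np.sqrt(0.5), abs=1e-9)


def test_mse_rmse_and_jensen_relations(rng):
    for _ in range(5):
        p, g = rng.normal(size=(12, 12)), rng.normal(size=(12, 12))
        vals = mx.pixel_metrics(p, g)
        assert vals["RMSE"] ** 2 == pytest.approx(vals["MSE"], rel=1e-12)
        assert vals["MAE"] <= vals["RMSE"] + 1e-12


def test_msle_shifts_negative_inputs(rng):
    p = rng.uniform(-1, 1, (8, 8))
    g = rng.uniform(-1, 1, (8, 8))
    vals = mx.pixel_metrics(p, g)
    assert np.isfinite(vals["MSLE"]) and vals["MSLE"] >= 0


# -------------------------------------------------------- structural metrics
def test_ssim_identities(rng):
    img = rng.uniform(0, 1, (32, 32))
    assert mx.ssim(img, img) == pytest.approx(1.0)
    assert mx.ms_ssim(img, img) == pytest.approx(1.0, abs=1e-6)
    other = rng.uniform(0, 1, (32, 32))
    assert mx.ssim(img, other, data_range=1.0) == pytest.approx(
        mx.ssim(other, img, data_range=1.0), abs=1e-9)


def test_ssim_negative_for_inverted_binary(rng):
    img = (rng.uniform(0, 1, (32, 32)) > 0.5).astype(float)
    assert mx.ssim(1.0 - img, img, data_range=1.0) < 0


def test_ms_ssim_uses_fewer_scales_on_small_images(rng):
    img = rng.uniform(0, 1, (16, 16))
    noisy = img + rng.normal(0, 0.05, img.shape)
    value = mx.ms_ssim(noisy, img)
    assert -1.0 <= value <= 1.0


# ------------------------------------------------------------ vector metrics
def test_vector_metric_identities(rng):
    img = rng.uniform(0, 1, (10, 10))
    vals = mx.vector_metrics(img, img)
    assert vals["COS"] == pytest.approx(1.0)
    assert vals["CoC"] == pytest.approx(1.0)


def test_affine_transform_keeps_correlation_not_cosine(rng):
    gt = rng.uniform(0, 1, (10, 10))
    pred = 2.0 * gt + 3.0
    vals = mx.vector_metrics(pred, gt)
    assert vals["CoC"] == pytest.approx(1.0, abs=1e-9)
    assert vals["COS"] < 1.0 - 1e-6


def test_orthogonal_indicators_have_zero_cosine():
    a = np.array([1.0, 0.0, 1.0, 0.0])
    b = np.array([0.0, 1.0, 0.0, 1.0])
    assert mx.vector_metrics(a, b)["COS"] == pytest.approx(0.0)


def test_degenerate_vectors_warn_not_nan():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        vals = mx.vector_metrics(np.zeros((4, 4)), np.ones((4, 4)))
    assert np.isfinite(vals["COS"]) and np.isfinite(vals["CoC"])
    assert caught


# ------------------------------------------------------------------- FID
def test_fid_zero_for_identical_sample_sets(rng):
    samples = [rng.normal(size=(8, 8)) for _ in range(6)]
    assert mx.fid(samples, list(samples)) == pytest.approx(0.0, abs=1e-8)


def test_fid_univariate_gaussian_closed_form(rng):
    """N(0,1) vs N(2,1): FID -> (mean gap)^2 = 4 at large n."""
    a = rng.normal(0.0, 1.0, (4000, 1))
    b = rng.normal(2.0, 1.0, (4000, 1))
    value = mx.fid(list(a), list(b), mx.identity_features)
    assert value == pytest.approx(4.0, abs=0.4)


def test_fid_symmetric_and_nonnegative(rng):
    a = [rng.normal(size=(6, 6)) for _ in range(8)]
    b = [rng.normal(0.5, 1.2, size=(6, 6)) for _ in range(8)]
    ext = mx.LinearFeatureExtractor(n_features=4, seed=0)
    ab, ba = mx.fid(a, b, ext), mx.fid(b, a, ext)
    assert ab == pytest.approx(ba, rel=1e-6)
    assert ab >= 0


def test_fid_constant_extractor_returns_zero_with_warning(rng):
    a = [rng.normal(size=(4, 4)) for _ in range(4)]
    b = [rng.normal(size=(4, 4)) for _ in range(4)]
    with pytest.warns(UserWarning, match="degenerate"):
        assert mx.fid(a, b, lambda img: np.zeros(3)) == 0.0


def test_fid_requires_two_samples(rng):
    with pytest.raises(ValueError):
        mx.fid([rng.normal(size=(4, 4))], [rng.normal(size=(4, 4))] * 3)


# --------------------------------------------------------------- fg/bg split
def test_fg_bg_perfect_prediction(rng):
    gt = np.where(rng.uniform(size=(16, 16)) > 0.7, 0.9, 0.1)
    out = mx.fg_bg_metrics(gt, gt)
    assert out["foreground"]["MSE"] == 0.0
    assert out["background"]["MSE"] == 0.0


def test_errors_confined_to_foreground(rng):
    gt = np.where(rng.uniform(size=(16, 16)) > 0.7, 0.9, 0.1)
    mask = gt > 0.5
    pred = gt.copy()
    pred[mask] += 0.2
    out = mx.fg_bg_metrics(pred, gt)
    assert out["background"]["MSE"] == 0.0
    assert out["foreground"]["MSE"] > 0.0


def test_constant_gt_has_no_foreground_entry():
    with pytest.warns(UserWarning):
        out = mx.fg_bg_metrics(np.zeros((8, 8)), np.full((8, 8), 2.0))
    assert "foreground" not in out and "background" in out


# ------------------------------------------------------------- error heatmap
def test_heatmap_zero_for_identical(rng):
    img = rng.uniform(size=(45, 45))
    np.testing.assert_array_equal(mx.error_heatmap(img, img), np.zeros((9, 9)))


def test_heatmap_localizes_injected_error(rng):
    gt = rng.uniform(size=(45, 45))
    pred = gt.copy()
    pred[10:15, 20:25] += 1.0  # inside block (2, 4) of the 5x5-pixel grid
    grid = mx.error_heatmap(pred, gt)
    nonzero = np.argwhere(grid > 0)
    assert len(nonzero) == 1 and tuple(nonzero[0]) == (2, 4)


def test_block_decomposition_reproduces_global_mse(rng):
    pred = rng.uniform(size=(50, 47))  # remainders exercise the last blocks
    gt = rng.uniform(size=(50, 47))
    grid = mx.error_heatmap(pred, gt)
    hy, hx = 50 // 9, 47 // 9
    sizes = np.zeros((9, 9))
    for i in range(9):
        ny = hy if i < 8 else 50 - 8 * hy
        for j in range(9):
            nx = hx if j < 8 else 47 - 8 * hx
            sizes[i, j] = ny * nx
    weighted = (grid * sizes).sum() / sizes.sum()
    assert weighted == pytest.approx(np.mean((pred - gt) ** 2), rel=1e-12)


# --------------------------------------------------------------- cube suite
def test_cubewise_identical_volumes(rng):
    vol = rng.uniform(size=(32, 32, 64)).astype(np.float32)
    report = mx.evaluate_cubewise(vol, vol, cube_edge=32,
                                  feature_extractor=mx.LinearFeatureExtractor(4, 0))
    assert len(report.per_cube["MSE"]) == 2
    assert all(v == 0.0 for v in report.per_cube["MSE"])
    assert all(v == pytest.approx(1.0) for v in report.per_cube["SSIM"])
    assert all(len(v) == 2 for v in report.per_cube.values())
    assert report.summary["MSE"]["median"] == 0.0


def test_cubewise_mse_matches_per_cube_recomputation(rng):
    gt = rng.uniform(size=(32, 64, 32)).astype(np.float32)
    pred = gt + rng.normal(0, 0.1, gt.shape).astype(np.float32)
    part = mx.partition_cubes(gt, 32)
    report = mx.evaluate_cubewise(pred, gt, partition=part,
                                  feature_extractor=mx.LinearFeatureExtractor(4, 0))
    for i in range(part.count):
        p = mx.extract_cube(pred, part, i)
        g = mx.extract_cube(gt, part, i)
        assert report.per_cube["MSE"][i] == pytest.approx(
            float(np.mean((p.astype(np.float64) - g) ** 2)), rel=1e-6)


def test_summary_is_tukey_box_with_range_whiskers():
    s = mx.summarize([1.0, 2.0, 3.0, 4.0, 100.0])
    assert s["median"] == 3.0 and s["min"] == 1.0 and s["max"] == 100.0
    assert s["q1"] == 2.0 and s["q3"] == 4.0
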