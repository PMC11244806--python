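"""Loss oracles (brute-force / hand arithmetic) and training-loop contracts."""

import numpy as np
import pytest

from vstain import training as tr
from vstain.nn.autograd import Tensor

TINY_GEN = "c7s1-4, d8, R8 (x1), u4, c7s1-1"
TINY_DISC = "C4 - C8 - F1"


# ---------------------------------------------------------------- Otsu
def brute_force_otsu(image, nbins=256):
    """Independent oracle: scan all candidate thresholds, maximize
    between-class variance directly from the voxel values."""
    vals = np.asarray(image, dtype=float).ravel()
    lo, hi = vals.min(), vals.max()
    candidates = np.linspace(lo, hi, nbins, endpoint=False)[1:]
    best_t, best_s = lo, -np.inf
    for t in candidates:
        fg = vals > t
        n1, n0 = fg.sum(), (~fg).sum()
        if n1 == 0 or n0 == 0:
            continue
        w1, w0 = n1 / vals.size, n0 / vals.size
        s = w0 * w1 * (vals[fg].mean() - vals[~fg].mean()) ** 2
        if s > best_s:
            best_t, best_s = t, s
    return best_t


def test_otsu_separates_bimodal_halves():
    img = np.array([0.1] * 8 + [0.9] * 8).reshape(4, 4)
    t = tr.otsu_threshold(img)
    assert 0.1 < t < 0.9
    np.testing.assert_array_equal(tr.otsu_mask(img), img > 0.5)


def test_otsu_matches_brute_force_oracle(rng):
    img = np.concatenate([rng.normal(0.2, 0.05, 400), rng.normal(0.8, 0.05, 200)])
    ours = tr.otsu_threshold(img)
    oracle = brute_force_otsu(img)
    assert abs(ours - oracle) < 0.05
    # the masks agree except possibly at the boundary between the modes
    assert np.mean((img > ours) != (img > oracle)) < 0.02


def test_otsu_matches_skimage(rng):
    from skimage.filters import threshold_otsu
    img = rng.uniform(0, 1, (32, 32)) ** 2
    assert abs(tr.otsu_threshold(img) - threshold_otsu(img, nbins=256)) < 0.01


def test_otsu_constant_image_all_background():
    with pytest.warns(UserWarning, match="constant"):
        t = tr.otsu_threshold(np.full((8, 8), 3.0))
    assert not (np.full((8, 8), 3.0) > t).any()


def test_otsu_mask_invariant_under_affine_rescaling(rng):
    img = rng.uniform(0, 1, (24, 24))
    m1 = tr.otsu_mask(img)
    m2 = tr.otsu_mask(3.5 * img + 11.0)
    assert np.mean(m1 != m2) < 0.01


# ------------------------------------------------------------ weighted MSE
def test_weighted_mse_hand_example():
    target = np.array([[0.0, 0.0], [1.0, 1.0]])
    pred = np.array([[0.1, 0.1], [0.6, 0.6]])
    mask = np.array([[0, 0], [1, 1]], bool)
    # 0.2 * mean((0.1)^2) + 0.8 * mean((0.4)^2) = 0.2*0.01 + 0.8*0.16
    assert tr.weighted_mse(pred, target, mask, 0.2, 0.8) == pytest.approx(0.130, abs=1e-6)


def test_weighted_mse_perfect_prediction_is_zero(rng):
    x = rng.normal(size=(8, 8))
    mask = rng.uniform(size=(8, 8)) > 0.5
    assert tr.weighted_mse(x, x, mask) == 0.0


def test_weighted_mse_all_foreground_reduces_to_scaled_mse(rng):
    pred, target = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
    full = np.ones((6, 6), bool)
    expected = 0.8 * np.mean((pred - target) ** 2)
    assert tr.weighted_mse(pred, target, full, 0.2, 0.8) == pytest.approx(expected)


def test_weighted_mse_equal_weights_equal_regions_is_plain_mse(rng):
    pred = np.zeros((2, 4))
    target = np.array([[0.2] * 4, [0.2] * 4])  # equal MSE in both halves
    mask = np.array([[1] * 4, [0] * 4], bool)
    plain = np.mean((pred - target) ** 2)
    assert tr.weighted_mse(pred, target, mask, 0.5, 0.5) == pytest.approx(plain)


def test_weighted_mse_shape_mismatch():
    with pytest.raises(ValueError):
        tr.weighted_mse(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2), bool))


def test_weighted_mse_differentiable():
    pred = Tensor(np.array([[0.1, 0.1], [0.6, 0.6]], np.float32), requires_grad=True)
    target = Tensor(np.array([[0.0, 0.0], [1.0, 1.0]], np.float32))
    mask = np.array([[0, 0], [1, 1]], bool)
    loss = tr.weighted_mse(pred, target, mask, 0.2, 0.8)
    loss.backward()
    assert pred.grad is not None and np.all(np.isfinite(pred.grad))


# -------------------------------------------------------- adversarial losses
def test_adversarial_losses_at_optima():
    g0, d0 = tr.adversarial_losses(np.ones((3, 3)), np.zeros((3, 3)))
    assert d0 == pytest.approx(0.0)
    g1, _ = tr.adversarial_losses(np.ones((3, 3)), np.ones((3, 3)))
    assert g1 == pytest.approx(0.0)


def test_adversarial_losses_half_scores():
    _, d = tr.adversarial_losses(np.full((4, 4), 0.5), np.full((4, 4), 0.5))
    assert d == pytest.approx(0.5)  # 0.25 + 0.25


# --------------------------------------------------------------- cycle loss
def test_cycle_loss_modes():
    x = np.array([[0.0, 0.0], [1.0, 1.0]])
    rec = np.array([[0.1, 0.1], [0.6, 0.6]])
    assert tr.cycle_loss(x, x) == pytest.approx(0.0)
    assert tr.cycle_loss(x, rec, "mse") == pytest.approx(np.mean((x - rec) ** 2))
    mask = np.array([[0, 0], [1, 1]], bool)
    assert tr.cycle_loss(x, rec, "otsu", mask=mask) == pytest.approx(0.130, abs=1e-6)


def test_losses_nonnegative(rng):
    for _ in range(5):
        a, b = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        g, d = tr.adversarial_losses(a, b)
        assert g >= 0 and d >= 0
        assert tr.cycle_loss(a, b) >= 0


# ------------------------------------------------------------ training loop
def _toy_sets(rng, n=12, size=16):
    a = rng.uniform(-1, 1, (n, size, size)).astype(np.float32)
    return a, -a


def test_unpaired_smoke_run_completes(rng):
    a, b = _toy_sets(rng)
    cfg = tr.TrainConfig(dims=2, epochs=2, seed=0, gen_spec=TINY_GEN,
                         disc_spec=TINY_DISC)
    g_ab, g_ba, d_a, d_b, hist = tr.train_unpaired(cfg, a, b)
    assert len(hist.epochs) == 2
    for epoch in hist.epochs:
        assert all(np.isfinite(v) for v in epoch.values())
    assert g_ab(a[0]).shape == a[0].shape


def test_unpaired_training_reproducible_under_seed(rng):
    a, b = _toy_sets(rng, n=8)
    cfg = tr.TrainConfig(dims=2, epochs=2, seed=3, gen_spec=TINY_GEN,
                         disc_spec=TINY_DISC)
    *_, h1 = tr.train_unpaired(cfg, a, b)
    *_, h2 = tr.train_unpaired(cfg, a, b)
    np.testing.assert_allclose(h1.loss_trace(), h2.loss_trace(), rtol=1e-6)


def test_unpaired_rejects_mismatched_shapes(rng):
    cfg = tr.TrainConfig(dims=2, epochs=1, gen_spec=TINY_GEN, disc_spec=TINY_DISC)
    with pytest.raises(ValueError, match="incompatible"):
        tr.train_unpaired(cfg, rng.normal(size=(4, 16, 16)).astype(np.float32),
                          rng.normal(size=(4, 8, 8)).astype(np.float32))


def test_paired_identity_task_loss_decreases(rng):
    a = rng.uniform(-1, 1, (10, 16, 16)).astype(np.float32)
    cfg = tr.TrainConfig(dims=2, epochs=6, seed=1, unet_depth=2, unet_base_filters=4)
    model, hist = tr.train_paired(cfg, a, a)
    trace = hist.loss_trace()
    assert trace[-1] < trace[0]
    assert np.all(np.isfinite(trace))


def test_config_validation():
    with pytest.raises(ValueError):
        tr.TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        tr.TrainConfig(w_bg=0.5, w_fg=0.6)
    cfg3d = tr.TrainConfig.default_3d()
    assert cfg3d.epochs == 300 and cfg3d.dims == 3 and cfg3d.early_stopping
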