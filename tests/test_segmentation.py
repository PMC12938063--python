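"""Dilated U-Net building blocks: receptive fields, patching, loss,
augmentation, scheduling, and the toy-scale training smoke test."""

import numpy as np
import pytest

from aaastress.nn import EarlyStopping, PlateauScheduler
from aaastress.segmentation import (DilatedConvSpec, PatchSpec, TOY_CONFIG,
                                    UNetConfig, augment, dice_bce_loss,
                                    extract_patches, load_checkpoint,
                                    predict, reassemble, receptive_field,
                                    save_checkpoint, train)
from aaastress.segmetrics import dice


# ---------------------------------------------------------------------------
# Receptive field
# ---------------------------------------------------------------------------

def test_receptive_field_values():
    assert receptive_field(3, 1) == 3  # d=1 reduces to k
    assert receptive_field(3, 2) == 5
    # enumerate tap positions of a dilated 1-D kernel: span = taps[-1]+1
    k, d = 5, 3
    taps = [i * d for i in range(k)]
    assert receptive_field(k, d) == taps[-1] + 1 == 13


def test_receptive_field_monotone():
    for k in (1, 3, 5, 7):
        for d in (1, 2, 3, 4):
            assert receptive_field(k, d) <= receptive_field(k + 2, d)
            assert receptive_field(k, d) <= receptive_field(k, d + 1)


def test_receptive_field_rejects_even_or_nonpositive_kernels():
    for bad in (0, -3, 2, 4):
        with pytest.raises(ValueError):
            receptive_field(bad, 1)
    with pytest.raises(ValueError):
        DilatedConvSpec(k=3, d=0)
    assert DilatedConvSpec(k=3, d=2).rf == 5


# ---------------------------------------------------------------------------
# Patching
# ---------------------------------------------------------------------------

def test_exact_tiling_and_identity():
    img = np.arange(64 * 64, dtype=float).reshape(64, 64)
    patches, placement = extract_patches(img, PatchSpec(32, 32))
    assert len(patches) == 4
    whole, _ = extract_patches(img, PatchSpec(64, 64))
    np.testing.assert_array_equal(whole[0], img)


def test_patch_count_from_axis_offsets():
    """100x100, size 64, stride 32: offsets per axis are 0, 32, 36 (final
    offset flush with the edge), giving 3 x 3 patches."""
    img = np.zeros((100, 100))
    patches, placement = extract_patches(img, PatchSpec(64, 32))
    starts = sorted({i for i, _ in placement["starts"]})
    assert starts == [0, 32, 36]
    assert len(patches) == 9


def test_small_image_is_padded():
    img = np.random.default_rng(0).random((40, 40))
    for padding in ("reflect", "zero"):
        patches, placement = extract_patches(
            img, PatchSpec(64, 64, padding))
        assert patches.shape == (1, 64, 64)
        np.testing.assert_array_equal(patches[0][:40, :40], img)


def test_extract_rejects_empty():
    with pytest.raises(ValueError):
        extract_patches(np.zeros((0, 0)), PatchSpec(8, 8))


def test_extract_reassemble_lossless():
    rng = np.random.default_rng(1)
    img = rng.random((96, 128))
    for stride in (64, 32):
        patches, placement = extract_patches(img, PatchSpec(64, stride))
        for agg in ("mean", "max"):
            np.testing.assert_allclose(
                reassemble(patches, placement, agg), img, atol=1e-12)


def test_reassemble_overlap_mean():
    """Two half-overlapping constant patches average to (a+b)/2."""
    patches = np.stack([np.full((4, 4), 2.0), np.full((4, 4), 6.0)])
    placement = {"orig_shape": (4, 6), "padded_shape": (4, 6),
                 "starts": [(0, 0), (0, 2)], "size": 4}
    out = reassemble(patches, placement, "mean")
    np.testing.assert_allclose(out[:, 2:4], 4.0)
    np.testing.assert_allclose(out[:, 0:2], 2.0)
    np.testing.assert_allclose(out[:, 4:6], 6.0)


def test_reassemble_inconsistent_placement():
    patches = np.zeros((2, 4, 4))
    placement = {"orig_shape": (4, 8), "padded_shape": (4, 8),
                 "starts": [(0, 0)], "size": 4}
    with pytest.raises(ValueError):
        reassemble(patches, placement)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def test_loss_zero_at_perfect_prediction():
    rng = np.random.default_rng(2)
    target = (rng.random((32, 32)) > 0.5).astype(float)
    assert dice_bce_loss(target, target) < 1e-5


def test_bce_term_is_ln2_for_uninformative_prediction():
    target = np.ones((16, 16))
    probs = np.full((16, 16), 0.5)
    bce_only = dice_bce_loss(probs, target, w_dice=0.0, w_bce=1.0)
    assert bce_only == pytest.approx(np.log(2), rel=1e-9)


def test_dice_term_zero_for_both_empty():
    probs = np.zeros((8, 8))
    target = np.zeros((8, 8))
    # zero up to the probability clipping applied before the logarithms
    dice_only = dice_bce_loss(probs, target, w_bce=0.0, smoothing=1.0)
    assert dice_only == pytest.approx(0.0, abs=1e-5)


def test_loss_shape_mismatch():
    with pytest.raises(ValueError):
        dice_bce_loss(np.zeros((4, 4)), np.zeros((5, 5)))


def test_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.05, 0.95, (6, 6))
    t = (rng.random((6, 6)) > 0.5).astype(float)
    loss, grad = dice_bce_loss(p, t, return_grad=True)
    eps = 1e-7
    for idx in [(0, 0), (2, 3), (5, 5)]:
        pp = p.copy()
        pp[idx] += eps
        lp = dice_bce_loss(pp, t)
        pp[idx] -= 2 * eps
        lm = dice_bce_loss(pp, t)
        assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def test_augment_reproducible_and_binary(fusiform_volume):
    images, masks, _ = fusiform_volume
    img, msk = images[5], masks[5]
    a1 = augment(img, msk, seed=13)
    a2 = augment(img, msk, seed=13)
    np.testing.assert_array_equal(a1[0], a2[0])
    np.testing.assert_array_equal(a1[1], a2[1])
    assert set(np.unique(a1[1])) <= {0, 1}


def test_augment_flips_preserve_foreground_count(fusiform_volume):
    images, masks, _ = fusiform_volume
    img, msk = images[5], masks[5]
    for seed in range(5):
        _, m2 = augment(img, msk, seed=seed, max_rotation=0.0,
                        zoom_range=(1.0, 1.0), intensity_range=(1.0, 1.0))
        assert m2.sum() == msk.sum()  # flips are pixel-count preserving


def test_augment_intensity_scales_image_only(fusiform_volume):
    images, masks, _ = fusiform_volume
    img, msk = images[5], masks[5]
    i1, m1 = augment(img, msk, seed=21, max_rotation=0.0,
                     zoom_range=(1.0, 1.0), intensity_range=(1.0, 1.0))
    i2, m2 = augment(img, msk, seed=21, max_rotation=0.0,
                     zoom_range=(1.0, 1.0), intensity_range=(2.0, 2.0))
    np.testing.assert_array_equal(m1, m2)  # mask untouched by intensity
    np.testing.assert_allclose(i2, 2.0 * i1)


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------

def test_plateau_scheduler_halves_twice_on_scripted_plateau():
    """Factor 0.5, patience 5: two consecutive 5-epoch plateaus leave the
    learning rate at 1e-4 * 0.25."""
    sched = PlateauScheduler(lr=1e-4, factor=0.5, patience=5, min_lr=1e-6)
    sched.step(0.9)  # initial improvement
    for _ in range(5):
        lr = sched.step(0.5)
    assert lr == pytest.approx(5e-5)
    for _ in range(5):
        lr = sched.step(0.5)
    assert lr == pytest.approx(2.5e-5)


def test_plateau_scheduler_respects_floor():
    sched = PlateauScheduler(lr=4e-6, factor=0.5, patience=1, min_lr=1e-6)
    for _ in range(10):
        lr = sched.step(0.0)
    assert lr == pytest.approx(1e-6)


def test_early_stopping_patience():
    stopper = EarlyStopping(patience=5)
    assert not stopper.step(0.8)
    flags = [stopper.step(0.5) for _ in range(5)]
    assert flags == [False, False, False, False, True]


# ---------------------------------------------------------------------------
# Training and prediction (toy scale)
# ---------------------------------------------------------------------------

def test_train_rejects_empty_dataset():
    with pytest.raises(ValueError):
        train(TOY_CONFIG, [])


def test_config_validation():
    with pytest.raises(ValueError):
        UNetConfig(dilation_schedule=())
    with pytest.raises(ValueError):
        UNetConfig(patch=PatchSpec(50, 50))  # not divisible by 2^(depth-1)
    assert UNetConfig().dilation_schedule == (1, 2, 3, 1)
    assert UNetConfig().learning_rate == pytest.approx(1e-4)
    assert UNetConfig().batch_size == 16


def test_overfit_reaches_high_training_dice(overfit_run):
    """Toy-scale overfit on 10 phantom slices reaches Dice >= 0.95."""
    assert max(overfit_run["history"]["val_dice"]) >= 0.95
    assert len(overfit_run["history"]["loss"]) <= TOY_CONFIG.max_epochs


def test_training_is_deterministic():
    rng = np.random.default_rng(0)
    img = rng.random((16, 16))
    msk = (img > 0.5).astype(np.uint8)
    cfg = UNetConfig(dilation_schedule=(1, 2), base_channels=2,
                     patch=PatchSpec(16, 16), max_epochs=2,
                     augment=False, seed=5, batch_size=2)
    _, h1 = train(cfg, [(img, msk)])
    _, h2 = train(cfg, [(img, msk)])
    assert h1["loss"] == h2["loss"]


def test_predict_shapes_and_threshold(overfit_run):
    images, masks = overfit_run["images"], overfit_run["masks"]
    pred = predict(overfit_run["model"], images)
    assert pred.shape == images.shape
    assert set(np.unique(pred)) <= {0, 1}
    mean_dice = np.mean([dice(pred[i], masks[i])
                         for i in range(len(images))])
    assert mean_dice >= 0.9


def test_checkpoint_roundtrip(tmp_path, overfit_run):
    path = tmp_path / "model.npz"
    save_checkpoint(path, overfit_run["model"])
    restored = load_checkpoint(path)
    images = overfit_run["images"]
    np.testing.assert_array_equal(predict(restored, images[:2]),
                                  predict(overfit_run["model"], images[:2]))
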