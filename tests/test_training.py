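"""Losses, schedule, preprocessing, augmentation, patching, train loop."""

import math

import numpy as np
import pytest

from dnlseg.network import TEST_PRESET, build_model
from dnlseg.training import (TrainConfig, augment_ibv_style, combined_loss,
                             dice_loss, poly_lr_factor,
                             preprocess_drive_style, sample_patches, train,
                             weighted_cross_entropy)


# ----------------------------------------------------------------- schedule

def test_poly_factor_closed_forms():
    assert poly_lr_factor(1, 200, 0.9) == 1.0
    assert math.isclose(poly_lr_factor(101, 200, 0.9), 0.5 ** 0.9,
                        rel_tol=1e-12)
    assert math.isclose(poly_lr_factor(200, 200, 1.0), 1.0 / 200,
                        rel_tol=1e-12)


def test_poly_factor_strictly_decreasing():
    factors = [poly_lr_factor(e, 50, 0.9) for e in range(1, 51)]
    assert all(a > b for a, b in zip(factors, factors[1:]))


def test_poly_factor_rejects_out_of_range():
    with pytest.raises(ValueError):
        poly_lr_factor(0, 10, 0.9)
    with pytest.raises(ValueError):
        poly_lr_factor(11, 10, 0.9)


# ------------------------------------------------------------------- losses

def test_dice_loss_perfect_and_disjoint():
    target = np.zeros((4, 4))
    target[:2] = 1.0
    assert dice_loss(target, target) < 1e-6
    assert abs(dice_loss(1.0 - target, target) - 1.0) < 1e-6


def test_dice_loss_worked_fixture_is_one_third():
    target = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    pred = np.full(8, 0.5)
    assert math.isclose(dice_loss(pred, target), 1.0 / 3.0, abs_tol=1e-6)


def test_dice_loss_all_zero_pair_is_zero():
    z = np.zeros((3, 3))
    assert dice_loss(z, z) == 0.0


def test_wce_half_prediction_is_ln2():
    target = np.array([1.0, 0.0, 1.0, 0.0])
    pred = np.full(4, 0.5)
    assert math.isclose(weighted_cross_entropy(pred, target, 1.0),
                        math.log(2.0), abs_tol=1e-6)


def test_wce_unweighted_matches_scalar_loop(rng):
    pred = rng.uniform(0.05, 0.95, size=12)
    target = (rng.uniform(size=12) > 0.5).astype(float)
    expected = -np.mean([t * math.log(p) + (1 - t) * math.log(1 - p)
                         for p, t in zip(pred, target)])
    assert math.isclose(weighted_cross_entropy(pred, target, 1.0),
                        expected, abs_tol=1e-9)


def test_wce_perfect_confident_prediction_is_tiny():
    target = np.array([1.0, 0.0])
    assert weighted_cross_entropy(target, target, 2.0) < 1e-5


def test_combined_loss_is_sum_of_parts(rng):
    pred = rng.uniform(0.05, 0.95, size=(5, 5))
    target = (rng.uniform(size=(5, 5)) > 0.6).astype(float)
    cfg = TrainConfig(w_pos=1.5, dice_w=0.7, wce_w=0.3)
    expected = 0.7 * dice_loss(pred, target) \
        + 0.3 * weighted_cross_entropy(pred, target, 1.5)
    assert math.isclose(combined_loss(pred, target, cfg), expected,
                        rel_tol=1e-12)


def test_combined_loss_monotone_under_single_pixel_corruption():
    target = np.zeros((4, 4))
    target[1:3, 1:3] = 1.0
    perfect = target * 0.98 + 0.01     # confident correct prediction
    base = combined_loss(perfect, target, TrainConfig(w_pos=1.0))
    for i in range(4):
        for j in range(4):
            bad = perfect.copy()
            bad[i, j] = 1.0 - bad[i, j]
            assert combined_loss(bad, target, TrainConfig(w_pos=1.0)) > base


def test_losses_permutation_invariant(rng):
    pred = rng.uniform(0.05, 0.95, size=36)
    target = (rng.uniform(size=36) > 0.5).astype(float)
    perm = rng.permutation(36)
    assert math.isclose(dice_loss(pred, target),
                        dice_loss(pred[perm], target[perm]), rel_tol=1e-12)
    assert math.isclose(weighted_cross_entropy(pred, target, 2.0),
                        weighted_cross_entropy(pred[perm], target[perm], 2.0),
                        rel_tol=1e-12)


# ------------------------------------------------------------- preprocessing

def test_preprocess_standardises_random_input(rng):
    img = rng.uniform(size=(64, 64))
    out = preprocess_drive_style(img, clahe=False, gamma=1.0)
    assert abs(out.mean()) < 1e-9
    assert abs(out.std() - 1.0) < 1e-6


def test_preprocess_gray_ramp_identity_subtransforms():
    ramp = np.tile(np.linspace(0, 1, 32), (32, 1))
    out = preprocess_drive_style(ramp, clahe=False, gamma=1.0)
    expected = (ramp - ramp.mean()) / (ramp.std() + 1e-7)
    assert np.allclose(out, expected)


def test_preprocess_gamma_matches_pointwise_power(rng):
    img = rng.uniform(size=(16, 16))
    out = preprocess_drive_style(img, clahe=False, standardize=False,
                                 gamma=2.0)
    lo, hi = img.min(), img.max()
    unit = (img - lo) / (hi - lo + 1e-7)
    expected = np.array([[u ** 2.0 for u in row] for row in unit])
    assert np.allclose(out, expected)


def test_preprocess_rgb_converts_to_gray(rng):
    img = rng.uniform(size=(24, 24, 3))
    out = preprocess_drive_style(img, clahe=True, gamma=1.2)
    assert out.shape == (24, 24)


# ------------------------------------------------------------------ patches

def test_sample_patches_deterministic_and_congruent(rng):
    img = rng.uniform(size=(584, 565))
    msk = (rng.uniform(size=(584, 565)) > 0.9).astype(np.uint8)
    a = sample_patches(img, msk, 5, 96, seed=4)
    b = sample_patches(img, msk, 5, 96, seed=4)
    assert len(a) == 5
    for (ia, ma), (ib, mb) in zip(a, b):
        assert ia.shape == (96, 96) and ma.shape == (96, 96)
        assert np.array_equal(ia, ib) and np.array_equal(ma, mb)


def test_sample_patches_zero_mask_stays_zero(rng):
    img = rng.uniform(size=(120, 100))
    patches = sample_patches(img, np.zeros((120, 100)), 3, 48, seed=1)
    assert all(not m.any() for _, m in patches)


def test_sample_patches_empty_request():
    assert sample_patches(np.zeros((10, 10)), np.zeros((10, 10)), 0, 4, 0) == []


# ------------------------------------------------------------- augmentation

def test_vertical_flip_is_involution(rng):
    img = rng.uniform(size=(20, 20))
    msk = (rng.uniform(size=(20, 20)) > 0.8).astype(np.uint8)
    once_i, once_m = augment_ibv_style(img, msk, seed=0, max_rotation=0,
                                       max_scale=0, max_shear=0, flip_prob=1)
    twice_i, twice_m = augment_ibv_style(once_i, once_m, seed=0,
                                         max_rotation=0, max_scale=0,
                                         max_shear=0, flip_prob=1)
    assert np.allclose(twice_i, img)
    assert np.array_equal(twice_m, msk)
    assert once_m.sum() == msk.sum()      # flips preserve pixel counts


def test_identity_augmentation_is_noop(rng):
    img = rng.uniform(size=(16, 16))
    msk = (rng.uniform(size=(16, 16)) > 0.8).astype(np.uint8)
    out_i, out_m = augment_ibv_style(img, msk, seed=0, max_rotation=0,
                                     max_scale=0, max_shear=0, flip_prob=0)
    assert np.allclose(out_i, img)
    assert np.array_equal(out_m, msk)


def test_augmentation_reproducible_and_mask_binary(rng):
    img = rng.uniform(size=(32, 32))
    msk = (rng.uniform(size=(32, 32)) > 0.7).astype(np.uint8)
    a_i, a_m = augment_ibv_style(img, msk, seed=42)
    b_i, b_m = augment_ibv_style(img, msk, seed=42)
    assert np.array_equal(a_i, b_i) and np.array_equal(a_m, b_m)
    assert set(np.unique(a_m)) <= {0, 1}


# --------------------------------------------------------------- train loop

def _tiny_dataset(rng, n=6, size=16):
    out = []
    for _ in range(n):
        msk = np.zeros((size, size))
        r = int(rng.integers(2, size - 4))
        msk[r:r + 2] = 1.0
        img = msk * 0.8 + 0.1 + rng.normal(0, 0.02, size=(size, size))
        out.append((img, msk))
    return out


def test_train_lr_trace_follows_poly_schedule(rng):
    model = build_model(TEST_PRESET, seed=0)
    cfg = TrainConfig(seed=0, total_epochs=4, batch_size=2)
    log = train(model, _tiny_dataset(rng), cfg)
    for epoch, lr, _, _ in log.rows:
        assert math.isclose(lr, cfg.initial_lr *
                            poly_lr_factor(epoch, 4, cfg.power),
                            rel_tol=1e-12)


def test_train_is_bit_reproducible(rng):
    ds = _tiny_dataset(rng)
    cfg = TrainConfig(seed=7, total_epochs=2, batch_size=2)
    m1 = build_model(TEST_PRESET, seed=7)
    m2 = build_model(TEST_PRESET, seed=7)
    log1 = train(m1, ds, cfg)
    log2 = train(m2, ds, cfg)
    assert log1.rows == log2.rows
    for p, q in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(p.data, q.data)


def test_train_rejects_empty_dataset():
    with pytest.raises(ValueError, match="empty"):
        train(build_model(TEST_PRESET, seed=0), [], TrainConfig())


def test_train_config_yaml_roundtrip():
    cfg = TrainConfig(total_epochs=17, w_pos=2.5, augment=True, seed=9)
    assert TrainConfig.from_yaml(cfg.to_yaml()) == cfg


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(initial_lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(total_epochs=0)
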