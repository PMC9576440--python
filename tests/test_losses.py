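"""Dice, focal and combined losses against analytic and oracle values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctlungseg import LossConfig, combined_loss, dice_loss, focal_loss
from ctlungseg.nn import Tensor


def square_mask(at, size=8):
    m = np.zeros((size, size))
    r, c = at
    m[r : r + 2, c : c + 2] = 1.0
    return m


class TestDiceLoss:
    def test_identical_nonempty_masks_score_zero(self):
        m = square_mask((2, 2))
        assert dice_loss(m, m, smooth=1e-7) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_nonempty_masks_score_one(self):
        a, b = square_mask((0, 0)), square_mask((5, 5))
        assert dice_loss(a, b, smooth=1e-7) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap_toy_value(self):
        # 4 true positives in e, 4 in f, 2 shared: 1 - 2*2/(4+4) = 0.5
        e = np.zeros((4, 4))
        e[0, :4] = 1
        f = np.zeros((4, 4))
        f[0, 2:4] = 1
        f[1, 0:2] = 1
        assert dice_loss(e, f, smooth=1e-9) == pytest.approx(0.5, abs=1e-6)

    def test_adding_correct_positive_never_increases_loss(self, rng):
        e = (rng.random((12, 12)) > 0.6).astype(float)
        f = rng.uniform(0, 1, (12, 12)) * e  # predictions only on positives
        base = dice_loss(e, f, smooth=1e-6)
        wrong = np.flatnonzero((e > 0) & (f.ravel().reshape(e.shape) < 1))
        if len(wrong):
            f2 = f.copy()
            f2.ravel()[wrong[0]] = 1.0  # one more fully-correct positive
            assert dice_loss(e, f2, smooth=1e-6) <= base

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="binary"):
            dice_loss(np.full((2, 2), 0.5), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="probabilities"):
            dice_loss(np.zeros((2, 2)), np.full((2, 2), 1.5))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_range_is_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        e = (r.random((6, 6)) > 0.5).astype(float)
        f = r.uniform(0, 1, (6, 6))
        val = dice_loss(e, f, smooth=1e-6)
        assert 0.0 <= val <= 1.0


class TestFocalLoss:
    def test_confident_correct_prediction_has_near_zero_loss(self):
        e = square_mask((1, 1))
        f = np.where(e > 0, 1 - 1e-9, 1e-9)
        assert focal_loss(e, f) == pytest.approx(0.0, abs=1e-6)

    def test_reduces_to_half_bce_when_unfocused(self, rng):
        cfg = LossConfig(focal_alpha=0.5, focal_gamma=0.0)
        for _ in range(100):
            e = (rng.random(64) > 0.5).astype(float)
            f = rng.uniform(1e-4, 1 - 1e-4, 64)
            bce = -(e * np.log(f) + (1 - e) * np.log(1 - f)).mean()
            assert focal_loss(e, f, cfg) == pytest.approx(0.5 * bce, abs=1e-6)

    def test_single_positive_pixel_hand_value(self):
        # −ɑ(1−y′)^r·log y′ with ɑ=0.25, r=2, y′=0.9
        e = np.ones((1,))
        f = np.array([0.9])
        expected = -0.25 * 0.1**2 * np.log(0.9)
        cfg = LossConfig(focal_alpha=0.25, focal_gamma=2.0)
        assert focal_loss(e, f, cfg) == pytest.approx(expected, rel=1e-9)

    def test_gamma_downweights_easy_pixels(self):
        e = np.ones((4,))
        f = np.full(4, 0.8)
        sharp = focal_loss(e, f, LossConfig(focal_gamma=2.0))
        flat = focal_loss(e, f, LossConfig(focal_gamma=0.0))
        assert sharp < flat


class TestCombinedLoss:
    def test_perfect_overlap_bottoms_out_at_log_floor(self):
        m = square_mask((3, 3))
        f = np.where(m > 0, 1 - 1e-12, 1e-12)
        cfg = LossConfig(smooth=1e-9, log_floor=1e-4)
        # Dice term clamps to log_floor, focal term ~ 0
        assert combined_loss(m, f, cfg) == pytest.approx(0.3 * np.log(1e-4), abs=1e-3)

    def test_disjoint_masks_reduce_to_focal_term(self):
        a, b = square_mask((0, 0)), square_mask((5, 5))
        f = np.where(b > 0, 1 - 1e-9, 1e-9)
        cfg = LossConfig(smooth=1e-12)
        # L_Dice = 1 so the log term vanishes
        assert combined_loss(a, f, cfg) == pytest.approx(
            focal_loss(a, f, cfg), abs=1e-9
        )

    def test_default_weight_is_0_3(self):
        assert LossConfig().alpha_combined == 0.3

    def test_always_finite(self, rng):
        e = (rng.random((8, 8)) > 0.5).astype(float)
        for f in (np.zeros((8, 8)), np.ones((8, 8)), rng.uniform(0, 1, (8, 8))):
            assert np.isfinite(combined_loss(e, f))


class TestGradientsOnToyProblem:
    """Autodiff vs central finite differences on a 2-pixel problem."""

    @pytest.mark.parametrize(
        "loss",
        [
            lambda e, f: dice_loss(e, f, smooth=0.1),
            lambda e, f: focal_loss(e, f, LossConfig()),
            lambda e, f: combined_loss(e, f, LossConfig(smooth=0.1)),
        ],
        ids=["dice", "focal", "combined"],
    )
    def test_loss_gradient_matches_finite_differences(self, loss):
        e = np.array([1.0, 0.0])
        f0 = np.array([0.7, 0.3])
        f = Tensor(f0.copy(), requires_grad=True)
        out = loss(e, f)
        out.backward()
        for i in range(2):
            eps = 1e-7
            up = f0.copy()
            up[i] += eps
            down = f0.copy()
            down[i] -= eps
            fd = (loss(e, Tensor(up)).item() - loss(e, Tensor(down)).item()) / (2 * eps)
            assert abs(f.grad[i] - fd) <= 1e-4 * max(1.0, abs(fd))


def test_loss_registry_resolves_and_rejects():
    from ctlungseg.losses import get_loss

    assert get_loss("dice") is dice_loss
    assert get_loss("focal") is focal_loss
    assert get_loss("combined") is combined_loss
    with pytest.raises(ValueError, match="unknown loss"):
        get_loss("tversky")
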