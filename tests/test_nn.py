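"""Autodiff engine: gradients vs finite differences and independent oracles."""

import numpy as np
import pytest
from scipy import ndimage

from ctlungseg import nn
from ctlungseg.nn import Tensor


def numeric_grad(fn, tensor, indices, eps=1e-6):
    """Central finite differences of scalar fn w.r.t. tensor entries."""
    grads = {}
    for idx in indices:
        orig = tensor.data[idx]
        tensor.data[idx] = orig + eps
        up = fn().item()
        tensor.data[idx] = orig - eps
        down = fn().item()
        tensor.data[idx] = orig
        grads[idx] = (up - down) / (2 * eps)
    return grads


def assert_grads_match(fn, tensors, rng, samples=4, rtol=1e-4):
    out = fn()
    out.backward()
    autodiff = {id(t): t.grad.copy() for t in tensors}
    for t in tensors:
        idxs = [
            tuple(rng.integers(0, s) for s in t.data.shape) for _ in range(samples)
        ]
        fd = numeric_grad(fn, t, idxs)
        for idx, val in fd.items():
            got = autodiff[id(t)][idx]
            assert abs(got - val) <= rtol * max(1.0, abs(val), abs(got)), (
                f"grad mismatch at {idx}: autodiff {got} vs fd {val}"
            )


class TestGradients:
    def test_conv2d_matches_finite_differences(self, rng):
        x = Tensor(rng.random((2, 3, 6, 6)), requires_grad=True)
        w = Tensor(rng.random((4, 3, 3, 3)) - 0.5, requires_grad=True)
        b = Tensor(rng.random(4), requires_grad=True)
        assert_grads_match(
            lambda: (nn.conv2d(x, w, b, padding=1) ** 2).mean(), [x, w, b], rng
        )

    def test_conv2d_1x1_matches_finite_differences(self, rng):
        x = Tensor(rng.random((2, 5, 4, 4)), requires_grad=True)
        w = Tensor(rng.random((3, 5, 1, 1)) - 0.5, requires_grad=True)
        assert_grads_match(lambda: (nn.conv2d(x, w) ** 2).mean(), [x, w], rng)

    def test_maxpool_matches_finite_differences(self, rng):
        # well-separated values so no argmax tie flips under perturbation
        x = Tensor(rng.permutation(64).reshape(1, 1, 8, 8) * 1.0, requires_grad=True)
        assert_grads_match(lambda: (nn.maxpool2x(x) ** 2).mean(), [x], rng)

    def test_upsample_matches_finite_differences(self, rng):
        x = Tensor(rng.random((2, 2, 3, 3)), requires_grad=True)
        assert_grads_match(lambda: (nn.upsample_nearest2x(x) ** 2).mean(), [x], rng)

    @pytest.mark.parametrize("training", [True, False])
    def test_batchnorm_matches_finite_differences(self, rng, training):
        bn = nn.BatchNorm2d(3, dtype=np.float64)
        bn.gamma.data = rng.random((1, 3, 1, 1)) + 0.5
        bn.training = training
        x = Tensor(rng.random((4, 3, 5, 5)), requires_grad=True)
        bn.running_mean = rng.random((1, 3, 1, 1))
        bn.running_var = rng.random((1, 3, 1, 1)) + 0.5
        assert_grads_match(lambda: (bn(x) ** 2).mean(), [x, bn.gamma, bn.beta], rng)

    def test_elementwise_chain_matches_finite_differences(self, rng):
        x = Tensor(rng.normal(0.5, 1.0, (4, 4)), requires_grad=True)
        assert_grads_match(
            lambda: (x.sigmoid().clamp(1e-6, 1 - 1e-6).log() ** 2).mean()
            + (x.leaky_relu(0.1) ** 2).mean()
            + (x.exp() / (1.0 + x**2)).mean(),
            [x],
            rng,
        )

    def test_concat_routes_gradients_to_both_parents(self, rng):
        a = Tensor(rng.random((1, 2, 3, 3)), requires_grad=True)
        b = Tensor(rng.random((1, 3, 3, 3)), requires_grad=True)
        assert_grads_match(
            lambda: (nn.concat([a, b], axis=1) ** 2).mean(), [a, b], rng
        )

    def test_broadcast_add_mul_unbroadcast_correctly(self, rng):
        a = Tensor(rng.random((3, 4)), requires_grad=True)
        b = Tensor(rng.random((1, 4)), requires_grad=True)
        assert_grads_match(lambda: ((a * b + b) ** 2).mean(), [a, b], rng)


class TestOracles:
    def test_conv2d_matches_scipy_correlate(self, rng):
        """Independent oracle: per-channel scipy.ndimage.correlate sum."""
        x = rng.random((1, 3, 7, 7))
        w = rng.random((2, 3, 3, 3)) - 0.5
        out = nn.conv2d(Tensor(x), Tensor(w), padding=1).data[0]
        for f in range(2):
            expected = np.zeros((7, 7))
            for c in range(3):
                expected += ndimage.correlate(
                    x[0, c], w[f, c], mode="constant", cval=0.0
                )
            assert np.allclose(out[f], expected, atol=1e-10)

    def test_maxpool_matches_block_maximum(self, rng):
        x = rng.random((2, 3, 6, 8))
        out = nn.maxpool2x(Tensor(x)).data
        for n in (0, 1):
            for c in range(3):
                for i in range(3):
                    for j in range(4):
                        block = x[n, c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                        assert out[n, c, i, j] == block.max()

    def test_sigmoid_is_stable_at_extremes(self):
        x = Tensor(np.array([-500.0, 0.0, 500.0]))
        s = x.sigmoid().data
        assert np.all(np.isfinite(s))
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert s[1] == pytest.approx(0.5)
        assert s[2] == pytest.approx(1.0, abs=1e-12)


class TestModules:
    def test_rmsprop_matches_hand_computed_update(self):
        p = Tensor(np.array([1.0]), requires_grad=True)
        opt = nn.RMSprop([p], lr=0.1, rho=0.9, eps=1e-8)
        p.grad = np.array([2.0])
        opt.step()
        sq = 0.1 * 4.0
        expected = 1.0 - 0.1 * 2.0 / (np.sqrt(sq) + 1e-8)
        assert p.data[0] == pytest.approx(expected, rel=1e-12)

    def test_dropout_eval_is_identity_and_train_scales(self, rng):
        d = nn.Dropout(0.5, rng=np.random.default_rng(0))
        x = Tensor(np.ones((1, 1, 50, 50)))
        d.eval()
        assert np.array_equal(d(x).data, x.data)
        d.train()
        out = d(x).data
        assert set(np.unique(out)) == {0.0, 2.0}  # inverted dropout
        assert out.mean() == pytest.approx(1.0, abs=0.15)

    def test_state_dict_roundtrip_restores_everything(self, rng):
        bn = nn.BatchNorm2d(2)
        conv = nn.Conv2d(2, 3, rng=rng)

        class Net(nn.Module):
            def __init__(self):
                super().__init__()
                self.conv = conv
                self.bn = bn

        net = Net()
        state = {k: v.copy() for k, v in net.state_dict().items()}
        for p in net.parameters():
            p.data = p.data * 0.0
        net.bn.running_mean = net.bn.running_mean + 5.0
        net.load_state_dict(state)
        for k, v in net.state_dict().items():
            assert np.array_equal(v, state[k]), k

    def test_backward_requires_scalar_output(self, rng):
        x = Tensor(rng.random((3, 3)), requires_grad=True)
        with pytest.raises(ValueError, match="scalar"):
            (x * 2.0).backward()

    def test_float32_graph_stays_float32(self):
        x = Tensor(np.ones((2, 2), dtype=np.float32), requires_grad=True)
        out = ((1.0 - x.sigmoid()) ** 2.0 * 3.0 / 2.0).mean()
        assert out.data.dtype == np.float32
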