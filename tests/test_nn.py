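"""Layer-level checks: conv against a scipy oracle, numerical gradients,
pool/unpool index bookkeeping, softmax/cross-entropy identities."""

import numpy as np
import pytest
from scipy import ndimage

from bollseg import nn

RNG = np.random.default_rng(1234)


def scipy_conv_same(x: np.ndarray, weight: np.ndarray, dilation: int) -> np.ndarray:
    """Independent dense-correlation oracle: dilate the kernel with zeros."""
    cout, cin, k, _ = weight.shape
    kd = k + (k - 1) * (dilation - 1)
    wd = np.zeros((cout, cin, kd, kd))
    wd[:, :, ::dilation, ::dilation] = weight
    n, _, h, w = x.shape
    out = np.zeros((n, cout, h, w))
    for ni in range(n):
        for oi in range(cout):
            acc = np.zeros((h, w))
            for ci in range(cin):
                acc += ndimage.correlate(
                    x[ni, ci].astype(float), wd[oi, ci], mode="constant", cval=0.0
                )
            out[ni, oi] = acc
    return out


class TestConv2d:
    @pytest.mark.parametrize("dilation", [1, 2, 3])
    def test_forward_matches_scipy_oracle(self, dilation):
        conv = nn.Conv2d(2, 3, kernel=3, dilation=dilation, rng=np.random.default_rng(0))
        x = RNG.standard_normal((2, 2, 12, 12)).astype(np.float32)
        got = conv.forward(x)
        want = scipy_conv_same(x, conv.weight.value.astype(float), dilation)
        want += conv.bias.value[None, :, None, None]
        assert got.shape == (2, 3, 12, 12)
        np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)

    def test_gradients_match_finite_differences(self):
        conv = nn.Conv2d(2, 2, dilation=2, rng=np.random.default_rng(3))
        x = RNG.standard_normal((1, 2, 6, 6)).astype(np.float32)
        dout = RNG.standard_normal((1, 2, 6, 6)).astype(np.float32)

        conv.forward(x)
        dx = conv.backward(dout)

        def loss(xv):
            return float((conv.forward(xv) * dout).sum())

        eps = 1e-3
        for idx in [(0, 0, 2, 3), (0, 1, 5, 0), (0, 0, 0, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (loss(xp) - loss(xm)) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=1e-2, abs=1e-3)

        # weight gradient at a few taps
        conv.weight.grad[...] = 0.0
        conv.forward(x)
        conv.backward(dout)
        for widx in [(0, 0, 0, 0), (1, 1, 2, 2)]:
            w0 = conv.weight.value[widx]
            for sign, store in ((+1, "p"), (-1, "m")):
                conv.weight.value[widx] = w0 + sign * eps
                val = float((conv.forward(x) * dout).sum())
                if store == "p":
                    lp = val
                else:
                    lm = val
            conv.weight.value[widx] = w0
            num = (lp - lm) / (2 * eps)
            assert conv.weight.grad[widx] == pytest.approx(num, rel=1e-2, abs=1e-3)


class TestBatchNorm:
    def test_normalizes_batch_statistics(self):
        bn = nn.BatchNorm2d(4)
        x = RNG.standard_normal((8, 4, 5, 5)).astype(np.float32) * 3 + 2
        y = bn.forward(x, train=True)
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0, atol=1e-5)
        assert np.allclose(y.std(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_gradient_matches_finite_differences(self):
        bn = nn.BatchNorm2d(2)
        x = RNG.standard_normal((3, 2, 4, 4)).astype(np.float32)
        dout = RNG.standard_normal((3, 2, 4, 4)).astype(np.float32)
        bn.forward(x, train=True)
        dx = bn.backward(dout)
        eps = 1e-3
        for idx in [(0, 0, 1, 1), (2, 1, 3, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (
                float((bn.forward(xp, train=True) * dout).sum())
                - float((bn.forward(xm, train=True) * dout).sum())
            ) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=2e-2, abs=2e-3)


class TestPoolUnpool:
    def test_hand_built_4x4_roundtrip(self):
        # maxima live at known positions; unpool must place them back exactly
        x = np.array(
            [[1, 2, 0, 0], [3, 4, 0, 5], [0, 0, 9, 0], [0, 7, 0, 0]], dtype=np.float32
        )[None, None]
        pool = nn.MaxPool2d()
        y, idx = pool.forward(x)
        np.testing.assert_array_equal(y[0, 0], [[4, 5], [7, 9]])
        restored = nn.unpool(y, idx, x.shape)
        want = np.zeros((4, 4), dtype=np.float32)
        want[1, 1], want[1, 3], want[3, 1], want[2, 2] = 4, 5, 7, 9
        np.testing.assert_array_equal(restored[0, 0], want)

    def test_unpool_restores_maxima_for_random_tensors(self):
        x = RNG.standard_normal((2, 3, 8, 8)).astype(np.float32)
        pool = nn.MaxPool2d()
        y, idx = pool.forward(x)
        restored = nn.unpool(y, idx, x.shape)
        # restored is x at the argmax positions and 0 elsewhere
        nz = restored != 0
        np.testing.assert_array_equal(restored[nz], x[nz])
        assert int(nz.sum()) == y.size

    def test_pool_backward_routes_to_argmax(self):
        x = np.array([[1, 2], [3, 4]], dtype=np.float32)[None, None]
        pool = nn.MaxPool2d()
        pool.forward(x)
        dx = pool.backward(np.array([[[[10.0]]]], dtype=np.float32))
        np.testing.assert_array_equal(dx[0, 0], [[0, 0], [0, 10]])


class TestLoss:
    def test_softmax_sums_to_one(self):
        logits = RNG.standard_normal((2, 3, 4, 4)).astype(np.float32) * 5
        p = nn.softmax(logits, axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_cross_entropy_of_perfect_prediction_is_small(self):
        logits = np.zeros((1, 2, 2, 2), dtype=np.float32)
        logits[0, 1] = 50.0
        labels = np.ones((1, 2, 2), dtype=np.int64)
        loss, _ = nn.cross_entropy(logits, labels)
        assert loss < 1e-6

    def test_cross_entropy_gradient_matches_finite_differences(self):
        logits = RNG.standard_normal((1, 2, 3, 3)).astype(np.float64)
        labels = RNG.integers(0, 2, size=(1, 3, 3))
        _, grad = nn.cross_entropy(logits.astype(np.float32), labels)
        eps = 1e-4
        for idx in [(0, 0, 1, 1), (0, 1, 2, 0)]:
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            num = (
                nn.cross_entropy(lp.astype(np.float32), labels)[0]
                - nn.cross_entropy(lm.astype(np.float32), labels)[0]
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-2, abs=1e-4)


class TestAdam:
    def test_moves_against_gradient(self):
        p = nn.Param(np.array([1.0]))
        opt = nn.Adam([p], lr=0.1)
        p.grad[...] = 1.0
        opt.step()
        assert p.value[0] < 1.0

    def test_zero_lr_is_a_no_op(self):
        p = nn.Param(np.array([1.0, -2.0]))
        opt = nn.Adam([p], lr=0.0)
        p.grad[...] = 3.0
        opt.step()
        np.testing.assert_array_equal(p.value, [1.0, -2.0])
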