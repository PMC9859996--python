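"""Finite-difference and oracle checks for the numpy autodiff backend.

Every backward rule used by the segmentation network is compared against
central finite differences; the convolution forward pass is additionally
checked against scipy's correlate2d.
"""

import numpy as np
import pytest
from scipy.signal import correlate2d

from busgate.nn import Adam, BatchNorm2d, Conv2d, ConvBlock, Linear, Tensor
from busgate.nn import autograd as ag

RNG = np.random.default_rng(20240901)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of scalar-valued f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_grad(build, x_data, atol=2e-2, rtol=2e-2):
    """Compare autodiff gradient of build(x)->scalar Tensor against FD."""
    x = Tensor(x_data.astype(np.float32), requires_grad=True)
    out = build(x)
    out.backward()
    num = numeric_grad(lambda: float(build(Tensor(x.data)).data), x.data)
    np.testing.assert_allclose(x.grad, num, atol=atol, rtol=rtol)


@pytest.mark.parametrize("op", [
    lambda x: ag.tsum(ag.relu(x)),
    lambda x: ag.tsum(ag.sigmoid(x)),
    lambda x: ag.tsum(ag.log(ag.clip(ag.sigmoid(x), 1e-6, 1 - 1e-6))),
    lambda x: ag.tmean(x * x + 2.0 * x - 1.0),
    lambda x: ag.tsum((x + 1.0) / (x * x + 2.0)),
    lambda x: ag.tsum(ag.reshape(x, (-1,)) * 0.5),
])
def test_elementwise_gradients_match_finite_differences(op):
    x = RNG.normal(0, 1, (3, 5)).astype(np.float32)
    check_grad(op, x)


def test_matmul_gradients():
    b = Tensor(RNG.normal(0, 1, (4, 2)).astype(np.float32), requires_grad=True)

    def build(x):
        return ag.tsum(ag.matmul(x, b) * ag.matmul(x, b))
    x = RNG.normal(0, 1, (3, 4)).astype(np.float32)
    check_grad(build, x)


@pytest.mark.parametrize("k", [1, 3])
def test_conv2d_matches_scipy_and_finite_differences(k):
    n, h, w, cin, cout = 2, 5, 6, 3, 2
    wdat = RNG.normal(0, 0.5, (k, k, cin, cout)).astype(np.float32)
    bdat = RNG.normal(0, 0.5, cout).astype(np.float32)
    xdat = RNG.normal(0, 1, (n, h, w, cin)).astype(np.float32)

    out = ag.conv2d(Tensor(xdat), Tensor(wdat), Tensor(bdat))
    # oracle: per-sample, per-channel scipy cross-correlation with zero padding
    expect = np.zeros((n, h, w, cout))
    for i in range(n):
        for co in range(cout):
            acc = np.zeros((h, w))
            for ci in range(cin):
                acc += correlate2d(xdat[i, :, :, ci], wdat[:, :, ci, co],
                                   mode="same")
            expect[i, :, :, co] = acc + bdat[co]
    np.testing.assert_allclose(out.data, expect, atol=1e-4)

    wt = Tensor(wdat, requires_grad=True)
    bt = Tensor(bdat, requires_grad=True)

    def build(x):
        return ag.tsum(ag.sigmoid(ag.conv2d(x, wt, bt)))
    check_grad(build, xdat.copy())
    # weight gradient
    x_fixed = Tensor(xdat)
    out = ag.tsum(ag.sigmoid(ag.conv2d(x_fixed, wt, bt)))
    wt.grad = None
    out.backward()
    num = numeric_grad(lambda: float(ag.tsum(ag.sigmoid(
        ag.conv2d(x_fixed, Tensor(wt.data), Tensor(bt.data)))).data), wt.data)
    np.testing.assert_allclose(wt.grad, num, atol=2e-2, rtol=2e-2)


def test_batchnorm_training_gradient():
    bn = BatchNorm2d(3)

    def build(x):
        return ag.tsum(ag.sigmoid(bn(x)))
    x = RNG.normal(1.0, 2.0, (4, 3, 3, 3)).astype(np.float32)
    check_grad(build, x)


def test_batchnorm_running_stats_drive_eval_mode():
    bn = BatchNorm2d(2, momentum=1.0)
    x = Tensor(RNG.normal(3.0, 2.0, (8, 4, 4, 2)).astype(np.float32))
    bn(x)  # momentum 1 -> running stats equal batch stats
    bn.eval()
    y = bn(x)
    assert abs(float(y.data.mean())) < 1e-3
    assert abs(float(y.data.std()) - 1.0) < 1e-2


def test_maxpool_gradient_routes_to_argmax():
    def build(x):
        return ag.tsum(ag.maxpool2x2(x) * ag.maxpool2x2(x))
    x = RNG.normal(0, 1, (2, 4, 4, 2)).astype(np.float32)
    check_grad(build, x)


@pytest.mark.parametrize("mode", ["nearest", "bilinear"])
def test_upsample_gradient(mode):
    def build(x):
        return ag.tsum(ag.sigmoid(ag.upsample2x(x, mode)))
    x = RNG.normal(0, 1, (2, 3, 4, 2)).astype(np.float32)
    check_grad(build, x)


def test_upsample_doubles_spatial_dims_and_preserves_constants():
    x = Tensor(np.full((1, 3, 5, 2), 7.0, dtype=np.float32))
    for mode in ("nearest", "bilinear"):
        y = ag.upsample2x(x, mode)
        assert y.shape == (1, 6, 10, 2)
        np.testing.assert_allclose(y.data, 7.0, atol=1e-5)


def test_concat_splits_gradient():
    a = Tensor(RNG.normal(0, 1, (2, 3)).astype(np.float32), requires_grad=True)
    b = Tensor(RNG.normal(0, 1, (2, 2)).astype(np.float32), requires_grad=True)
    out = ag.tsum(ag.concat([a, b], axis=1) * ag.concat([a, b], axis=1))
    out.backward()
    np.testing.assert_allclose(a.grad, 2 * a.data, atol=1e-5)
    np.testing.assert_allclose(b.grad, 2 * b.data, atol=1e-5)


def test_bce_with_logits_value_and_gradient():
    z = Tensor(np.array([0.0, 2.0, -1.5], dtype=np.float32),
               requires_grad=True)
    t = np.array([1.0, 0.0, 1.0], dtype=np.float32)
    loss = ag.bce_with_logits(z, t)
    s = 1 / (1 + np.exp(-z.data))
    expect = -(t * np.log(s) + (1 - t) * np.log(1 - s)).mean()
    assert abs(loss.item() - expect) < 1e-6
    loss.backward()
    np.testing.assert_allclose(z.grad, (s - t) / 3, atol=1e-6)


def test_convblock_emits_growth_rate_channels():
    rng = np.random.default_rng(0)
    blk = ConvBlock(10, 4, rng)
    y = blk(Tensor(RNG.normal(0, 1, (2, 8, 8, 10)).astype(np.float32)))
    assert y.shape == (2, 8, 8, 4)


def test_conv_rejects_nonpositive_channels():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        Conv2d(0, 4, 3, rng)
    with pytest.raises(ValueError):
        ConvBlock(4, 0, rng)


def test_adam_descends_quadratic():
    p = Tensor(np.array([5.0, -3.0], dtype=np.float32), requires_grad=True)
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        opt.zero_grad()
        loss = ag.tsum(p * p)
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 0.05


def test_linear_and_state_roundtrip():
    rng = np.random.default_rng(1)
    lin = Linear(3, 2, rng)
    x = Tensor(RNG.normal(0, 1, (4, 3)).astype(np.float32))
    y0 = lin(x).data.copy()
    state = {k: v.copy() for k, v in lin.named_state().items()}
    lin.weight.data += 1.0
    lin.load_state(state)
    np.testing.assert_array_equal(lin(x).data, y0)
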