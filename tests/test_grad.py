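"""Finite-difference validation of the autodiff engine.

Every operation used by the networks is checked against central-difference
numerical gradients on small random tensors.
"""

import numpy as np
import pytest

from palocal.grad import (Adam, BatchNorm, Conv, ConvTranspose2x, Module,
                          SpatialDropout, Tensor, avg_pool_nd, concatenate,
                          conv_nd, max_pool_nd, pixel_shuffle_2d)

RNG = np.random.default_rng(0)


def numerical_grad(make_scalar, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = make_scalar()
        x[i] -= 2 * eps
        fm = make_scalar()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(make_out, tensors, tol=1e-5):
    for t in tensors:
        t.grad = None
    make_out().backward()
    for t in tensors:
        analytic = t.grad.copy()
        numeric = numerical_grad(lambda: make_out().item(), t.data)
        assert np.abs(analytic - numeric).max() < tol


@pytest.fixture
def conv2d_tensors():
    x = Tensor(RNG.normal(size=(2, 3, 6, 7)), requires_grad=True)
    w = Tensor(RNG.normal(size=(4, 3, 3, 3)), requires_grad=True)
    b = Tensor(RNG.normal(size=4), requires_grad=True)
    return x, w, b


def test_conv2d_stride1_same(conv2d_tensors):
    x, w, b = conv2d_tensors
    assert_grads_match(lambda: (conv_nd(x, w, b, stride=1, pad="same") ** 2).sum(),
                       [x, w, b])


def test_conv2d_stride2(conv2d_tensors):
    x, w, b = conv2d_tensors
    assert_grads_match(lambda: (conv_nd(x, w, b, stride=2, pad=1) ** 2).sum(),
                       [x, w, b])


def test_conv3d_strides():
    x = Tensor(RNG.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
    w = Tensor(RNG.normal(size=(3, 2, 3, 3, 3)), requires_grad=True)
    assert_grads_match(lambda: (conv_nd(x, w, None, stride=2, pad=1) ** 2).sum(),
                       [x, w])
    assert_grads_match(lambda: (conv_nd(x, w, None, stride=1, pad="same") ** 2).sum(),
                       [x, w])


def test_conv2d_forward_matches_scipy():
    from scipy.signal import correlate

    x = RNG.normal(size=(1, 1, 8, 9))
    w = RNG.normal(size=(1, 1, 3, 3))
    out = conv_nd(Tensor(x), Tensor(w), None, stride=1, pad="same").data
    ref = correlate(x[0, 0], w[0, 0], mode="same")
    assert np.allclose(out[0, 0], ref, atol=1e-12)


def test_max_pool_gradients():
    x = Tensor(RNG.normal(size=(2, 2, 6, 6)), requires_grad=True)
    assert_grads_match(lambda: (max_pool_nd(x, 2) ** 2).sum(), [x])
    assert_grads_match(lambda: (max_pool_nd(x, 3, stride=1, same=True) ** 2).sum(),
                       [x])
    x3 = Tensor(RNG.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
    assert_grads_match(lambda: (max_pool_nd(x3, 2) ** 2).sum(), [x3])


def test_avg_pool_gradients_and_truncation():
    x = Tensor(RNG.normal(size=(2, 2, 6, 6)), requires_grad=True)
    assert_grads_match(lambda: (avg_pool_nd(x, 2) ** 2).sum(), [x])
    odd = Tensor(RNG.normal(size=(2, 2, 5, 7)), requires_grad=True)
    out = avg_pool_nd(odd, 2)
    assert out.shape == (2, 2, 2, 3)  # trailing remainder cropped
    assert_grads_match(lambda: (avg_pool_nd(odd, 2) ** 2).sum(), [odd])


def test_pixel_shuffle_gradient_and_index_formula():
    x = Tensor(RNG.normal(size=(1, 8, 3, 4)), requires_grad=True)
    assert_grads_match(lambda: (pixel_shuffle_2d(x, 2) ** 2).sum(), [x])
    arr = RNG.normal(size=(1, 4, 3, 3))
    out = pixel_shuffle_2d(Tensor(arr), 2).data
    for i in range(3):
        for j in range(3):
            for di in range(2):
                for dj in range(2):
                    assert out[0, 0, 2 * i + di, 2 * j + dj] == arr[0, 2 * di + dj, i, j]


def test_dilate_pad_gradient():
    x = Tensor(RNG.normal(size=(1, 2, 3, 3)), requires_grad=True)
    assert_grads_match(
        lambda: ((x.dilate((2, 2)).pad([(0, 0), (0, 0), (0, 1), (0, 1)])) ** 2).sum(),
        [x])


def test_concatenate_gradient():
    a = Tensor(RNG.normal(size=(2, 3)), requires_grad=True)
    b = Tensor(RNG.normal(size=(2, 2)), requires_grad=True)
    assert_grads_match(lambda: (concatenate([a, b], axis=1) ** 2).sum(), [a, b])


def test_elementwise_gradients():
    a = Tensor(RNG.normal(size=(2, 3)), requires_grad=True)
    assert_grads_match(lambda: -(a.sigmoid().clip(1e-7, 1 - 1e-7).log()).mean(), [a])
    assert_grads_match(lambda: (a.leaky_relu(0.2).abs()).sum(), [a])
    assert_grads_match(lambda: ((a * 2.0 + 1.0) / 3.0 - 0.5).sum(), [a])
    pos = Tensor(np.abs(RNG.normal(size=(2, 3))) + 0.5, requires_grad=True)
    assert_grads_match(lambda: (pos.sqrt() + pos ** 1.5).sum(), [pos])


def test_conv_transpose_doubles_spatial_size():
    rng = np.random.default_rng(3)
    for dim, shape in [(2, (1, 2, 5, 6)), (3, (1, 2, 3, 4, 5))]:
        op = ConvTranspose2x(2, 3, 3, dim=dim, rng=rng)
        out = op(Tensor(RNG.normal(size=shape)))
        assert out.shape == (1, 3) + tuple(2 * n for n in shape[2:])


def test_batchnorm_normalizes_and_tracks_running_stats():
    bn = BatchNorm(3)
    x = Tensor(RNG.normal(loc=2.0, scale=3.0, size=(8, 3, 5, 5)))
    out = bn(x)
    mu = out.data.mean(axis=(0, 2, 3))
    sd = out.data.std(axis=(0, 2, 3))
    assert np.allclose(mu, 0.0, atol=1e-7)
    assert np.allclose(sd, 1.0, atol=1e-3)
    assert not np.allclose(bn.running_mean, 0.0)
    bn.eval()
    out_eval = bn(x)  # uses running stats, not batch stats
    assert not np.allclose(out_eval.data, out.data)


def test_spatial_dropout_drops_whole_channels():
    drop = SpatialDropout(0.5, rng=np.random.default_rng(0))
    x = Tensor(np.ones((4, 8, 6, 6)))
    out = drop(x).data
    per_channel = out.reshape(4, 8, -1)
    kept = dropped = 0
    for b in range(4):
        for c in range(8):
            vals = np.unique(per_channel[b, c])
            assert len(vals) == 1 and vals[0] in (0.0, 2.0)  # dropped or rescaled
            kept += vals[0] == 2.0
            dropped += vals[0] == 0.0
    assert kept > 0 and dropped > 0
    assert out.mean() == pytest.approx(2.0 * kept / 32)  # inverted scaling
    drop.eval()
    assert np.array_equal(drop(x).data, x.data)


def test_adam_minimizes_quadratic():
    w = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([w], lr=0.1)
    for _ in range(200):
        loss = (w ** 2).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(w.data).max() < 1e-2


def test_adam_weight_decay_shrinks_weights():
    w1 = Tensor(np.array([1.0]), requires_grad=True)
    w2 = Tensor(np.array([1.0]), requires_grad=True)
    for w, wd in ((w1, 0.0), (w2, 0.5)):
        opt = Adam([w], lr=0.01, weight_decay=wd)
        for _ in range(50):
            loss = ((w - 1.0) ** 2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
    assert w2.data[0] < w1.data[0]  # L2 regularization pulls toward zero


def test_module_state_roundtrip():
    rng = np.random.default_rng(7)
    conv = Conv(2, 3, 3, dim=2, rng=rng)
    state = [a.copy() for a in conv.state_arrays()]
    conv.weight.data += 1.0
    conv.load_state_arrays(state)
    assert np.array_equal(conv.weight.data, state[0])
    with pytest.raises(ValueError, match="expected"):
        conv.load_state_arrays(state[:1])


def test_backward_requires_scalar():
    t = Tensor(np.ones((2, 2)), requires_grad=True)
    with pytest.raises(ValueError, match="scalar"):
        (t * 2).backward()
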