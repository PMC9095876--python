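"""Differentiable convolution, pooling and channel-to-space operators.

Dimension-agnostic (2D and 3D) implementations built on
``numpy.lib.stride_tricks.sliding_window_view`` with hand-written backward
passes. Gradients are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv_nd", "max_pool_nd", "avg_pool_nd", "pixel_shuffle_2d"]


def _tuplize(v, d: int) -> tuple[int, ...]:
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * d


def _conv_forward(x: np.ndarray, w: np.ndarray, stride, pad):
    """Cross-correlate x (B,Ci,*S) with w (Co,Ci,*K); returns out and windows."""
    d = x.ndim - 2
    xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pad])
    win = sliding_window_view(xp, w.shape[2:], axis=tuple(range(2, 2 + d)))
    win = win[(slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)]
    # win: (B, Ci, *O, *K); contract Ci and kernel axes against w
    out = np.tensordot(
        win, w,
        axes=([1] + list(range(2 + d, 2 + 2 * d)), [1] + list(range(2, 2 + d))),
    )  # (B, *O, Co)
    return np.moveaxis(out, -1, 1), win


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None,
            stride=1, pad=0) -> Tensor:
    """n-D cross-correlation of `x` (B, C_in, *spatial) with kernel `w`.

    `pad` may be an int, a per-axis tuple, or "same" (stride-1 shape
    preservation for odd kernels).
    """
    d = x.ndim - 2
    stride = _tuplize(stride, d)
    if pad == "same":
        pad = tuple((k - 1) // 2 for k in w.shape[2:])
    else:
        pad = _tuplize(pad, d)
    out_data, win = _conv_forward(x.data, w.data, stride, pad)
    parents = (x, w) if b is None else (x, w, b)
    if b is not None:
        out_data = out_data + b.data.reshape((1, -1) + (1,) * d)
    out = Tensor(out_data, _parents=parents)
    K = w.shape[2:]

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + d))))
        if w.requires_grad:
            # (B,Co,*O) x (B,Ci,*O,*K) -> (Co,Ci,*K)
            dw = np.tensordot(
                g, win,
                axes=([0] + list(range(2, 2 + d)), [0] + list(range(2, 2 + d))),
            )
            w._accum(dw)
        if x.requires_grad:
            x._accum(_conv_input_grad(g, w.data, x.shape, stride, pad))

    out._backward = bw
    return out


def _conv_input_grad(g, w, x_shape, stride, pad):
    """Gradient of conv_nd w.r.t. its input: transposed convolution of g."""
    d = g.ndim - 2
    K = w.shape[2:]
    # zero-stuff g by the forward stride
    stuffed_shape = list(g.shape[:2]) + [(g.shape[2 + i] - 1) * stride[i] + 1 for i in range(d)]
    gs = np.zeros(stuffed_shape, dtype=g.dtype)
    gs[(slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)] = g
    pads = []
    for i in range(d):
        a = (x_shape[2 + i] + 2 * pad[i] - K[i]) % stride[i]  # forward remainder
        pads.append((K[i] - 1 - pad[i], K[i] - 1 - pad[i] + a))
    wt = np.flip(w, axis=tuple(range(2, 2 + d))).swapaxes(0, 1).copy()
    dx, _ = _conv_forward(gs, wt, (1,) * d, (0,) * d) if all(
        p == (0, 0) for p in pads
    ) else _conv_forward(np.pad(gs, [(0, 0), (0, 0)] + pads), wt, (1,) * d, (0,) * d)
    return dx


def max_pool_nd(x: Tensor, kernel, stride=None, same: bool = False) -> Tensor:
    """n-D max pooling.

    With ``same=True`` the input is padded with -inf so the output keeps the
    input's spatial shape (used by the stride-1 short skip connections);
    otherwise no padding is applied.
    """
    d = x.ndim - 2
    kernel = _tuplize(kernel, d)
    stride = kernel if stride is None else _tuplize(stride, d)
    if same:
        if any(s != 1 for s in stride):
            raise ValueError("same-size max pooling requires stride 1")
        pad = tuple((k - 1) // 2 for k in kernel)
    else:
        pad = (0,) * d
    xp = np.pad(x.data, [(0, 0), (0, 0)] + [(p, p) for p in pad],
                constant_values=-np.inf)
    win = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + d)))
    win = win[(slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)]
    out_sp = win.shape[2:2 + d]
    flat = win.reshape(win.shape[:2 + d] + (-1,))
    arg = flat.argmax(axis=-1)
    out = Tensor(flat.max(axis=-1), _parents=(x,))

    padded_sp = xp.shape[2:]

    def bw(g):
        if not x.requires_grad:
            return
        offs = np.unravel_index(arg, kernel)  # offsets within window
        grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(out_sp, stride)],
                            indexing="ij")
        full = np.zeros_like(xp)
        B, C = x.shape[:2]
        bidx = np.arange(B).reshape((B, 1) + (1,) * d)
        cidx = np.arange(C).reshape((1, C) + (1,) * d)
        spatial_idx = tuple(grids[i][None, None] + offs[i] for i in range(d))
        np.add.at(full, (bidx, cidx) + spatial_idx, g)
        sl = tuple(slice(p, p + n) for p, n in zip(pad, x.shape[2:]))
        x._accum(full[(slice(None), slice(None)) + sl])

    out._backward = bw
    return out


def avg_pool_nd(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping n-D average pooling by `factor` (trailing remainder cropped)."""
    d = x.ndim - 2
    sp = x.shape[2:]
    crop = tuple(slice(0, (n // factor) * factor) for n in sp)
    xc = x[(slice(None), slice(None)) + crop] if any(
        n % factor for n in sp
    ) else x
    new_sp = tuple(n // factor for n in xc.shape[2:])
    shape = xc.shape[:2] + tuple(v for n in new_sp for v in (n, factor))
    xr = xc.reshape(shape)
    axes = tuple(3 + 2 * i for i in range(d))
    return xr.mean(axis=axes)


def pixel_shuffle_2d(x: Tensor, factor: int = 2) -> Tensor:
    """Rearrange (B, C*r^2, H, W) to (B, C, H*r, W*r); a pure permutation.

    Index contract: out[c, r*i + di, r*j + dj] = in[c*r^2 + r*di + dj, i, j].
    """
    B, C2, H, W = x.shape
    r = factor
    if C2 % (r * r):
        raise ValueError(f"channel count {C2} not divisible by factor^2 = {r * r}")
    C = C2 // (r * r)
    xr = x.reshape(B, C, r, r, H, W)
    xt = xr.transpose((0, 1, 4, 2, 5, 3))  # (B, C, H, r, W, r)
    return xt.reshape(B, C, H * r, W * r)
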