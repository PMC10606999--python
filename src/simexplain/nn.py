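"""Minimal numpy neural-network kernels with hand-written backprop.

Only the operations the small Siamese backbone needs: 3x3 same-padded
convolution, ReLU, 2x2 max pooling, global average pooling, dense layers and
an Adam optimizer. Arrays are NHWC float64; gradients are exact (verified
against finite differences in the test suite), which is what makes the
Grad-CAM activation gradients trustworthy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 convolution, stride 1, zero padding 1.

    x: (N,H,W,Cin); W: (3,3,Cin,Cout); b: (Cout,). Returns (out, cache).
    """
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,Cin,3,3)
    out = np.einsum("nhwcij,ijco->nhwo", win, W, optimize=True) + b
    return out, (x.shape, win, W)


def conv2d_backward(dout: np.ndarray, cache):
    x_shape, win, W = cache
    dW = np.einsum("nhwcij,nhwo->ijco", win, dout, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    dp = np.pad(dout, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dwin = sliding_window_view(dp, (3, 3), axis=(1, 2))  # (N,H,W,Cout,3,3)
    Wflip = W[::-1, ::-1]  # (3,3,Cin,Cout) spatially flipped
    dx = np.einsum("nhwoij,ijco->nhwc", dwin, Wflip, optimize=True)
    return dx, dW, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling, stride 2. Requires even H and W."""
    n, h, w, c = x.shape
    xr = (
        x.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // 2, w // 2, c, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, x_shape = cache
    n, h, w, c = x_shape
    dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(n, h // 2, w // 2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, w, c)
    )


def gap_forward(x: np.ndarray):
    """Global average pooling over the spatial dimensions: (N,H,W,C) -> (N,C)."""
    return x.mean(axis=(1, 2)), x.shape


def gap_backward(dout: np.ndarray, x_shape) -> np.ndarray:
    n, h, w, c = x_shape
    return np.broadcast_to(dout[:, None, None, :] / (h * w), x_shape).copy()


def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def dense_backward(dout: np.ndarray, cache, W: np.ndarray):
    x = cache
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a flat dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
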