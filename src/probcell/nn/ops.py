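"""Low-level volumetric network operations with explicit backward passes.

All activations are ``(channels, depth, height, width)`` float32 arrays.
Convolutions use 3x3x3 kernels with zero padding of 1 ("same" shape) and are
implemented as im2col + BLAS matmul; the input gradient of a same-padding
correlation is again a same-padding correlation with the spatially flipped,
channel-transposed kernel, so no scatter-add is needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def he_init(rng: np.random.Generator, c_out: int, c_in: int, k: int = 3) -> np.ndarray:
    fan_in = c_in * k ** 3
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k)).astype(
        np.float32
    )


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (C*27, D*H*W) patch matrix for a same-padded 3^3 window.

    Assembled offset-by-offset with contiguous row copies; the kernel index
    runs row-major over the 3x3x3 offsets, matching ``W.reshape(c_out, -1)``.
    """
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    col = np.empty((c, 27, d * h * w), dtype=x.dtype)
    k = 0
    for a in range(3):
        for bb in range(3):
            for cc in range(3):
                col[:, k, :] = xp[:, a:a + d, bb:bb + h, cc:cc + w].reshape(c, -1)
                k += 1
    return col.reshape(c * 27, d * h * w)


def conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padding 3D correlation. Returns (y, cache)."""
    c_out, c_in = W.shape[:2]
    _, d, h, w = x.shape
    col = _im2col(x)
    y = W.reshape(c_out, c_in * 27) @ col + b[:, None]
    return y.reshape(c_out, d, h, w), (col, x.shape, W)


def conv3d_backward(dy: np.ndarray, cache):
    col, x_shape, W = cache
    c_out, c_in = W.shape[:2]
    dy_mat = dy.reshape(c_out, -1)
    dW = (dy_mat @ col.T).reshape(W.shape)
    db = dy_mat.sum(axis=1)
    # input gradient = same-padding correlation with flipped/transposed kernel
    W_flip = np.ascontiguousarray(W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    dx, _ = conv3d_forward(dy, W_flip, np.zeros(c_in, dtype=W.dtype))
    return dx, dW, db


def proj1x1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """1x1x1 channel projection used on residual shortcuts. W is (C_out, C_in)."""
    y = np.tensordot(W, x, axes=(1, 0)) + b[:, None, None, None]
    return y.astype(x.dtype), (x, W)


def proj1x1_backward(dy: np.ndarray, cache):
    x, W = cache
    dW = np.tensordot(dy, x, axes=((1, 2, 3), (1, 2, 3)))
    db = dy.sum(axis=(1, 2, 3))
    dx = np.tensordot(W.T, dy, axes=(1, 0))
    return dx.astype(dy.dtype), dW, db


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0.0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def maxpool2_forward(x: np.ndarray):
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError("spatial dims must be even for 2x2x2 max pooling")
    xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    xr = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
        c, d // 2, h // 2, w // 2, 8
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, x_shape = cache
    c, d, h, w = x_shape
    g = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
    np.put_along_axis(g, idx[..., None], dy[..., None], axis=-1)
    g = g.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
    return np.ascontiguousarray(g).reshape(c, d, h, w)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


def spatial_dropout_mask(
    rng: np.random.Generator, channels: int, rate: float
) -> np.ndarray:
    """Per-channel (spatial) inverted-dropout mask, shape (C, 1, 1, 1)."""
    keep = rng.random(channels) >= rate
    scale = 1.0 / (1.0 - rate) if rate > 0 else 1.0
    return (keep[:, None, None, None] * scale).astype(np.float32)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                params[k].dtype
            )
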