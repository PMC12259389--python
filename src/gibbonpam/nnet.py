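"""Minimal CNN framework on numpy: layers, losses, Adam, one-cycle schedule.

This is a small, fully deterministic engine sized for spectrogram-image
classification on a CPU: im2col convolutions, ReLU, 2x2 max pooling, global
average pooling, linear layers, and residual blocks. Parameters carry a
``trainable`` flag so a backbone can be frozen while its classification head
trains. Everything is float32 and seeded through explicitly passed
generators; two runs with the same seeds produce identical histories.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "GlobalAvgPool",
    "Linear",
    "ResidualBlock",
    "Sequential",
    "Adam",
    "OneCycleLR",
    "bce_with_logits_loss",
    "softmax_cross_entropy_loss",
    "sigmoid",
    "softmax",
]


class Param:
    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int):
    # x: (N, C, H, W) already padded -> (N, OH, OW, C*k*k)
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (N, C, OH, OW, k, k)
    n, c, oh, ow = view.shape[:4]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * k * k)
    return cols, oh, ow


class Conv2d(Layer):
    """2-D convolution via im2col; He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1, pad: int = 0, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols, oh, ow = _im2col(x, self.k, self.stride)
        out = cols @ self.weight.value.T + self.bias.value
        self._cache = (cols, x.shape, oh, ow)
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, oh, ow = self._cache
        n = dout.shape[0]
        d = dout.transpose(0, 2, 3, 1)  # (N, OH, OW, c_out)
        flat_d = d.reshape(-1, self.c_out)
        flat_cols = cols.reshape(-1, cols.shape[-1])
        self.weight.grad += (flat_d.T @ flat_cols).astype(np.float32)
        self.bias.grad += flat_d.sum(axis=0).astype(np.float32)
        dcols = (flat_d @ self.weight.value).reshape(n, oh, ow, self.c_in, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, OH, OW, k, k)
        dx = np.zeros(x_shape, dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, :, :, i, j]
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad or None, self.pad : -self.pad or None]
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "MaxPool2d requires even spatial dims"
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None].astype(np.float32), axis=-1)
        return dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Flatten(Layer):
    """(N, C, H, W) -> (N, C*H*W)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape).astype(np.float32)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) by spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)).astype(np.float32) / (h * w)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in))
        self.bias = Param(np.zeros(d_out))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        self.weight.grad += (dout.T @ self._x).astype(np.float32)
        self.bias.grad += dout.sum(axis=0).astype(np.float32)
        return (dout @ self.weight.value).astype(np.float32)


class ResidualBlock(Layer):
    """conv3x3 -> ReLU -> conv3x3 plus a (possibly projected) skip, then ReLU."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(c_in, c_out, 3, 1, 1, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng=rng)
        self.proj = Conv2d(c_in, c_out, 1, 1, 0, rng=rng) if c_in != c_out else None
        self.relu_out = ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=False):
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        skip = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu_out.forward(main + skip, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        d_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        d_skip = self.proj.backward(d) if self.proj is not None else d
        return d_main + d_skip


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam with per-step settable learning rate; frozen params are skipped."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class OneCycleLR:
    """One-cycle policy: cosine ramp up to max_lr, cosine anneal down.

    Stepped per batch. Starts at max_lr / div_factor, peaks at max_lr after
    ``pct_start`` of the steps, ends at max_lr / final_div_factor.
    """

    def __init__(
        self,
        max_lr: float,
        total_steps: int,
        pct_start: float = 0.3,
        div_factor: float = 25.0,
        final_div_factor: float = 1e4,
    ):
        self.max_lr = max_lr
        self.total_steps = max(total_steps, 1)
        self.pct_start = pct_start
        self.initial_lr = max_lr / div_factor
        self.final_lr = max_lr / final_div_factor
        self.step_num = 0
        self.history: list = []

    def lr_at(self, step: int) -> float:
        up = self.pct_start * self.total_steps
        if step <= up:
            frac = step / max(up, 1)
            lo, hi = self.initial_lr, self.max_lr
        else:
            frac = (step - up) / max(self.total_steps - up, 1)
            lo, hi = self.max_lr, self.final_lr
            frac = min(frac, 1.0)
            return hi + (lo - hi) * (1 + np.cos(np.pi * frac)) / 2
        return lo + (hi - lo) * (1 - np.cos(np.pi * frac)) / 2

    def step(self) -> float:
        self.step_num += 1
        lr = float(self.lr_at(self.step_num))
        self.history.append(lr)
        return lr


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=-1, keepdims=True)


def bce_with_logits_loss(logits: np.ndarray, targets: np.ndarray, sample_weights: np.ndarray):
    """Weighted binary cross-entropy on a single logit per sample.

    Per-sample weights realize the class weighting: a misclassified sample of
    a class weighted w contributes w times the unweighted loss. Loss is the
    weight-normalized mean; returns (loss, dlogits).
    """
    z = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(targets, dtype=np.float64).ravel()
    w = np.asarray(sample_weights, dtype=np.float64).ravel()
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    wsum = w.sum()
    loss = float((w * per).sum() / wsum)
    dz = ((sigmoid(z) - y) * w / wsum).astype(np.float32)
    return loss, dz


def softmax_cross_entropy_loss(logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray):
    """Class-weighted multiclass cross-entropy; mean normalized by the summed
    weights of the targets present (the convention of the standard DL
    runtimes, which keeps the loss scale invariant to rescaling all weights).
    Returns (loss, dlogits).
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.int64)
    cw = np.asarray(class_weights, dtype=np.float64)
    p = softmax(z)
    n = len(y)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-300, None))
    w = cw[y]
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    dz = (grad * (w / wsum)[:, None]).astype(np.float32)
    return loss, dz
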