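"""A small, fully deterministic NumPy convolutional network.

The classifier needs two things most frameworks entangle with heavyweight
dependencies: seeded, reproducible training on modest grayscale images, and
gradients of a class score with respect to the *input* pixels (the primitive
behind SmoothGrad saliency).  Both are provided here directly: conv blocks
(3x3 conv + ReLU + 2x2 max-pool), a ReLU dense layer, a linear head, softmax
cross-entropy, and Adam, all in float32 NumPy with explicit backward passes.

Convolutions use im2col via ``sliding_window_view``; the input gradient of a
"same" 3x3 convolution is the convolution of the output gradient with the
spatially flipped, channel-transposed kernel, so the same machinery serves
forward and backward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*9) patch matrix for a same-padded 3x3 conv."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, W, 3, 3)
    win = win.transpose(0, 2, 3, 1, 4, 5)  # (B, H, W, C, 3, 3)
    return np.ascontiguousarray(win).reshape(b * h * w, c * 9)


class Conv3x3:
    """Same-padded 3x3 convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray, store: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x)
        out = cols @ self.w + self.b
        if store:
            self._cols, self._shape = cols, (b, c, h, w)
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray, need_dx: bool = True,
                 accumulate: bool = True) -> np.ndarray | None:
        b, cout, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        if accumulate:
            self.grads[0] += (self._cols.T @ dflat).astype(np.float32)
            self.grads[1] += dflat.sum(axis=0).astype(np.float32)
        if not need_dx:
            return None
        # dx = dout convolved with flipped kernels, channels transposed
        wk = self.w.reshape(self.c_in, 3, 3, cout)
        wk_flip = wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (cout,3,3,cin)
        wt = np.ascontiguousarray(wk_flip).reshape(cout * 9, self.c_in)
        cols_d = _im2col(dout)
        dx = cols_d @ wt
        return dx.reshape(b, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, store: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if store:
            self._mask = x > 0
        else:
            self._mask = x > 0  # cheap; needed for input-gradient passes too
        return out

    def backward(self, dout, need_dx=True, accumulate=True):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (input H, W must be even)."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, store: bool) -> np.ndarray:
        b, c, h, w = x.shape
        v = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(b, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        self._idx, self._shape = idx, (b, c, h, w)
        return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout, need_dx=True, accumulate=True):
        b, c, h, w = self._shape
        dv = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dv, self._idx[..., None], dout[..., None], axis=-1)
        dv = dv.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(b, c, h, w)


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, store: bool):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, need_dx=True, accumulate=True):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, store: bool):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout, need_dx=True, accumulate=True):
        if accumulate:
            self.grads[0] += (self._x.T @ dout).astype(np.float32)
            self.grads[1] += dout.sum(axis=0).astype(np.float32)
        if not need_dx:
            return None
        return dout @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, (d / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SmallCNN:
    """Conv blocks + dense head; supports class scores and input gradients."""

    gradient_capable = True

    def __init__(self, input_size: int, conv_channels: tuple[int, ...],
                 dense_units: int, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        layers: list = []
        c_prev, size = 1, input_size
        for c in conv_channels:
            if size % 2 != 0:
                raise ValueError("input_size must halve evenly at every block")
            layers += [Conv3x3(c_prev, c, rng), ReLU(), MaxPool2()]
            c_prev, size = c, size // 2
        layers.append(Flatten())
        layers.append(Dense(c_prev * size * size, dense_units, rng))
        layers.append(ReLU())
        layers.append(Dense(dense_units, n_classes, rng))
        self.layers = layers

    # -- plumbing -----------------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    # -- passes -------------------------------------------------------------

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        return x

    def forward(self, images: np.ndarray, store: bool = False) -> np.ndarray:
        x = self._as_batch(images)
        for layer in self.layers:
            x = layer.forward(x, store)
        return x

    def backward(self, dlogits: np.ndarray, need_dx: bool = False,
                 accumulate: bool = True) -> np.ndarray | None:
        d = dlogits
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            d = layer.backward(d, need_dx=(not last) or need_dx,
                               accumulate=accumulate)
        return d

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.forward(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images).argmax(axis=1)

    def input_gradient(self, images: np.ndarray,
                       target_class: int | np.ndarray) -> np.ndarray:
        """d(score of target class logit) / d(input pixels), per image."""
        logits = self.forward(images, store=True)
        d = np.zeros_like(logits)
        idx = np.broadcast_to(np.asarray(target_class), (len(logits),))
        d[np.arange(len(logits)), idx] = 1.0
        dx = self.backward(d, need_dx=True, accumulate=False)
        return dx[:, 0]  # drop channel axis (grayscale)
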