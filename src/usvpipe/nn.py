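"""Minimal CPU neural-network engine (numpy, NCHW layout, float32).

Implements exactly the layer set the classifier needs: 2-D convolution
(im2col + GEMM), batch normalization, ELU, 2x2 max pooling, dense layers,
dropout and a softmax cross-entropy head with per-class weights.  Gradients
are hand-derived; the optimizer is SGD with Nesterov momentum and decoupled
L2 weight decay.
"""

from __future__ import annotations

import numpy as np

from usvpipe.errors import ShapeMismatchError

_DTYPE = np.float32


class Layer:
    """Base layer: stateless unless it overrides ``params``/``state``."""

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray, bool]]:
        """(value, gradient, decay?) triples; decay marks L2-regularized weights."""
        return []

    def state(self) -> list[np.ndarray]:
        """Arrays beyond trainable params to persist in snapshots."""
        return []


class Conv2D(Layer):
    """Same-padded 2-D convolution with optional stride."""

    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, int],
                 stride: tuple[int, int] = (1, 1), rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kh, kw)).astype(_DTYPE)
        self.b = np.zeros(out_channels, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.kernel = kernel
        self._cache = None

    def _pad(self) -> tuple[tuple[int, int], tuple[int, int]]:
        kh, kw = self.kernel
        return ((kh - 1) // 2, kh // 2), ((kw - 1) // 2, kw // 2)

    def forward(self, x, train, rng=None):
        kh, kw = self.kernel
        sh, sw = self.stride
        (pt, pb), (pl, pr) = self._pad()
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        n, c, hp, wp = xp.shape
        ho = (hp - kh) // sh + 1
        wo = (wp - kw) // sw + 1
        cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = cols[:, :, ::sh, ::sw][:, :, :ho, :wo]  # (n, c, ho, wo, kh, kw)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw)
        wmat = self.w.reshape(self.w.shape[0], -1).T  # (c*kh*kw, f)
        out = cols2 @ wmat + self.b
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (cols2, x.shape, xp.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        cols2, x_shape, xp_shape = self._cache
        n, f, ho, wo = grad.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        c = self.w.shape[1]
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(n * ho * wo, f)
        self.dw[...] = (gmat.T @ cols2).reshape(self.w.shape)
        self.db[...] = gmat.sum(axis=0)
        dcols = (gmat @ self.w.reshape(f, -1)).reshape(n, ho, wo, c, kh, kw)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, ho, wo, kh, kw)
        dxp = np.zeros(xp_shape, dtype=_DTYPE)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += dcols[:, :, :, :, i, j]
        (pt, pb), (pl, pr) = self._pad()
        h, w = x_shape[2], x_shape[3]
        return dxp[:, :, pt:pt + h, pl:pl + w]

    def params(self):
        return [(self.w, self.dw, True), (self.b, self.db, False)]


class BatchNorm(Layer):
    """Per-channel batch normalization for NCHW or (N, D) inputs."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels, dtype=_DTYPE)
        self.beta = np.zeros(n_channels, dtype=_DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_channels, dtype=_DTYPE)
        self.running_var = np.ones(n_channels, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @staticmethod
    def _axes(x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x, v):
        return v if x.ndim == 2 else v.reshape(1, -1, 1, 1)

    def forward(self, x, train, rng=None):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, inv_std)
        if train:
            self._cache = (xhat, inv_std)
        return self._shape(x, self.gamma) * xhat + self._shape(x, self.beta)

    def backward(self, grad):
        xhat, inv_std = self._cache
        axes = self._axes(grad)
        m = grad.size / grad.shape[1]
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = grad * self._shape(grad, self.gamma)
        dx = (g - self._shape(grad, g.sum(axis=axes) / m)
              - xhat * self._shape(grad, (g * xhat).sum(axis=axes) / m))
        return (dx * self._shape(grad, inv_std)).astype(_DTYPE)

    def params(self):
        return [(self.gamma, self.dgamma, False), (self.beta, self.dbeta, False)]

    def state(self):
        return [self.running_mean, self.running_var]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._out = None

    def forward(self, x, train, rng=None):
        out = x.astype(_DTYPE, copy=True)
        neg = out < 0
        out[neg] = self.alpha * np.expm1(out[neg])
        self._out = out
        return out

    def backward(self, grad):
        slope = np.ones_like(self._out)
        neg = self._out < 0
        slope[neg] = self._out[neg] + self.alpha
        grad = grad * slope
        return grad


class MaxPool2D(Layer):
    """2x2 (or (ph, pw)) max pooling with stride = pool size; crops remainders."""

    def __init__(self, pool: tuple[int, int] = (2, 2)):
        self.pool = pool
        self._cache = None

    def forward(self, x, train, rng=None):
        ph, pw = self.pool
        n, c, h, w = x.shape
        ho, wo = h // ph, w // pw
        out = None
        for i in range(ph):
            for j in range(pw):
                s = x[:, :, i:ho * ph:ph, j:wo * pw:pw]
                out = s.copy() if out is None else np.maximum(out, s, out=out)
        self._cache = (x, out, x.shape)
        return out

    def backward(self, grad):
        x, out, x_shape = self._cache
        ph, pw = self.pool
        n, c, ho, wo = grad.shape
        dx = np.zeros(x_shape, dtype=_DTYPE)
        claimed = np.zeros(grad.shape, dtype=bool)
        for i in range(ph):
            for j in range(pw):
                s = x[:, :, i:ho * ph:ph, j:wo * pw:pw]
                hit = (s == out) & ~claimed  # route each grad to one argmax
                claimed |= hit
                dx[:, :, i:ho * ph:ph, j:wo * pw:pw] += grad * hit
        return dx


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim),
                            size=(in_dim, out_dim)).astype(_DTYPE)
        self.b = np.zeros(out_dim, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw, True), (self.b, self.db, False)]


class Dropout(Layer):
    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def forward(self, x, train, rng=None):
        if not train or self.p <= 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout needs an rng in training mode")
        self._mask = (rng.uniform(size=x.shape) >= self.p).astype(_DTYPE) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain sequential network with a weighted softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=_DTYPE)
        if out.ndim == 3:  # (n, h, w) -> single-channel images
            out = out[:, None]
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        chunks = [softmax(self.forward(x[i:i + batch_size], train=False))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray,
                      class_weight: np.ndarray | None,
                      rng: np.random.Generator) -> float:
        """Weighted cross-entropy on integer labels; backprops through all layers."""
        if len(x) != len(y):
            raise ShapeMismatchError("x and y batch sizes differ")
        logits = self.forward(x, train=True, rng=rng)
        p = softmax(logits)
        n, k = p.shape
        cw = np.ones(k, dtype=_DTYPE) if class_weight is None else class_weight
        sample_w = cw[y]
        eps = 1e-12
        loss = float(np.mean(sample_w * -np.log(p[np.arange(n), y] + eps)))
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (sample_w / n)[:, None]
        grad = dlogits.astype(_DTYPE)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    # --- parameter access -------------------------------------------------
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(v.size for v, _, _ in self.params())

    def get_state(self) -> list[np.ndarray]:
        arrays = [v.copy() for v, _, _ in self.params()]
        for layer in self.layers:
            arrays.extend(a.copy() for a in layer.state())
        return arrays

    def set_state(self, arrays: list[np.ndarray]) -> None:
        targets = [v for v, _, _ in self.params()]
        for layer in self.layers:
            targets.extend(layer.state())
        if len(targets) != len(arrays):
            raise ShapeMismatchError("snapshot does not match network layout")
        for tgt, src in zip(targets, arrays):
            tgt[...] = src


class NesterovSGD:
    """SGD with Nesterov momentum and L2 weight decay on flagged params."""

    def __init__(self, network: Network, momentum: float = 0.9,
                 l2_coeff: float = 0.0):
        self.network = network
        self.momentum = momentum
        self.l2_coeff = l2_coeff
        self.velocity = [np.zeros_like(v) for v, _, _ in network.params()]

    def step(self, lr: float) -> None:
        mu = self.momentum
        for vel, (value, grad, decay) in zip(self.velocity, self.network.params()):
            g = grad + self.l2_coeff * value if decay and self.l2_coeff else grad
            vel *= mu
            vel += g
            value -= (lr * (g + mu * vel)).astype(value.dtype)
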