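"""Compact NumPy neural-network layers with reverse-mode gradients.

Implements exactly what the reward-regression agent needs: 3x3 same-pad
convolutions (im2col + BLAS matmul), ReLU, 2x2 max pooling, batch
normalisation (2d per-channel and 1d per-feature, with running statistics
for inference), dense layers, and an RMSProp optimiser with heavy-ball
momentum and a stepped learning-rate schedule.  All computation is
float32.

Layers expose ``forward(x, train)`` and ``backward(grad)``; parameters
and their gradients are flat lists so the optimiser is layer-agnostic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "BatchNorm",
    "Flatten",
    "Dense",
    "Sequential",
    "RMSProp",
]

F32 = np.float32


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def state(self) -> dict:
        return {}

    def load_state(self, state: dict) -> None:
        pass


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of the zero-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, h, w, 3, 3),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
    )
    # (N, H, W, C, 3, 3) -> rows
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (c_in * 9, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train):
        from . import _nnops

        self.x_shape = x.shape
        n, c, h, w = x.shape
        x = np.ascontiguousarray(x, dtype=F32)
        if _nnops.HAVE_NUMBA:
            wk = np.ascontiguousarray(self.w.reshape(self.c_in, 3, 3, self.c_out))
            out, self.xp = _nnops.conv3x3_forward(x, wk, self.b)
            self.cols = None
            return out
        self.cols = _im2col3(x)
        out = self.cols @ self.w + self.b
        return np.ascontiguousarray(
            out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, g):
        from . import _nnops

        n, _, h, w = self.x_shape
        if self.cols is None:  # numba path
            wk = np.ascontiguousarray(self.w.reshape(self.c_in, 3, 3, self.c_out))
            dwk, db, dx = _nnops.conv3x3_backward(self.xp, wk, g)
            self.dw[...] = dwk.reshape(self.c_in * 9, self.c_out)
            self.db[...] = db
            return dx
        gr = g.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dw[...] = self.cols.T @ gr
        self.db[...] = gr.sum(axis=0)
        # grad wrt input = correlation of g with spatially flipped kernels
        wk = self.w.reshape(self.c_in, 3, 3, self.c_out)
        wk_flip = wk[:, ::-1, ::-1, :]
        w_back = wk_flip.transpose(3, 1, 2, 0).reshape(self.c_out * 9, self.c_in)
        cols_g = _im2col3(np.ascontiguousarray(g, dtype=F32))
        dx = cols_g @ w_back
        return np.ascontiguousarray(
            dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        )

    def state(self):
        return {"w": self.w, "b": self.b}

    def load_state(self, st):
        self.w[...] = st["w"]
        self.b[...] = st["b"]


class ReLU(Layer):
    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input sides must be even)."""

    def forward(self, x, train):
        from . import _nnops

        self.in_shape = x.shape
        if _nnops.HAVE_NUMBA:
            out, self.idx = _nnops.pool2_forward(
                np.ascontiguousarray(x, dtype=F32)
            )
            self._numba = True
            return out
        self._numba = False
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self.idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        from . import _nnops

        n, c, h, w = self.in_shape
        if self._numba:
            return _nnops.pool2_backward(g, self.idx, self.in_shape)
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(out, self.idx[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class BatchNorm(Layer):
    """Batch normalisation over batch (+ spatial) axes.

    ``ndim=4`` normalises per channel of (N, C, H, W); ``ndim=2`` per
    feature of (N, F).  Inference uses exponential running statistics.
    """

    def __init__(self, n_feat: int, ndim: int, momentum: float = 0.9):
        self.gamma = np.ones(n_feat, dtype=F32)
        self.beta = np.zeros(n_feat, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(n_feat, dtype=F32)
        self.run_var = np.ones(n_feat, dtype=F32)
        self.momentum = momentum
        self.eps = 1e-5
        self.axes = (0, 2, 3) if ndim == 4 else (0,)
        self.ndim = ndim

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def _shape(self, v):
        return v.reshape(1, -1, 1, 1) if self.ndim == 4 else v.reshape(1, -1)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - self._shape(mean)) * self._shape(self.inv_std)
        return self._shape(self.gamma) * self.xhat + self._shape(self.beta)

    def backward(self, g):
        m = g.size / g.shape[1] if self.ndim == 4 else g.shape[0]
        self.dgamma[...] = (g * self.xhat).sum(axis=self.axes)
        self.dbeta[...] = g.sum(axis=self.axes)
        gg = g * self._shape(self.gamma)
        dx = (
            gg
            - self._shape(gg.sum(axis=self.axes) / m)
            - self.xhat * self._shape((gg * self.xhat).sum(axis=self.axes) / m)
        ) * self._shape(self.inv_std)
        return dx.astype(g.dtype)

    def state(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "run_mean": self.run_mean,
            "run_var": self.run_var,
        }

    def load_state(self, st):
        for k, v in st.items():
            getattr(self, k)[...] = v


class Flatten(Layer):
    def forward(self, x, train):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self.in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train):
        self.x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw[...] = self.x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.w.T

    def state(self):
        return {"w": self.w, "b": self.b}

    def load_state(self, st):
        self.w[...] = st["w"]
        self.b[...] = st["b"]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def state(self):
        return {str(i): l.state() for i, l in enumerate(self.layers) if l.state()}

    def load_state(self, st):
        for i, l in enumerate(self.layers):
            if str(i) in st:
                l.load_state(st[str(i)])


class RMSProp:
    """RMSProp with heavy-ball momentum and a stepped learning-rate decay.

    The squared-gradient running average uses smoothing ``alpha``; the
    RMS-normalised step is accumulated into a momentum buffer with factor
    ``momentum``.  The effective learning rate is
    ``lr * decay_ratio ** (iteration // decay_interval)``.
    """

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 0.01,
        momentum: float = 0.9,
        alpha: float = 0.9,
        decay_ratio: float = 0.8,
        decay_interval: int = 10_000,
        eps: float = 1e-8,
        max_grad_norm: float | None = 10.0,
    ):
        self.params = params
        self.lr0 = lr
        self.momentum = momentum
        self.alpha = alpha
        self.decay_ratio = decay_ratio
        self.decay_interval = decay_interval
        self.eps = eps
        self.max_grad_norm = max_grad_norm
        self.sq = [np.zeros_like(p) for p in params]
        self.mom = [np.zeros_like(p) for p in params]
        self.iteration = 0

    def current_lr(self, iteration: int | None = None) -> float:
        it = self.iteration if iteration is None else iteration
        return self.lr0 * self.decay_ratio ** (it // self.decay_interval)

    def step(self, grads: list[np.ndarray]) -> None:
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.max_grad_norm:
                scale = F32(self.max_grad_norm / (total + 1e-12))
                grads = [g * scale for g in grads]
        self.iteration += 1
        lr = F32(self.current_lr(self.iteration - 1))
        for p, g, s, m in zip(self.params, grads, self.sq, self.mom):
            s *= self.alpha
            s += (1 - self.alpha) * g * g
            m *= self.momentum
            m -= lr * g / np.sqrt(s + self.eps)
            p += m
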