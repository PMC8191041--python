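"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implements exactly the pieces the two networks in this package need: 1-D
convolutions (full and depthwise, with stride and dilation), batch
normalisation, ReLU, residual wrappers, nearest-neighbour upsampling, global
average pooling, dense heads, softmax/sigmoid losses, and Adam.  Shapes follow
the (batch, channels, length) convention throughout.

The layers are deliberately small and explicit rather than general; gradient
correctness is guarded by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

#: default parameter/activation precision; float32 halves memory traffic,
#: which dominates runtime for these small networks on one core
DTYPE = np.float32


class Layer:
    """Base class: a layer owns its parameters and their gradients."""

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(k: int, dilation: int) -> tuple[int, int]:
    total = dilation * (k - 1)
    return total // 2, total - total // 2


class Conv1D(Layer):
    """1-D convolution with 'same'-style padding.

    ``depthwise=True`` ties channels (groups == c_in == c_out).  With
    ``stride=s`` the output length is ``ceil(L / s)``.
    """

    def __init__(self, c_in, c_out, kernel, rng, stride=1, dilation=1, depthwise=False,
                 dtype=None):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.stride, self.dilation = stride, dilation
        self.depthwise = depthwise
        dtype = dtype or DTYPE
        if depthwise:
            if c_in != c_out:
                raise ValueError("depthwise convolution requires c_in == c_out")
            scale = np.sqrt(2.0 / kernel)
            self.w = rng.normal(0.0, scale, size=(c_in, kernel)).astype(dtype)
        else:
            scale = np.sqrt(2.0 / (c_in * kernel))
            self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def _tap(self, kk: int) -> slice:
        off = kk * self.dilation
        return slice(off, off + self.stride * (self._lo - 1) + 1, self.stride)

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=self.w.dtype)
        b, c, l = x.shape
        pl, pr = _same_pad(self.k, self.dilation)
        l_out = -(-l // self.stride)
        need = (l_out - 1) * self.stride + self.dilation * (self.k - 1) + 1
        pr = pr + max(0, need - (l + pl + pr))
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._xp, self._pl, self._l, self._lo = xp, pl, l, l_out
        if self.depthwise:
            out = np.zeros((b, self.c_out, l_out), dtype=x.dtype)
            for kk in range(self.k):
                out += xp[:, :, self._tap(kk)] * self.w[None, :, kk, None]
        elif self.k == 1 and self.stride == 1:
            # pointwise: a single channel-mixing matmul
            out = np.tensordot(self.w[:, :, 0], xp, axes=([1], [1])).transpose(1, 0, 2)
        else:
            out = np.zeros((self.c_out, b, l_out), dtype=x.dtype)
            for kk in range(self.k):
                out += np.tensordot(self.w[:, :, kk], xp[:, :, self._tap(kk)], axes=([1], [1]))
            out = out.transpose(1, 0, 2)
        return out + self.b[None, :, None]

    def backward(self, grad):
        self.gb += grad.sum(axis=(0, 2))
        gxp = np.zeros_like(self._xp)
        if self.depthwise:
            for kk in range(self.k):
                tap = self._tap(kk)
                self.gw[:, kk] += (self._xp[:, :, tap] * grad).sum(axis=(0, 2))
                gxp[:, :, tap] += grad * self.w[None, :, kk, None]
        else:
            for kk in range(self.k):
                tap = self._tap(kk)
                xs = self._xp[:, :, tap]
                self.gw[:, :, kk] += np.tensordot(grad, xs, axes=([0, 2], [0, 2]))
                gxp[:, :, tap] += np.tensordot(self.w[:, :, kk], grad, axes=([0], [1])).transpose(
                    1, 0, 2
                )
        return gxp[:, :, self._pl : self._pl + self._l]


class BatchNorm1D(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5, dtype=None):
        dtype = dtype or DTYPE
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.ggamma = np.zeros(c, dtype=dtype)
        self.gbeta = np.zeros(c, dtype=dtype)
        self.run_mean = np.zeros(c, dtype=dtype)
        self.run_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = (x - mean[None, :, None]) * self._istd[None, :, None]
        self._train = train
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        self.ggamma += (grad * self._xhat).sum(axis=(0, 2))
        self.gbeta += grad.sum(axis=(0, 2))
        gx = grad * self.gamma[None, :, None]
        if not self._train:
            return gx * self._istd[None, :, None]
        n = grad.shape[0] * grad.shape[2]
        gsum = gx.sum(axis=(0, 2))[None, :, None]
        gxhat_sum = (gx * self._xhat).sum(axis=(0, 2))[None, :, None]
        return (self._istd[None, :, None] / n) * (n * gx - gsum - self._xhat * gxhat_sum)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class UpsampleNearest(Layer):
    def __init__(self, factor=2):
        self.factor = factor

    def forward(self, x, train):
        return np.repeat(x, self.factor, axis=2)

    def backward(self, grad):
        b, c, l = grad.shape
        lo = l // self.factor
        return grad[:, :, : lo * self.factor].reshape(b, c, lo, self.factor).sum(axis=3)


class CropTo(Layer):
    """Crop the length axis to match a residual partner (decoder bookkeeping)."""

    def __init__(self):
        self.target = None

    def forward(self, x, train):
        self._l = x.shape[2]
        if self.target is None or self.target >= self._l:
            self._crop = 0
            return x
        self._crop = self._l - self.target
        return x[:, :, : self.target]

    def backward(self, grad):
        if self._crop == 0:
            return grad
        return np.pad(grad, ((0, 0), (0, 0), (0, self._crop)))


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._l, axis=2) / self._l


class Dense(Layer):
    def __init__(self, c_in, c_out, rng, dtype=None):
        dtype = dtype or DTYPE
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train):
        x = np.asarray(x, dtype=self.w.dtype)
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw += grad.T @ self._x
        self.gb += grad.sum(axis=0)
        return grad @ self.w


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class Residual(Layer):
    """y = x + f(x); the inner block must preserve shape."""

    def __init__(self, block: Layer):
        self.block = block

    def params(self):
        return self.block.params()

    def forward(self, x, train):
        return x + self.block.forward(x, train)

    def backward(self, grad):
        return grad + self.block.backward(grad)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_ce_loss(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """(Weighted) mean cross-entropy over (B, n_classes) logits.

    Returns (loss, dloss/dlogits).  ``class_weights`` reweights each sample by
    its true class, shifting the trained operating point between classes.
    """
    p = softmax(logits)
    n = logits.shape[0]
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    loss = -(w * np.log(np.maximum(p[np.arange(n), labels], 1e-12))).sum() / wsum
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad * (w / wsum)[:, None]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def bce_logits_loss(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Masked mean binary cross-entropy on arbitrary-shape logits."""
    p = sigmoid(logits)
    if mask is None:
        mask = np.ones_like(logits)
    n = max(mask.sum(), 1.0)
    eps = 1e-12
    loss = -(mask * (targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))).sum() / n
    grad = mask * (p - targets) / n
    return float(loss), grad


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


def state_arrays(model: Layer) -> list[np.ndarray]:
    """All learnable parameters plus batch-norm running statistics, in order."""
    arrays = [p for p, _ in model.params()]
    for lay in _walk(model):
        if isinstance(lay, BatchNorm1D):
            arrays.extend([lay.run_mean, lay.run_var])
    return arrays


def _walk(layer: Layer):
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _walk(sub)
    elif isinstance(layer, Residual):
        yield from _walk(layer.block)


def save_state(model: Layer, path, meta: dict) -> None:
    arrays = {f"arr_{i}": a for i, a in enumerate(state_arrays(model))}
    import json

    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_state(model: Layer, path) -> dict:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        for i, a in enumerate(state_arrays(model)):
            a[...] = data[f"arr_{i}"]
    return meta


def parameter_count(model: Layer) -> int:
    return int(sum(p.size for p, _ in model.params()))
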