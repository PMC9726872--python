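"""Minimal NumPy neural-network engine with manual backpropagation.

Layers operate on NHWC arrays (batch, height, width, channels) in float64 and
expose ``forward(x, train)`` / ``backward(dout)`` with gradients accumulated on
:class:`Param` objects.  The engine implements exactly what the generative and
classification networks in this package need: dense, strided convolution,
strided transposed convolution, batch normalisation, max pooling, dropout and
the usual activations, plus an Adam optimiser.  Everything is driven by
explicit ``numpy.random.Generator`` instances so runs are bit-reproducible.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

#: dtype for newly created parameters; float32 roughly halves training cost
#: (the engine is memory-bandwidth-bound) at ample precision for SGD.
DTYPE = np.dtype("float64")


@contextmanager
def default_dtype(dtype):
    """Temporarily change the parameter dtype for layer construction."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        DTYPE = old

__all__ = [
    "Param", "Layer", "Sequential", "Dense", "Conv2D", "ConvTranspose2D",
    "BatchNorm", "ReLU", "LeakyReLU", "Tanh", "Sigmoid", "Flatten", "Reshape",
    "Dropout", "MaxPool2D", "Adam", "softmax_cross_entropy",
    "iter_layers", "get_state", "set_state",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: stateless by default, subclasses cache what backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def set_rng(self, rng: np.random.Generator) -> None:
        """Propagate an RNG to stochastic layers (dropout)."""

    def sublayers(self) -> list["Layer"]:
        return []

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def set_rng(self, rng):
        for layer in self.layers:
            layer.set_rng(rng)

    def sublayers(self):
        return list(self.layers)


def iter_layers(root: Layer):
    """Depth-first walk over a layer tree (root included)."""
    yield root
    for child in root.sublayers():
        yield from iter_layers(child)


def get_state(root: Layer) -> list[np.ndarray]:
    """All trainable parameters plus batch-norm running statistics, in a
    deterministic order, as copies."""
    arrays = [p.value.copy() for p in root.params()]
    for layer in iter_layers(root):
        if isinstance(layer, BatchNorm):
            arrays.append(layer.running_mean.copy())
            arrays.append(layer.running_var.copy())
    return arrays


def set_state(root: Layer, arrays: list[np.ndarray]) -> None:
    """Inverse of :func:`get_state`."""
    arrays = list(arrays)
    params = root.params()
    for p, a in zip(params, arrays[:len(params)]):
        if p.value.shape != a.shape:
            raise ValueError("state shape mismatch")
        p.value = np.asarray(a, dtype=p.value.dtype).copy()
        p.grad = np.zeros_like(p.value)
    rest = arrays[len(params):]
    bns = [l for l in iter_layers(root) if isinstance(l, BatchNorm)]
    if len(rest) != 2 * len(bns):
        raise ValueError("state does not match layer tree")
    for bn, mean, var in zip(bns, rest[0::2], rest[1::2]):
        bn.running_mean = np.asarray(mean, dtype=bn.running_mean.dtype).copy()
        bn.running_var = np.asarray(var, dtype=bn.running_var.dtype).copy()


# ---------------------------------------------------------------------------
# initialisers

def _init_weight(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int, std: float | None) -> np.ndarray:
    """Normal(0, std) if std given, else He initialisation sqrt(2/fan_in)."""
    scale = std if std is not None else np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, scale, size=shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# dense

def _cast(x, ref):
    x = np.asarray(x)
    return x if x.dtype == ref.dtype else x.astype(ref.dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_std: float | None = None, bias: bool = True) -> None:
        self.W = Param(_init_weight(rng, (n_in, n_out), n_in, w_std), "dense.W")
        self.b = Param(np.zeros(n_out), "dense.b") if bias else None
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        x = _cast(x, self.W.value)
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dout):
        dout = _cast(dout, self.W.value)
        self.W.grad += self._x.T @ dout
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


# ---------------------------------------------------------------------------
# im2col machinery (NHWC)

def _out_size(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def _im2col(x: np.ndarray, kh: int, kw: int, s: int, p: int,
            oh: int, ow: int) -> np.ndarray:
    """(N,H,W,C) -> (N*oh*ow, kh*kw*C) patch matrix."""
    n, h, w, c = x.shape
    if kh == kw == 1 and s == 1 and p == 0:  # pointwise conv fast path
        return x.reshape(n * h * w, c)
    if p:
        xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
        xp[:, p:p + h, p:p + w, :] = x
    else:
        xp = x
    cols = np.empty((n, oh, ow, kh, kw, c), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i:i + s * oh:s, j:j + s * ow:s, :]
    return cols.reshape(n * oh * ow, kh * kw * c)


def _col2im(cols: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int,
            s: int, p: int, oh: int, ow: int,
            pad_extra: int = 0) -> np.ndarray:
    """Adjoint of :func:`_im2col`; ``pad_extra`` allows bottom/right slack
    (transposed convolution output padding)."""
    n, h, w, c = x_shape
    if kh == kw == 1 and s == 1 and p == 0 and pad_extra == 0:
        return cols.reshape(n, h, w, c)
    xp = np.zeros((n, h + 2 * p + pad_extra, w + 2 * p + pad_extra, c),
                  dtype=cols.dtype)
    cols = cols.reshape(n, oh, ow, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            xp[:, i:i + s * oh:s, j:j + s * ow:s, :] += cols[:, :, :, i, j, :]
    return xp[:, p:p + h, p:p + w, :]


class Conv2D(Layer):
    """Strided 2-D convolution, symmetric zero padding (default ``k // 2``)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None, w_std: float | None = None,
                 bias: bool = True) -> None:
        self.k, self.s = kernel, stride
        self.p = kernel // 2 if padding is None else padding
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel * kernel * c_in
        self.W = Param(_init_weight(rng, (fan_in, c_out), fan_in, w_std),
                       "conv.W")
        self.b = Param(np.zeros(c_out), "conv.b") if bias else None
        self._cols = None
        self._x_shape = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        x = _cast(x, self.W.value)
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        oh, ow = _out_size(h, self.k, self.s, self.p), _out_size(w, self.k, self.s, self.p)
        self._cols, self._x_shape = _im2col(x, self.k, self.k, self.s, self.p, oh, ow), x.shape
        y = self._cols @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y.reshape(n, oh, ow, self.c_out)

    def backward(self, dout):
        dout = _cast(dout, self.W.value)
        n, oh, ow, _ = dout.shape
        dflat = dout.reshape(n * oh * ow, self.c_out)
        self.W.grad += self._cols.T @ dflat
        if self.b is not None:
            self.b.grad += dflat.sum(axis=0)
        return _col2im(dflat @ self.W.value.T, self._x_shape,
                       self.k, self.k, self.s, self.p, oh, ow)


class ConvTranspose2D(Layer):
    """Transposed convolution (fractionally-strided), the exact adjoint of a
    strided :class:`Conv2D`; with kernel 3, stride 2, padding 1 and output
    padding 1 it doubles each spatial dimension."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 2, padding: int = 1,
                 output_padding: int = 1, w_std: float | None = None,
                 bias: bool = True) -> None:
        self.k, self.s, self.p, self.op = kernel, stride, padding, output_padding
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel * kernel * c_in
        # weight laid out as the adjoint conv's (k*k*c_out, c_in) matrix
        self.W = Param(_init_weight(rng, (kernel * kernel * c_out, c_in),
                                    fan_in, w_std), "tconv.W")
        self.b = Param(np.zeros(c_out), "tconv.b") if bias else None
        self._x = None
        self._out_shape = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_size(self, h: int) -> int:
        return (h - 1) * self.s - 2 * self.p + self.k + self.op

    def forward(self, x, train=False):
        x = _cast(x, self.W.value)
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        oh, ow = self.out_size(h), self.out_size(w)
        self._x, self._out_shape = x, (n, oh, ow, self.c_out)
        cols = x.reshape(n * h * w, c) @ self.W.value.T
        y = _col2im(cols, self._out_shape, self.k, self.k, self.s, self.p,
                    h, w, pad_extra=self.op)
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dout):
        dout = _cast(dout, self.W.value)
        n, h, w, _ = self._x.shape
        # pad dout with the output-padding slack so im2col geometry matches
        if self.op:
            no, ho, wo, co = dout.shape
            dpad = np.zeros((no, ho + self.op, wo + self.op, co),
                            dtype=dout.dtype)
            dpad[:, :ho, :wo, :] = dout
        else:
            dpad = dout
        cols = _im2col(dpad, self.k, self.k, self.s, self.p, h, w)
        self.W.grad += cols.T @ self._x.reshape(n * h * w, self.c_in)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 1, 2))
        return (cols @ self.W.value).reshape(n, h, w, self.c_in)


class BatchNorm(Layer):
    """Batch normalisation over batch (and spatial, for 4-D) axes.

    ``momentum`` follows the Keras convention: running = m*running + (1-m)*batch.
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        x = _cast(x, self.gamma.value)
        axes = (0, 1, 2) if x.ndim == 4 else (0,)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std, axes, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, std, axes, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value
        if not train:
            return dout * g / std
        m = np.prod([xhat.shape[a] for a in axes])
        return (g / (m * std)) * (m * dout
                                  - dout.sum(axis=axes, keepdims=True)
                                  - xhat * (dout * xhat).sum(axis=axes,
                                                             keepdims=True))


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    """Reshape each sample to ``shape`` (batch axis preserved)."""

    def __init__(self, shape: tuple[int, ...]) -> None:
        self.shape = shape

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None
        self._mask = None

    def set_rng(self, rng):
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout needs an RNG: call set_rng() first")
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling (window = stride); input dims must divide."""

    def __init__(self, size: int = 2) -> None:
        self.size = size

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k = self.size
        if h % k or w % k:
            raise ValueError(f"spatial dims {(h, w)} not divisible by {k}")
        win = x.reshape(n, h // k, k, w // k, k, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, h // k, w // k, c, k * k)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._in_shape
        k = self.size
        dwin = np.zeros((n, h // k, w // k, c, k * k), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(n, h // k, w // k, c, k, k).transpose(0, 1, 4, 2, 5, 3)
        return dwin.reshape(n, h, w, c)


# ---------------------------------------------------------------------------
# loss and optimiser

def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dlogits)`` with the gradient already averaged over the
    batch.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)
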