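"""Minimal CPU neural-network layers with explicit backpropagation.

Float32 throughout.  Convolutions use strided window views feeding BLAS
matrix products, chunked over the batch to bound the im2col buffer.  Each
layer caches what its backward pass needs during forward; ``backward``
accumulates parameter gradients and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Param", "Layer", "Sequential", "Conv2d", "Linear", "BatchNorm2d",
    "AvgPool2d", "MaxPool2d", "Dropout", "Flatten", "SEBlock",
    "ReLU", "ELU", "Sigmoid", "Square", "SafeLog",
]

# cap on the im2col scratch buffer (float32 elements)
_COL_BUDGET = 48_000_000


class Param:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    training: bool = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def train(self, mode: bool = True) -> None:
        self.training = mode

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _windows(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """Read-only sliding-window view (B, C, OH, OW, kh, kw) of a contiguous x."""
    b, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    view = as_strided(
        x, (b, c, oh, ow, kh, kw), (s0, s1, s2 * sh, s3 * sw, s2, s3), writeable=False
    )
    return view, oh, ow


def _conv2d_raw(x, w, stride, groups):
    """Valid cross-correlation of padded input x with kernel w.

    x: (B, Cin, H, W) contiguous; w: (Cout, Cin/groups, kh, kw).
    Returns (B, Cout, OH, OW).
    """
    b, cin, _, _ = x.shape
    cout, cg, kh, kw = w.shape
    sh, sw = stride
    og = cout // groups
    _, oh, ow = None, None, None
    out = None
    for g in range(groups):
        xg = x[:, g * cg : (g + 1) * cg]
        wg = w[g * og : (g + 1) * og].reshape(og, cg * kh * kw)
        view, oh, ow = _windows(xg, kh, kw, sh, sw)
        if out is None:
            out = np.empty((b, cout, oh, ow), dtype=np.float32)
        per_item = oh * ow * cg * kh * kw
        chunk = max(1, _COL_BUDGET // max(per_item, 1))
        for lo in range(0, b, chunk):
            hi = min(lo + chunk, b)
            cols = np.ascontiguousarray(
                view[lo:hi].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(-1, cg * kh * kw)
            y = cols @ wg.T  # (n*oh*ow, og)
            out[lo:hi, g * og : (g + 1) * og] = y.reshape(
                hi - lo, oh, ow, og
            ).transpose(0, 3, 1, 2)
    return out


def _conv2d_grad_w(x, grad, kh, kw, stride, groups, cout):
    """Kernel gradient for _conv2d_raw: accumulate cols^T @ grad per group."""
    b, cin, _, _ = x.shape
    cg = cin // groups
    og = cout // groups
    sh, sw = stride
    dw = np.zeros((cout, cg, kh, kw), dtype=np.float32)
    for g in range(groups):
        xg = x[:, g * cg : (g + 1) * cg]
        view, oh, ow = _windows(xg, kh, kw, sh, sw)
        gg = grad[:, g * og : (g + 1) * og]
        per_item = oh * ow * cg * kh * kw
        chunk = max(1, _COL_BUDGET // max(per_item, 1))
        acc = np.zeros((og, cg * kh * kw), dtype=np.float32)
        for lo in range(0, b, chunk):
            hi = min(lo + chunk, b)
            cols = np.ascontiguousarray(
                view[lo:hi].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(-1, cg * kh * kw)
            gcols = np.ascontiguousarray(
                gg[lo:hi].transpose(0, 2, 3, 1)
            ).reshape(-1, og)
            acc += gcols.T @ cols
        dw[g * og : (g + 1) * og] = acc.reshape(og, cg, kh, kw)
    return dw


class Conv2d(Layer):
    """2-D cross-correlation with optional grouping (groups == Cin: depthwise)."""

    def __init__(self, in_channels, out_channels, kernel, stride=(1, 1),
                 padding=(0, 0), groups=1, bias=True, rng=None, name="conv"):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        self.groups = groups
        self.name = name
        #: set by Sequential on its first layer; skips the (expensive, unused)
        #: input-gradient computation
        self.skip_input_grad = False
        rng = rng or np.random.default_rng(0)
        kh, kw = self.kernel
        fan_in = (in_channels // groups) * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.normal(0, scale, (out_channels, in_channels // groups, kh, kw)),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self._x_padded = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def output_shape(self, h, w):
        kh, kw = self.kernel
        ph, pw = self.padding
        sh, sw = self.stride
        oh = (h - kh + 2 * ph) // sh + 1
        ow = (w - kw + 2 * pw) // sw + 1
        return oh, ow

    def forward(self, x):
        ph, pw = self.padding
        x = np.ascontiguousarray(x, dtype=np.float32)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        kh, kw = self.kernel
        if x.shape[2] < kh or x.shape[3] < kw:
            raise ValueError(
                f"{self.name}: kernel {self.kernel} larger than padded input "
                f"{x.shape[2:]}"
            )
        self._x_padded = x
        out = _conv2d_raw(x, self.weight.data, self.stride, self.groups)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return out

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        x = self._x_padded
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        self.weight.grad += _conv2d_grad_w(
            x, grad, kh, kw, self.stride, self.groups, self.out_channels
        )
        if self.skip_input_grad:
            self._x_padded = None
            return None
        # input gradient = full correlation of the (dilated) output gradient
        # with the spatially flipped, channel-transposed kernel
        b, _, oh, ow = grad.shape
        if sh > 1 or sw > 1:
            dil = np.zeros(
                (b, grad.shape[1], (oh - 1) * sh + 1, (ow - 1) * sw + 1),
                dtype=np.float32,
            )
            dil[:, :, ::sh, ::sw] = grad
            grad = dil
        grad_p = np.pad(grad, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        # reshape kernel: (Cout, Cg, kh, kw) -> per group (Cg, Og, kh, kw) flipped
        cg = self.in_channels // self.groups
        og = self.out_channels // self.groups
        w = self.weight.data.reshape(self.groups, og, cg, kh, kw)
        w_t = np.ascontiguousarray(
            w.transpose(0, 2, 1, 3, 4)[..., ::-1, ::-1]
        ).reshape(self.in_channels, og, kh, kw)
        dx_full = _conv2d_raw(np.ascontiguousarray(grad_p), w_t, (1, 1), self.groups)
        # crop any overshoot (input sizes not aligned with the stride grid)
        hp, wp = x.shape[2], x.shape[3]
        dx = np.zeros_like(x)
        dx[:, :, : dx_full.shape[2], : dx_full.shape[3]] = dx_full[:, :, :hp, :wp]
        if ph or pw:
            dx = dx[:, :, ph : hp - ph, pw : wp - pw]
        self._x_padded = None
        return dx


class Linear(Layer):
    """Affine map.  ``init='zero'`` suits classification heads: logits start
    at zero (maximum-entropy softmax), avoiding saturated losses at init."""

    def __init__(self, in_features, out_features, bias=True, rng=None, name="linear",
                 init="he"):
        rng = rng or np.random.default_rng(0)
        if init == "zero":
            w = np.zeros((out_features, in_features))
        else:
            w = rng.normal(0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self.weight = Param(w, name=f"{name}.weight")
        self.bias = Param(np.zeros(out_features), name=f"{name}.bias") if bias else None
        self._x = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.data
        self._x = None
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (batch, H, W)."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1, name="bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(num_features), name=f"{name}.gamma")
        self.beta = Param(np.zeros(num_features), name=f"{name}.beta")
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_sd[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv_sd)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, inv_sd = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        dbeta = grad.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data[None, :, None, None] * inv_sd[None, :, None, None]
        dx = g * (
            grad
            - dbeta[None, :, None, None] / n
            - xhat * dgamma[None, :, None, None] / n
        )
        self._cache = None
        return dx.astype(np.float32)


class AvgPool2d(Layer):
    """Average pooling; stride defaults to the kernel (non-overlapping)."""

    def __init__(self, kernel, stride=None):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride) if stride is not None else self.kernel
        self._in_shape = None

    def output_shape(self, h, w):
        kh, kw = self.kernel
        sh, sw = self.stride
        return (h - kh) // sh + 1, (w - kw) // sw + 1

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._in_shape = x.shape
        view, _, _ = _windows(x, *self.kernel, *self.stride)
        return view.mean(axis=(4, 5))

    def backward(self, grad):
        kh, kw = self.kernel
        sh, sw = self.stride
        b, c, oh, ow = grad.shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        g = grad / (kh * kw)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += g
        return dx


class MaxPool2d(Layer):
    def __init__(self, kernel, stride=None):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride) if stride is not None else self.kernel
        self._cache = None

    def output_shape(self, h, w):
        kh, kw = self.kernel
        sh, sw = self.stride
        return (h - kh) // sh + 1, (w - kw) // sw + 1

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        view, oh, ow = _windows(x, *self.kernel, *self.stride)
        flat = view.reshape(*view.shape[:4], -1)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        in_shape, idx = self._cache
        kh, kw = self.kernel
        sh, sw = self.stride
        b, c, oh, ow = grad.shape
        dx = np.zeros(in_shape, dtype=np.float32)
        bb, cc, hh, ww = np.indices((b, c, oh, ow), sparse=False)
        h_in = hh * sh + idx // kw
        w_in = ww * sw + idx % kw
        np.add.at(dx, (bb, cc, h_in, w_in), grad)
        self._cache = None
        return dx


class Dropout(Layer):
    def __init__(self, p=0.5):
        self.p = p
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (
            1.0 - self.p
        )
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class ELU(Layer):
    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def forward(self, x):
        neg = self.alpha * (np.exp(np.minimum(x, 0)) - 1)
        self._y_neg = neg
        self._pos = x > 0
        return np.where(self._pos, x, neg).astype(np.float32)

    def backward(self, grad):
        return np.where(self._pos, grad, grad * (self._y_neg + self.alpha)).astype(
            np.float32
        )


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Square(Layer):
    def forward(self, x):
        self._x = x
        return x * x

    def backward(self, grad):
        return 2.0 * self._x * grad


class SafeLog(Layer):
    """log(max(x, eps)); gradient is zero inside the clamped region."""

    def __init__(self, eps=1e-6):
        self.eps = eps

    def forward(self, x):
        self._x = x
        return np.log(np.maximum(x, self.eps))

    def backward(self, grad):
        return np.where(self._x > self.eps, grad / np.maximum(self._x, self.eps), 0.0).astype(
            np.float32
        )


class SEBlock(Layer):
    """Squeeze-and-excitation channel recalibration.

    Squeeze: global average per channel.  Excitation: two-layer bottleneck
    (C -> C/r -> C) ending in a sigmoid; the resulting weights in (0,1)
    rescale each channel of the input.
    """

    def __init__(self, channels, reduction=8, rng=None, name="se"):
        if channels < reduction:
            raise ValueError(
                f"SE reduction {reduction} exceeds channel count {channels}"
            )
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.w1 = Param(
            rng.normal(0, np.sqrt(2.0 / channels), (hidden, channels)),
            name=f"{name}.w1",
        )
        self.b1 = Param(np.zeros(hidden), name=f"{name}.b1")
        self.w2 = Param(
            rng.normal(0, np.sqrt(2.0 / hidden), (channels, hidden)),
            name=f"{name}.w2",
        )
        self.b2 = Param(np.zeros(channels), name=f"{name}.b2")
        self._cache = None

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def channel_weights(self, x):
        """Excitation weights s in (0,1), shape (B, C)."""
        z = x.mean(axis=(2, 3))
        pre = z @ self.w1.data.T + self.b1.data
        h = np.maximum(pre, 0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.w2.data.T + self.b2.data)))
        return s

    def forward(self, x):
        z = x.mean(axis=(2, 3))
        pre = z @ self.w1.data.T + self.b1.data
        h = np.maximum(pre, 0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.w2.data.T + self.b2.data)))
        self._cache = (x, z, pre, h, s)
        return x * s[:, :, None, None]

    def backward(self, grad):
        x, z, pre, h, s = self._cache
        hw = x.shape[2] * x.shape[3]
        ds = (grad * x).sum(axis=(2, 3))
        dx = grad * s[:, :, None, None]
        dpre2 = ds * s * (1.0 - s)
        self.w2.grad += dpre2.T @ h
        self.b2.grad += dpre2.sum(axis=0)
        dh = dpre2 @ self.w2.data
        dh = dh * (pre > 0)
        self.w1.grad += dh.T @ z
        self.b1.grad += dh.sum(axis=0)
        dz = dh @ self.w1.data
        dx = dx + dz[:, :, None, None] / hw
        self._cache = None
        return dx.astype(np.float32)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)
        if self.layers and isinstance(self.layers[0], Conv2d):
            self.layers[0].skip_input_grad = True

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for layer in self.layers:
            layer.train(mode)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
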