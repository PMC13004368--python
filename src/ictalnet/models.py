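"""Classifier architectures for EEG time-frequency maps.

Three binary classifiers over (n_eeg_channels, n_freq, n_time) inputs:

* ``eegnet_se`` — EEGNet-style compact CNN: temporal convolution, depthwise
  convolution along the frequency/scale axis, a depthwise-separable (3, 16)
  convolution, and a squeeze-and-excitation block, regularized with batch
  norm and dropout.
* ``shallow_convnet`` — ShallowConvNet-style: a temporal kernel, a depthwise
  convolution spanning the entire frequency extent, square -> average pool
  over time -> log, and a linear head.
* ``alexnet_baseline`` — a five-convolution reference stack whose first
  layer is widened to accept the EEG channel count directly.

Every head is sized by composing the convolution output-size rule
O = floor((I - K + 2P) / S) + 1 over the layer chain (dynamic dimension
adaptation): no flatten size is hard-coded, so the same architecture builds
for both the (22, 2560) scalogram and the (129, 39) spectrogram geometry.
Kernels and pool lengths are clipped to the current feature-map extent when
an input is too small for the nominal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ConvGeometry",
    "BatchNormParams",
    "ModelSpec",
    "Model",
    "ConstructionError",
    "conv_output_size",
    "batch_normalize",
    "se_recalibrate",
    "build_model",
    "count_parameters",
    "ARCHITECTURES",
]

ARCHITECTURES = ("eegnet_se", "shallow_convnet", "alexnet_baseline")


class ConstructionError(ValueError):
    """A layer chain cannot be realized for the requested input geometry."""


@dataclass(frozen=True)
class ConvGeometry:
    """One convolution stage's geometry in one spatial dimension pair."""

    i_h: int
    i_w: int
    k_h: int
    k_w: int
    padding: int = 0
    stride: int = 1

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if min(self.i_h, self.i_w, self.k_h, self.k_w) < 1 or self.padding < 0:
            raise ValueError("sizes must be positive, padding non-negative")


def conv_output_size(g: ConvGeometry) -> tuple[int, int]:
    """Output (height, width) under floor-division semantics."""
    if g.i_h + 2 * g.padding < g.k_h or g.i_w + 2 * g.padding < g.k_w:
        raise ValueError(
            f"kernel ({g.k_h}, {g.k_w}) larger than padded input "
            f"({g.i_h + 2 * g.padding}, {g.i_w + 2 * g.padding})"
        )
    o_h = (g.i_h - g.k_h + 2 * g.padding) // g.stride + 1
    o_w = (g.i_w - g.k_w + 2 * g.padding) // g.stride + 1
    return o_h, o_w


@dataclass
class BatchNormParams:
    """Per-feature batch-normalization parameters."""

    gamma: float | np.ndarray = 1.0
    beta: float | np.ndarray = 0.0
    eps: float = 1e-5

    def __post_init__(self):
        if not self.eps > 0:
            raise ValueError("eps must be positive")


def batch_normalize(x: np.ndarray, p: BatchNormParams) -> np.ndarray:
    """Normalize per feature over the batch axis (axis 0), then affine.

    Output = gamma * (x - mu_B) / sqrt(var_B + eps) + beta.  A zero-variance
    feature yields gamma*0 + beta thanks to the eps guard.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] < 1:
        raise ValueError("batch must contain at least one item")
    mu = x.mean(axis=0)
    var = x.var(axis=0)
    return p.gamma * (x - mu) / np.sqrt(var + p.eps) + p.beta


def se_recalibrate(feature_map: np.ndarray, reduction: int = 8, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized SE block to a single (C, H, W) feature map.

    Convenience functional form; use :class:`ictalnet.nn.SEBlock` directly to
    inspect or train the excitation weights.
    """
    fmap = np.asarray(feature_map, dtype=np.float32)
    if fmap.ndim != 3:
        raise ValueError("feature_map must be (C, H, W)")
    block = nn.SEBlock(fmap.shape[0], reduction, rng=np.random.default_rng(seed))
    return block.forward(fmap[None])[0]


@dataclass
class ModelSpec:
    """Architecture selection plus the knobs the architectures expose."""

    architecture: str = "eegnet_se"
    in_channels: int = 23
    input_hw: tuple[int, int] = (22, 2560)
    dropout_rate: float = 0.5
    se_reduction: int = 8
    n_classes: int = 2
    # eegnet_se knobs
    n_temporal_filters: int = 16
    depth_multiplier: int = 2
    temporal_kernel: int = 16
    separable_kernel: tuple[int, int] = (3, 16)  # (frequency axis, time axis)
    swap_separable_axes: bool = False
    # shallow_convnet knobs
    shallow_filters: int = 16
    shallow_temporal_kernel: int = 25
    #: temporal stride used when the time axis is >= ``long_input_threshold``
    shallow_time_stride: int = 4
    long_input_threshold: int = 1000
    #: clip nominal kernels/pools to the current feature-map extent; with
    #: False, a geometry too small for the chain raises ConstructionError
    adaptive_kernels: bool = True

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; one of {ARCHITECTURES}"
            )
        if min(self.input_hw) < 1 or self.in_channels < 1:
            raise ValueError("input dimensions must be positive")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")


class Model:
    """A built classifier: a layer stack plus its shape trace and spec."""

    def __init__(self, net: nn.Sequential, spec: ModelSpec, shape_trace: list):
        self.net = net
        self.spec = spec
        self.shape_trace = shape_trace  # [(stage name, (C, H, W))]

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def train(self, mode: bool = True) -> None:
        self.net.train(mode)

    def set_rng(self, rng: np.random.Generator) -> None:
        """Route one generator to every stochastic (dropout) layer."""
        for layer in self.net.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=np.float32))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        self.net.train(False)
        out = []
        for lo in range(0, x.shape[0], batch_size):
            out.append(self.net.forward(np.asarray(x[lo : lo + batch_size], np.float32)))
        return np.concatenate(out, axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        logits = self.predict_logits(x, batch_size)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.params(), state):
            p.data[...] = arr

    def save(self, path) -> None:
        np.savez(path, *[p.data for p in self.params()])

    def load(self, path) -> None:
        with np.load(path) as npz:
            self.load_state_dict([npz[k] for k in npz.files])


class _Tracer:
    """Accumulates layers while chaining conv_output_size; raises on collapse."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.layers: list[nn.Layer] = []
        self.trace: list[tuple[str, tuple[int, int, int]]] = []
        self.rng = rng
        self.adaptive = spec.adaptive_kernels
        self.c, (self.h, self.w) = spec.in_channels, spec.input_hw
        self.trace.append(("input", (self.c, self.h, self.w)))

    def clip_h(self, nominal: int) -> int:
        return _clip(nominal, self.h) if self.adaptive else nominal

    def clip_w(self, nominal: int) -> int:
        return _clip(nominal, self.w) if self.adaptive else nominal

    def _advance(self, stage, kh, kw, sh, sw, ph=0, pw=0):
        try:
            oh, _ = conv_output_size(ConvGeometry(self.h, self.h, kh, kh, ph, sh))
            _, ow = conv_output_size(ConvGeometry(self.w, self.w, kw, kw, pw, sw))
        except ValueError as exc:
            raise ConstructionError(f"stage {stage!r}: {exc}") from exc
        if oh < 1 or ow < 1:
            raise ConstructionError(
                f"stage {stage!r} collapses the feature map to ({oh}, {ow})"
            )
        self.h, self.w = oh, ow

    def conv(self, stage, out_c, kernel, stride=(1, 1), groups=1, bias=True):
        kh, kw = kernel
        layer = nn.Conv2d(self.c, out_c, (kh, kw), stride=stride, groups=groups,
                          bias=bias, rng=self.rng, name=stage)
        self.layers.append(layer)
        self._advance(stage, kh, kw, *stride)
        self.c = out_c
        self.trace.append((stage, (self.c, self.h, self.w)))

    def pool(self, stage, kernel, stride=None, kind="avg"):
        cls = nn.AvgPool2d if kind == "avg" else nn.MaxPool2d
        layer = cls(kernel, stride)
        self.layers.append(layer)
        stride = stride or kernel
        self._advance(stage, kernel[0], kernel[1], stride[0], stride[1])
        self.trace.append((stage, (self.c, self.h, self.w)))

    def add(self, layer):
        self.layers.append(layer)


def _clip(nominal: int, extent: int) -> int:
    return max(1, min(nominal, extent))


def _build_eegnet_se(spec: ModelSpec, rng) -> _Tracer:
    t = _Tracer(spec, rng)
    f1 = spec.n_temporal_filters
    f2 = f1 * spec.depth_multiplier
    kf, kt = spec.separable_kernel
    if spec.swap_separable_axes:
        kf, kt = kt, kf
    t.conv("temporal_conv", f1, (1, t.clip_w(spec.temporal_kernel)), bias=False)
    t.add(nn.BatchNorm2d(f1, name="bn1"))
    t.conv("depthwise_freq_conv", f2, (t.clip_h(3), 1), groups=f1, bias=False)
    t.add(nn.BatchNorm2d(f2, name="bn2"))
    t.add(nn.ELU())
    p1 = _clip(8, max(1, t.w // 4)) if t.adaptive else 8
    t.pool("avgpool1", (1, p1))
    t.add(nn.Dropout(spec.dropout_rate))
    t.conv("separable_depthwise", f2, (t.clip_h(kf), t.clip_w(kt)),
           groups=f2, bias=False)
    t.conv("separable_pointwise", f2, (1, 1), bias=False)
    t.add(nn.BatchNorm2d(f2, name="bn3"))
    t.add(nn.ELU())
    t.add(nn.SEBlock(f2, spec.se_reduction, rng=rng))
    p2 = _clip(8, t.w) if t.adaptive else 8
    t.pool("avgpool2", (1, p2))
    t.add(nn.Dropout(spec.dropout_rate))
    t.add(nn.Flatten())
    t.add(nn.Linear(t.c * t.h * t.w, spec.n_classes, rng=rng, name="head", init="zero"))
    t.trace.append(("head", (spec.n_classes, 1, 1)))
    return t


def _build_shallow_convnet(spec: ModelSpec, rng) -> _Tracer:
    t = _Tracer(spec, rng)
    stride = spec.shallow_time_stride if t.w >= spec.long_input_threshold else 1
    t.conv("temporal_conv", spec.shallow_filters,
           (1, t.clip_w(spec.shallow_temporal_kernel)), stride=(1, stride))
    # depthwise convolution covering the entire frequency extent
    t.conv("full_freq_depthwise", spec.shallow_filters, (t.h, 1),
           groups=spec.shallow_filters, bias=False)
    t.add(nn.BatchNorm2d(spec.shallow_filters, name="bn"))
    t.add(nn.Square())
    pool_len = _clip(75, max(1, t.w // 8)) if t.adaptive else 75
    pool_stride = max(1, pool_len // 5)
    t.pool("time_avgpool", (1, pool_len), stride=(1, pool_stride))
    t.add(nn.SafeLog())
    t.add(nn.Dropout(spec.dropout_rate))
    t.add(nn.Flatten())
    t.add(nn.Linear(t.c * t.h * t.w, spec.n_classes, rng=rng, name="head", init="zero"))
    t.trace.append(("head", (spec.n_classes, 1, 1)))
    return t


def _build_alexnet_baseline(spec: ModelSpec, rng) -> _Tracer:
    t = _Tracer(spec, rng)
    stride1 = 4 if t.w >= 512 else 1
    t.conv("conv1", 32, (t.clip_h(5), t.clip_w(11)), stride=(1, stride1))
    t.add(nn.ReLU())
    t.pool("maxpool1", (t.clip_h(2), t.clip_w(3)), kind="max")
    t.conv("conv2", 64, (t.clip_h(3), t.clip_w(5)))
    t.add(nn.ReLU())
    t.pool("maxpool2", (t.clip_h(2), t.clip_w(3)), kind="max")
    t.conv("conv3", 96, (t.clip_h(3), t.clip_w(3)))
    t.add(nn.ReLU())
    t.conv("conv4", 96, (t.clip_h(3), t.clip_w(3)))
    t.add(nn.ReLU())
    t.conv("conv5", 64, (t.clip_h(3), t.clip_w(3)))
    t.add(nn.ReLU())
    t.pool("maxpool3", (t.clip_h(2), t.clip_w(3)), kind="max")
    t.add(nn.Flatten())
    t.add(nn.Linear(t.c * t.h * t.w, 256, rng=rng, name="fc1"))
    t.add(nn.ReLU())
    t.add(nn.Dropout(spec.dropout_rate))
    t.add(nn.Linear(256, spec.n_classes, rng=rng, name="head", init="zero"))
    t.trace.append(("head", (spec.n_classes, 1, 1)))
    return t


_BUILDERS = {
    "eegnet_se": _build_eegnet_se,
    "shallow_convnet": _build_shallow_convnet,
    "alexnet_baseline": _build_alexnet_baseline,
}


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Construct a classifier for ``spec``; raises ConstructionError naming
    the offending stage when the input geometry is too small for the chain."""
    rng = np.random.default_rng(seed)
    tracer = _BUILDERS[spec.architecture](spec, rng)
    return Model(nn.Sequential(tracer.layers), spec, tracer.trace)


def count_parameters(model: Model) -> int:
    """Total trainable scalar count."""
    return int(sum(p.data.size for p in model.params()))
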