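"""Filtering, segmentation, and normalization of raw EEG.

The preprocessing recipe: a 4th-order Butterworth 1–50 Hz band-pass applied
forward-backward (zero phase), segmentation into fixed 10-second blocks with
zero padding of the trailing remainder, and Z-score normalization of the
resulting feature maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synth import EEGRecord

__all__ = [
    "FilterSpec",
    "Block",
    "design_bandpass",
    "apply_zero_phase",
    "segment",
    "zscore",
]

EPS_GUARD = 1e-8


@dataclass(frozen=True)
class FilterSpec:
    """Discretized Butterworth band-pass design (second-order sections).

    ``order`` follows the lowpass-prototype convention: the realized
    band-pass has 2 x order poles.  ``center_rad`` is the geometric center
    angular frequency sqrt(w1*w2); ``bandwidth_rad`` = w2 - w1.
    """

    sos: np.ndarray
    low_hz: float
    high_hz: float
    order: int
    fs: float

    @property
    def center_rad(self) -> float:
        w1 = 2 * np.pi * self.low_hz
        w2 = 2 * np.pi * self.high_hz
        return float(np.sqrt(w1 * w2))

    @property
    def bandwidth_rad(self) -> float:
        return float(2 * np.pi * (self.high_hz - self.low_hz))

    def gain_at(self, freq_hz: float) -> float:
        """Single-pass magnitude response at ``freq_hz`` (response oracle)."""
        _, h = signal.sosfreqz(self.sos, worN=[2 * np.pi * freq_hz / self.fs])
        return float(np.abs(h[0]))


@dataclass
class Block:
    """One fixed-length segment of a record, zero-padded if needed."""

    data: np.ndarray  # (n_channels, block_samples)
    fs: float
    pad_samples: int = 0
    source: tuple[str, int] = ("", 0)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def design_bandpass(
    low_hz: float = 1.0, high_hz: float = 50.0, order: int = 4, fs: float = 256.0
) -> FilterSpec:
    """Design the Butterworth band-pass (bilinear discretization, SOS form).

    Maximally flat in the passband; monotone decay in each stopband.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({fs / 2})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return FilterSpec(sos=sos, low_hz=low_hz, high_hz=high_hz, order=order, fs=fs)


def _min_samples(spec: FilterSpec) -> int:
    # sosfiltfilt default padding contract
    return 3 * (2 * spec.sos.shape[0] + 1 - min((spec.sos[:, 2] == 0).sum(),
                                                (spec.sos[:, 5] == 0).sum())) + 1


def apply_zero_phase(spec: FilterSpec, record: EEGRecord) -> EEGRecord:
    """Forward-backward (zero-phase) filtering of every channel.

    The effective magnitude response is |H|^2 and the group delay is zero.
    """
    if record.n_samples <= _min_samples(spec):
        raise ValueError(
            f"record too short for zero-phase filtering: {record.n_samples} samples, "
            f"need > {_min_samples(spec)}"
        )
    filtered = signal.sosfiltfilt(spec.sos, record.data, axis=-1)
    return replace(record, data=filtered, channel_names=list(record.channel_names))


def segment(record: EEGRecord, block_s: float = 10.0) -> list[Block]:
    """Cut a record into ceil(n/block) fixed-length blocks, zero-padding the last.

    Concatenating the blocks and trimming the pad reconstructs the input.
    """
    if not block_s > 0:
        raise ValueError("block_s must be > 0")
    if record.n_samples < 1:
        raise ValueError("record is empty")
    block_samples = int(round(block_s * record.fs))
    n_blocks = -(-record.n_samples // block_samples)  # ceil
    blocks = []
    for i in range(n_blocks):
        chunk = record.data[:, i * block_samples : (i + 1) * block_samples]
        pad = block_samples - chunk.shape[1]
        if pad:
            chunk = np.pad(chunk, ((0, 0), (0, pad)))
        blocks.append(
            Block(data=chunk, fs=record.fs, pad_samples=pad,
                  source=(record.subject_id, i))
        )
    return blocks


def zscore(x: np.ndarray, eps: float = EPS_GUARD) -> np.ndarray:
    """Z-score over the whole array: mean 0, SD 1.

    A constant (zero-SD) input maps to all zeros via the epsilon guard.
    Normalization grouping (per block, per channel) is the caller's choice:
    pass the slice to normalize.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    sd = x.std()
    if sd < eps:
        return np.zeros_like(x)
    return (x - x.mean()) / sd
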