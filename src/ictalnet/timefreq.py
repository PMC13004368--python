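"""Time-frequency transforms: CWT scalograms and STFT spectrograms.

Default geometry for a 10-second, 256 Hz block (2560 samples):

* CWT, complex Morlet cmor1.5-1.0, integer scales 3..24 -> (n_channels, 22, 2560)
  = 56,320 features per channel per block.
* STFT, Hann window, nperseg=128, noverlap=64, nfft=256 -> (n_channels, 129, 39)
  = 5,031 features per channel per block.

With center frequency fc = 1.0 and fs = 256 Hz the scale grid 3..24 covers
approximately 10.7–85.3 Hz (f = fc*fs/scale); see docs/methods.md for why
this differs from a nominal 1–50 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .preprocess import Block

__all__ = [
    "TFMap",
    "DEFAULT_SCALES",
    "DEFAULT_WAVELET",
    "cwt_transform",
    "stft_transform",
    "scale_to_frequency",
    "feature_count",
]

DEFAULT_WAVELET = "cmor1.5-1.0"
DEFAULT_SCALES = np.arange(3, 25)  # 22 integer scales, 3..24 inclusive


@dataclass
class TFMap:
    """Per-block time-frequency feature array with axis calibration.

    ``values`` has shape (n_channels, n_freq, n_time).  ``freq_axis`` gives
    the Hz value of each row (for CWT, the pseudo-frequency of each scale);
    ``time_axis`` the second value of each column.
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def scale_to_frequency(scale: float, wavelet: str = DEFAULT_WAVELET, fs: float = 256.0) -> float:
    """Pseudo-frequency in Hz of a CWT scale: f = fc * fs / scale."""
    if not np.all(np.asarray(scale) > 0):
        raise ValueError("scale must be positive")
    return float(pywt.scale2frequency(wavelet, scale) * fs)


def cwt_transform(
    block: Block,
    scales: np.ndarray | None = None,
    wavelet: str = DEFAULT_WAVELET,
    keep_phase: bool = False,
) -> TFMap:
    """Continuous wavelet transform of every channel; modulus scalogram.

    Channels are transformed one at a time to keep the complex intermediate
    small.  Each channel is mean-subtracted first so the zero-mean wavelet
    annihilates constant signals exactly (otherwise boundary effects leak a
    DC response at the block edges).  ``keep_phase=True`` returns the complex
    coefficients instead of the modulus (off by default: the classifiers take
    real-valued maps).
    """
    if scales is None:
        scales = DEFAULT_SCALES
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0:
        raise ValueError("scale list is empty")
    if np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly positive and increasing")
    n_ch, n_t = block.data.shape
    dtype = np.complex64 if keep_phase else np.float32
    values = np.empty((n_ch, scales.size, n_t), dtype=dtype)
    for c in range(n_ch):
        x = block.data[c] - block.data[c].mean()
        coef, freqs = pywt.cwt(
            x, scales, wavelet, sampling_period=1.0 / block.fs, method="fft"
        )
        values[c] = coef if keep_phase else np.abs(coef)
    return TFMap(
        values=values,
        freq_axis=np.asarray(freqs, dtype=float),
        time_axis=np.arange(n_t) / block.fs,
        method="cwt",
        params={"wavelet": wavelet, "scales": scales.tolist(), "fs": block.fs},
    )


def stft_transform(
    block: Block,
    nperseg: int = 128,
    noverlap: int = 64,
    nfft: int = 256,
    window: str = "hann",
) -> TFMap:
    """Magnitude spectrogram via the short-time Fourier transform.

    One-sided spectrum (nfft/2 + 1 bins); frame count is
    1 + floor((n_samples - nperseg) / (nperseg - noverlap)).
    """
    if not (noverlap < nperseg <= nfft):
        raise ValueError("need noverlap < nperseg <= nfft")
    if block.n_samples < nperseg:
        raise ValueError(
            f"block has {block.n_samples} samples, shorter than nperseg={nperseg}"
        )
    freqs, times, zxx = signal.stft(
        block.data,
        fs=block.fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        boundary=None,
        padded=False,
        axis=-1,
    )
    return TFMap(
        values=np.abs(zxx).astype(np.float32),
        freq_axis=np.asarray(freqs, dtype=float),
        time_axis=np.asarray(times, dtype=float),
        method="stft",
        params={
            "nperseg": nperseg,
            "noverlap": noverlap,
            "nfft": nfft,
            "window": window,
            "fs": block.fs,
        },
    )


def feature_count(tfmap: TFMap) -> int:
    """Features per channel per block: n_freq x n_time."""
    _, n_freq, n_time = tfmap.shape
    return int(n_freq) * int(n_time)


def save_tfmap(tfmap: TFMap, path) -> None:
    """Persist values as .npy with a JSON sidecar carrying axis calibration."""
    import json
    from pathlib import Path

    path = Path(path)
    np.save(path, tfmap.values)
    sidecar = {
        "method": tfmap.method,
        "freq_axis": tfmap.freq_axis.tolist(),
        "time_axis": tfmap.time_axis.tolist(),
        "params": tfmap.params,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_tfmap(path) -> TFMap:
    import json
    from pathlib import Path

    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return TFMap(
        values=values,
        freq_axis=np.asarray(sidecar["freq_axis"]),
        time_axis=np.asarray(sidecar["time_axis"]),
        method=sidecar["method"],
        params=sidecar["params"],
    )
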