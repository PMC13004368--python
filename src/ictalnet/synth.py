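"""Synthetic multichannel scalp-EEG generator.

Produces labeled 10-second blocks that mimic the statistical structure a
seizure-detection pipeline relies on: a 1/f (pink) background with a
band-limited alpha-range rhythm for the "normal" class, and the same
background with injected epileptiform transients — spikes, sharp waves,
spike-and-slow complexes, and high-frequency paroxysmal bursts — for the
"abnormal" class.  The generator replaces clinical recordings in every test;
it makes no claim of physiological realism beyond the spectral/amplitude
features the classifiers exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EEGRecord",
    "EventSpec",
    "EVENT_KINDS",
    "generate_background",
    "inject_events",
    "make_labeled_dataset",
    "write_dataset",
]

EVENT_KINDS = ("spike", "sharp", "spike_and_slow", "hf_paroxysm")

#: Clinical-morphology template widths in seconds (config-exposed defaults).
SPIKE_WIDTH_S = (0.020, 0.070)
SHARP_WIDTH_S = (0.070, 0.200)
SLOW_WAVE_HZ = (2.5, 4.0)
HF_BAND_HZ = (20.0, 50.0)


@dataclass
class EEGRecord:
    """Multichannel time-domain EEG segment (microvolt scale)."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    subject_id: str = ""
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a (n_channels, n_samples) array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"CH{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EventSpec:
    """One epileptiform transient to inject into a record.

    ``amplitude_gain`` scales the template relative to the per-channel
    background standard deviation, so gain 10 means a ~10-sigma transient.
    """

    kind: str
    onset_s: float
    duration_s: float
    amplitude_gain: float = 6.0
    channels: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; one of {EVENT_KINDS}")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not self.amplitude_gain > 0:
            raise ValueError("amplitude_gain must be > 0")
        if len(self.channels) == 0:
            raise ValueError("channels must be non-empty")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """1/f-power noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    # amplitude ~ f^-1/2 gives 1/f power; kill DC so the background is zero-mean
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5
    pink = np.fft.irfft(spectrum * shaping, n=n_samples, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True)
    return pink


def generate_background(
    n_channels: int,
    duration_s: float,
    fs: float,
    seed: int = 0,
    alpha_snr: float = 1.0,
    amplitude_uv: float = 20.0,
    subject_id: str = "",
) -> EEGRecord:
    """Generate interictal-like background: pink noise plus an alpha rhythm.

    Each channel receives unit-variance pink noise and a sinusoid with a
    random frequency in the 8–12 Hz alpha band and random phase, scaled so
    that its RMS relative to the noise equals ``alpha_snr``.  The result is
    scaled to ``amplitude_uv`` microvolts RMS.  Deterministic for a fixed
    seed.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    if not fs > 0:
        raise ValueError("fs must be > 0")
    n_samples = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    noise = _pink_noise(rng, n_channels, n_samples)
    t = np.arange(n_samples) / fs
    f_alpha = rng.uniform(8.0, 12.0, size=(n_channels, 1))
    phase = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
    alpha = np.sqrt(2.0) * np.sin(2 * np.pi * f_alpha * t + phase)  # unit RMS
    data = noise + alpha_snr * alpha
    data *= amplitude_uv / data.std(axis=-1, keepdims=True)
    return EEGRecord(data=data, fs=fs, subject_id=subject_id)


def _event_template(kind: str, duration_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-peak waveform for one event kind, sampled at fs."""
    n = max(2, int(round(duration_s * fs)))
    t = np.arange(n) / fs
    if kind in ("spike", "sharp"):
        # biphasic transient: one full sine period across the event
        return np.sin(2 * np.pi * t / duration_s)
    if kind == "spike_and_slow":
        # narrow spike followed by a slow half-wave at 2.5–4 Hz
        f_slow = rng.uniform(*SLOW_WAVE_HZ)
        spike_w = min(rng.uniform(*SPIKE_WIDTH_S), duration_s / 2)
        out = np.zeros(n)
        n_spike = max(2, int(round(spike_w * fs)))
        out[:n_spike] = np.sin(2 * np.pi * np.arange(n_spike) / n_spike)
        n_slow = min(n - n_spike, int(round(fs / (2 * f_slow))))
        if n_slow > 1:
            out[n_spike : n_spike + n_slow] = -0.8 * np.sin(
                np.pi * np.arange(n_slow) / n_slow
            )
        return out
    if kind == "hf_paroxysm":
        # high-frequency burst; carrier chirps downward within 20–50 Hz,
        # mirroring the high-to-low frequency evolution of paroxysmal rhythms
        f_hi = rng.uniform(35.0, HF_BAND_HZ[1])
        f_lo = rng.uniform(HF_BAND_HZ[0], 35.0)
        inst_f = f_hi + (f_lo - f_hi) * t / t[-1]
        phase = 2 * np.pi * np.cumsum(inst_f) / fs
        envelope = np.hanning(n)
        return envelope * np.sin(phase)
    raise ValueError(f"unknown event kind {kind!r}")


def inject_events(record: EEGRecord, events: list[EventSpec], seed: int = 0) -> EEGRecord:
    """Return a copy of ``record`` with event templates added.

    Template amplitude = event.amplitude_gain x the per-channel background
    standard deviation.  Samples outside every event window are unchanged.
    Raises if any event extends past the end of the record.
    """
    rng = np.random.default_rng(seed)
    data = record.data.copy()
    n = record.n_samples
    for ev in events:
        start = int(round(ev.onset_s * record.fs))
        template = _event_template(ev.kind, ev.duration_s, record.fs, rng)
        stop = start + template.size
        if stop > n:
            raise ValueError(
                f"event {ev.kind} at {ev.onset_s}s (+{ev.duration_s}s) extends "
                f"past record end ({record.duration_s}s)"
            )
        for ch in ev.channels:
            amp = ev.amplitude_gain * record.data[ch].std()
            data[ch, start:stop] += amp * template
    return replace(record, data=data, channel_names=list(record.channel_names))


def _random_events(
    rng: np.random.Generator,
    n_channels: int,
    block_s: float,
    amplitude_gain: float,
) -> list[EventSpec]:
    """Event mix for one abnormal block: >=1 hf_paroxysm plus 0-2 transients."""
    events: list[EventSpec] = []
    n_ch_hit = max(1, n_channels // 2)
    channels = tuple(int(c) for c in rng.choice(n_channels, size=n_ch_hit, replace=False))
    dur = float(rng.uniform(1.0, min(3.0, block_s / 2)))
    onset = float(rng.uniform(0, block_s - dur))
    events.append(
        EventSpec("hf_paroxysm", onset, dur, amplitude_gain, channels)
    )
    for _ in range(rng.integers(0, 3)):
        kind = str(rng.choice(["spike", "sharp", "spike_and_slow"]))
        if kind == "spike":
            dur = float(rng.uniform(*SPIKE_WIDTH_S))
        elif kind == "sharp":
            dur = float(rng.uniform(*SHARP_WIDTH_S))
        else:
            dur = float(rng.uniform(0.25, 0.5))
        onset = float(rng.uniform(0, block_s - dur))
        chans = tuple(
            int(c) for c in rng.choice(n_channels, size=max(1, n_channels // 3), replace=False)
        )
        events.append(EventSpec(kind, onset, dur, amplitude_gain, chans))
    return events


def make_labeled_dataset(
    n_normal: int,
    n_abnormal: int,
    block_s: float = 10.0,
    fs: float = 256.0,
    seed: int = 0,
    n_channels: int = 23,
    n_subjects: int = 23,
    amplitude_gain: float = 6.0,
    alpha_snr: float = 1.0,
) -> tuple[list[EEGRecord], np.ndarray, list[str]]:
    """Generate labeled blocks: ``n_normal`` clean + ``n_abnormal`` with events.

    Returns (blocks, labels, subject_ids) where labels[i] = 1 marks an
    abnormal block (>=1 injected event, always including a 20–50 Hz
    paroxysmal burst).  Subject IDs are drawn round-robin from a pool of
    ``n_subjects`` synthetic subjects so subject-independent splits are
    testable.  Fully deterministic for a fixed seed.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("block counts must be non-negative")
    if n_normal + n_abnormal < 1:
        raise ValueError("at least one block must be requested")
    rng = np.random.default_rng(seed)
    blocks: list[EEGRecord] = []
    labels = np.concatenate(
        [np.zeros(n_normal, dtype=np.int64), np.ones(n_abnormal, dtype=np.int64)]
    )
    subject_pool = [f"subj{i:02d}" for i in range(n_subjects)]
    subject_ids = [subject_pool[i % n_subjects] for i in range(n_normal + n_abnormal)]
    for i, label in enumerate(labels):
        block_seed = int(rng.integers(0, 2**31 - 1))
        rec = generate_background(
            n_channels, block_s, fs, seed=block_seed,
            alpha_snr=alpha_snr, subject_id=subject_ids[i],
        )
        if label == 1:
            ev_rng = np.random.default_rng(block_seed + 1)
            events = _random_events(ev_rng, n_channels, block_s, amplitude_gain)
            rec = inject_events(rec, events, seed=block_seed + 2)
        blocks.append(rec)
    return blocks, labels, subject_ids


def write_dataset(
    out_dir,
    blocks: list[EEGRecord],
    labels: np.ndarray,
    subject_ids: list[str],
) -> None:
    """Persist blocks as one .npy per block plus a CSV manifest."""
    import csv
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["block_id", "subject_id", "label", "fs", "path"])
        for i, (rec, label, subj) in enumerate(zip(blocks, labels, subject_ids)):
            name = f"block{i:05d}.npy"
            np.save(out / name, rec.data)
            writer.writerow([i, subj, int(label), rec.fs, name])
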