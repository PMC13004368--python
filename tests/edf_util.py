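"""Minimal EDF writer for round-trip fixtures (synthetic test data only).

Writes a spec-compliant 16-bit European Data Format file: one 256-byte main
header, 256 bytes of per-signal header fields, then little-endian int16
sample records.  Only what the round-trip tests need; not a general exporter.
"""

import numpy as np


def _field(text, width):
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data, fs, channel_names=None, record_s=1.0):
    """Write (n_channels, n_samples) microvolt data at integer rate ``fs``."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(round(fs * record_s))  # samples per record per signal
    n_rec = n_samp // spr
    data = data[:, : n_rec * spr]
    if channel_names is None:
        channel_names = [f"CH{i}" for i in range(n_ch)]
    phys_min = float(np.floor(data.min() - 1))
    phys_max = float(np.ceil(data.max() + 1))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field("synthetic test subject", 80),
        _field("synthetic test recording", 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(256 * (n_ch + 1), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field(record_s, 8),
        _field(n_ch, 4),
    ])
    sig = b"".join(
        b"".join(_field(v, w) for v in vals)
        for vals, w in [
            (channel_names, 16),
            ([""] * n_ch, 80),
            (["uV"] * n_ch, 8),
            ([phys_min] * n_ch, 8),
            ([phys_max] * n_ch, 8),
            ([dig_min] * n_ch, 8),
            ([dig_max] * n_ch, 8),
            ([""] * n_ch, 80),
            ([spr] * n_ch, 8),
            ([""] * n_ch, 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())
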