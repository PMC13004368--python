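"""Figure helpers: normal-vs-abnormal time-frequency panels and confusion
heat maps.  Decorative output for reports; not exercised by the test suite."""

from __future__ import annotations

import numpy as np


def tf_comparison_panel(normal_map, abnormal_map, channel: int = 0, out_path=None):
    """Side-by-side scalogram/spectrogram panels for one channel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, m, title in zip(axes, (normal_map, abnormal_map), ("normal", "abnormal")):
        ax.pcolormesh(m.time_axis, m.freq_axis, m.values[channel], shading="auto")
        ax.set_title(f"{m.method.upper()} — {title}")
        ax.set_xlabel("time (s)")
    axes[0].set_ylabel("frequency (Hz)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig


def confusion_heatmap(counts, out_path=None):
    """2x2 confusion-matrix heat map (rows: true, columns: predicted)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = counts.as_matrix()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["normal", "abnormal"])
    ax.set_yticks([0, 1], ["normal", "abnormal"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
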