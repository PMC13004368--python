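import numpy as np
import pytest

from ictalnet.dataset import LabeledDataset
from ictalnet.preprocess import Block, apply_zero_phase, design_bandpass, segment, zscore
from ictalnet.synth import make_labeled_dataset
from ictalnet.timefreq import TFMap, stft_transform


def featurize_blocks(blocks, labels, subjects, method="stft", block_s=10.0):
    """Shared helper: filter -> segment -> transform -> per-channel z-score."""
    from ictalnet.timefreq import cwt_transform

    spec = design_bandpass(1, 50, 4, blocks[0].fs)
    transform = cwt_transform if method == "cwt" else stft_transform
    maps = []
    for rec in blocks:
        filtered = apply_zero_phase(spec, rec)
        for b in segment(filtered, block_s):
            m = transform(b)
            for c in range(m.values.shape[0]):
                m.values[c] = zscore(m.values[c]).astype(m.values.dtype)
            maps.append(m)
    return maps


@pytest.fixture(scope="session")
def stft_dataset():
    """Small, fast labeled dataset of spectrogram maps (4 EEG channels)."""
    blocks, labels, subjects = make_labeled_dataset(
        36, 18, 10, 256, seed=5, n_channels=4, amplitude_gain=10.0
    )
    maps = featurize_blocks(blocks, labels, subjects, method="stft")
    return LabeledDataset(maps, labels, subjects)


@pytest.fixture
def toy_maps():
    """Ten tiny random TFMaps for bookkeeping-level dataset tests."""
    rng = np.random.default_rng(0)
    maps = []
    for _ in range(10):
        maps.append(
            TFMap(
                values=rng.random((1, 4, 6)).astype(np.float32),
                freq_axis=np.arange(4.0),
                time_axis=np.arange(6.0),
                method="stft",
                params={},
            )
        )
    return maps


@pytest.fixture
def noise_block():
    rng = np.random.default_rng(7)
    return Block(data=rng.standard_normal((4, 2560)), fs=256.0)
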