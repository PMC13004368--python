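# Methods

## Problem and model

`ictalnet` classifies fixed 10-second blocks of multichannel scalp EEG as
*normal* or *abnormal* (containing epileptiform discharge activity). Blocks
are represented as two-dimensional time–frequency maps — scalograms or
spectrograms — stacked over EEG channels, and classified by compact
convolutional networks. The package treats the EEG channel axis as the
convolutional channel dimension, so no montage-specific spatial layout is
assumed.

## Synthetic EEG generator

The generator produces the statistical contrast the classifiers rely on,
not physiologically realistic EEG:

* **Background** (normal class): per-channel pink noise (1/f power, DC
  removed, unit variance) plus a band-limited alpha-range sinusoid
  (frequency ~ U(8, 12) Hz, random phase) at a configurable
  oscillation-to-noise RMS ratio (default 1.0), scaled to 20 µV RMS.
* **Events** (abnormal class): biphasic spikes (20–70 ms), sharp waves
  (70–200 ms), spike-and-slow complexes (narrow spike followed by a
  2.5–4 Hz slow half-wave), and high-frequency paroxysmal bursts (Hann
  envelope, carrier chirping downward inside 20–50 Hz, mirroring the
  high-to-low frequency evolution of seizure rhythms). Event amplitude is
  expressed as a gain on the per-channel background SD (default 6). Every
  abnormal block receives at least one paroxysmal burst, plus up to two
  additional transients, on a random half of the channels.

Template widths and rates are engineering defaults — clinical literature
names these waveform classes but standard morphology fixes only the duration
ranges above. Because events are added to an otherwise untouched background,
label soundness is checkable: 20–50 Hz band power over an event window
strictly exceeds that of the seed-matched event-free background.

What the generator does **not** emulate: inter-channel propagation
structure, artifact classes (EMG, ocular, electrode pop), non-stationary
background drift, or realistic seizure evolution. Passing the test suite
therefore demonstrates the pipeline's correctness and trainability, not
clinical-grade detection performance.

## Preprocessing

1–50 Hz 4th-order Butterworth band-pass (scipy SOS design, bilinear
discretization), applied with `sosfiltfilt` so the effective response is
|H|² with zero group delay. The passband gain at 25 Hz is 0.9995; DC is
removed exactly. Segmentation zero-pads the trailing block. Z-score
normalization is applied **per block and per channel on the time–frequency
map** (mean 0, SD 1, with a 10⁻⁸ guard mapping constant inputs to zeros).
Per-block normalization is self-contained, so no statistics leak across
folds; a train-fold-statistics mode was considered and rejected because the
per-block variant makes every block independent of the split.

## Time–frequency features

* **CWT**: complex Morlet `cmor1.5-1.0`, integer scales 3–24 (22 scales),
  modulus. Each channel is mean-subtracted before the transform so the
  zero-mean wavelet annihilates constants exactly (edge effects otherwise
  leak a DC response). With center frequency f_c = 1.0 and f_s = 256 Hz the
  pseudo-frequency map f = f_c·f_s/scale places the grid at ≈ 10.7–85.3 Hz.
  A nominal 1–50 Hz interpretation of this scale range circulates in the
  application literature but is inconsistent with the standard mapping; the
  implementation reports the standard pseudo-frequencies and does not
  rescale. Phase retention is available (`keep_phase=True`) but off by
  default since the classifiers take real-valued maps.
* **STFT**: Hann window, `nperseg=128`, `noverlap=64`, `nfft=256`,
  one-sided magnitude (not power). Frame count obeys
  1 + ⌊(L − 128)/64⌋, verified against brute-force frame counting.

## Class balance and augmentation

SMOTE oversamples whichever class is deficient relative to the 2:1
normal:abnormal target: a synthetic map is p₁ + λ(p₂ − p₁) with λ ~ U(0, 1)
and p₂ one of the k = 5 nearest same-class neighbours in flattened-map
space. Augmentation is class-conditional: Gaussian noise (σ = 0.05 × map
SD) and amplitude scaling (U(0.8, 1.2)) on abnormal maps, ±10 % time
shifting with zero fill on normal maps.

Inside cross-validation the default order is *split first, then balance and
augment the training side only*, so no interpolated or augmented item can
reach a test fold (asserted at run time). The alternative
balance-before-split order is available as `balance_before_split=True` for
comparison; it risks leakage through interpolated samples and is not the
default. In small training folds k adapts to the minority size
(k = min(5, n_minority − 1)); balancing is skipped if interpolation is
impossible.

## Architectures

All heads are sized by composing O = ⌊(I − K + 2P)/S⌋ + 1 along the layer
chain; nominal kernels and pool lengths are clipped to the current
feature-map extent (dynamic dimension adaptation), so each architecture
builds unchanged for both the (22, 2560) scalogram and (129, 39)
spectrogram geometries. Setting `adaptive_kernels=False` disables clipping,
in which case an undersized input raises a construction error naming the
offending stage.

Defaults where no published value exists (all exposed on `ModelSpec`):

* `eegnet_se`: 16 temporal filters, depth multiplier 2, temporal kernel 16,
  separable kernel (3, 16) — 3 on the frequency/scale axis, 16 on time (the
  orientation is swappable via `swap_separable_axes`, since the two
  conventions conflict in the application literature); average pools of
  length min(8, T/4) and 8 along time; SE reduction 8; dropout 0.5.
* `shallow_convnet`: 16 filters, temporal kernel 25 with temporal stride 4
  when the time axis is ≥ 1000 samples (2560-sample scalograms are
  decimated to 634 frames; spectrograms keep stride 1); the second-layer
  depthwise convolution spans the full frequency extent; square →
  average-pool (length min(75, T/8), stride length/5) → log; dropout 0.5.
* `alexnet_baseline`: five convolutions (32→64→96→96→64 filters) with the
  first layer accepting the EEG channel count directly rather than resizing
  maps to an image geometry (resizing would distort the axis calibration);
  max pooling; a 256-unit fully connected layer.

Classification heads are zero-initialized: logits start at zero (maximum-
entropy softmax), which avoids saturated focal losses at initialization and
markedly accelerates convergence in short training budgets. Batch norm uses
ε = 10⁻⁵, momentum 0.1. The backward pass of the first convolution skips
the input-gradient computation (nothing below it needs gradients), which
removes the single most expensive operation per step.

## Training

Focal loss FL(P_t) = −α_t (1 − P_t)^γ log(P_t) with α = 0.6 on the abnormal
class (1 − α on normal) and γ = 2.0; probabilities clamped at 10⁻⁷; mean
reduction; gradients derived analytically through the two-class softmax and
verified against finite differences. AdamW (decoupled weight decay) at
lr 5·10⁻⁴, weight decay 10⁻³, β = (0.9, 0.999); global gradient-norm
clipping at 1.0; at most 20 epochs per fold. Early stopping monitors
validation loss (a held-out 10 % of the training fold — the test fold stays
untouched) with patience 8; the learning rate is multiplied by 0.3 after a
3-epoch plateau. The best-validation weights are restored at the end.
"Performance improvement" is defined as a strict decrease of the monitored
loss; monitoring training loss instead is a config option. Batch size
defaults to 32; the scaled cross-validation benchmark uses 16 so that its
~150-item training folds still yield ≈ 10 updates per epoch.

The decision threshold is chosen by grid search (step 0.01) over
[0.3, 0.7] on the training fold's validation split — maximizing F1 by
default (balanced accuracy and Youden's J are selectable), ties broken
toward 0.5 — and frozen before the test fold is scored.

## Evaluation

Accuracy (TP+TN)/N, recall TP/(TP+FN), precision TP/(TP+FP); the abnormal
class is positive. Zero-denominator metrics are flagged undefined and
excluded from aggregation with a warning and a drop count. Fold aggregation
reports the arithmetic mean and sample SD (ddof = 1).

## Problem sizes in the tests

The scaled cross-validation benchmark uses 210 ten-second blocks (140
normal, 70 abnormal — already at the 2:1 ratio), 4 EEG channels, event gain
10 ("high-SNR": a linear oracle on peak-pooled features verifies
separability before the networks are scored), CWT features, ShallowConvNet,
5-fold CV at 5 epochs per fold. Four channels keep the in-memory scalogram
tensor near 2 GB; the channel count only scales the convolutional fan-in,
so the pipeline logic exercised is identical to the 23-channel
configuration, which the shape and geometry tests cover separately. Unit
tests use small spectrogram datasets (4 channels, 54 blocks) and toy maps.

## Known limitations

* The numpy engine is CPU-only and single-threaded apart from BLAS; it is
  meant for tests and small studies, not full-scale clinical training runs.
* The synthetic benchmark's accuracies say nothing about performance on
  clinical recordings (see generator limitations above).
* EDF ingestion resamples to 256 Hz and preserves channel names but
  performs no artifact rejection, re-referencing, or notch filtering —
  none are part of the preprocessing recipe.
* Subject-independent evaluation on synthetic data is structurally honest
  (no subject overlap) but synthetic "subjects" differ only by random seed,
  not by the physiological inter-individual variability that makes the
  clinical version of the split hard.
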