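# Methods

## The model

`ictal2d` implements a five-part seizure-detection pipeline for EEG:

1. **Decomposition.** A record is cut into fixed-length slices by a
   sliding window with configurable overlap (default 50%). The slice is
   the unit of classification. A slice is labeled *seizure* when the
   fraction of its span covered by annotated seizure intervals reaches a
   containment threshold; the default threshold is 1.0 (the slice must lie
   wholly inside a seizure), which avoids ambiguous boundary slices when
   seizure and non-seizure material are drawn from wholly-ictal and
   wholly-interictal records.
2. **Feature extraction.** Single-channel slices are transformed with the
   continuous wavelet transform at integer scales 1..10 (complex Gaussian
   mother wavelet of order 8, `cgau8`), giving a scale x time magnitude
   scalogram. Multichannel slices are transformed per channel with the
   FFT; magnitudes are averaged into 1 Hz-wide bins over a chosen band,
   giving a channel x frequency map (a 23-channel slice over 1-23 Hz is a
   23x23 map; over 1-46 Hz, 23x46).
3. **2D representation.** Scalograms are rendered as filled-contour
   images; channel x frequency maps are rendered one pixel per cell. Both
   are min-max scaled per image and mapped through a fixed
   perceptually-uniform colormap (viridis) to 3 channels. Optional
   augmentation applies flips and right-angle rotations.
4. **Depth-feature extraction.** Images are bilinearly resized to the
   network's input resolution, scaled to [0,1] and standardized, then fed
   to a compound-scalable MBConv convolutional network. The depth features
   are the pooled penultimate representation (the layer before the
   classification head).
5. **Classification and evaluation.** A softmax head (the network's own),
   KNN, or SVM classifies the depth features. Metrics are accuracy,
   sensitivity, and specificity in percent, from TP/FP/TN/FN with the
   seizure class positive.

## The scalable network

The baseline is the canonical 9-stage design: a 3x3 stem convolution
(stride 2, 32 channels), seven MBConv stages with channels
(16, 24, 40, 80, 112, 192, 320), repeats (1, 2, 2, 3, 3, 4, 1), kernels
(3, 3, 5, 3, 5, 5, 3) and expansion 6 except the first (expansion 1), and
a 1x1 convolution to 1280 channels followed by global average pooling and
a fully-connected head. First-stage strides follow the resolution halving
pattern 224 -> 112 -> 112 -> 56 -> 28 -> 14 -> 14 -> 7 -> 7.

Compound scaling per level multiplies channel counts by a width
coefficient (rounded to the nearest multiple of 8, bumped up one step if
rounding fell below 90% of the unrounded value), multiplies MBConv repeats
by a depth coefficient (rounded up), and sets the input resolution.
Levels 0..7 use (224,1.0,1.0), (240,1.0,1.1), (260,1.1,1.2),
(300,1.2,1.4), (380,1.4,1.8), (456,1.6,2.2), (528,1.8,2.6),
(600,2.0,3.1). Depth scaling is applied to the MBConv stages only; the
stem and head always have one layer (applying the ceiling rule to them
would contradict the one-row head of the architecture table).

MBConv internals follow the reference description: 1x1 expansion, k x k
depthwise convolution, squeeze-excitation with ratio 0.25 of the block's
input channels, 1x1 projection, batch normalization (momentum 0.1, eps
1e-3) after every convolution, swish activations, and a residual
connection when stride is 1 and channel counts match. Stochastic depth is
off.

The network, including training, is implemented on a compact NumPy
reverse-mode autodiff engine written for this package (im2col
convolutions with a precomputed sparse scatter matrix for the backward
col2im, hand-derived batch-norm and cross-entropy gradients). Every
primitive's gradient is pinned against central finite differences in the
test suite. All arithmetic is float32 and fully deterministic given the
seeds, which is what makes the reproducibility contracts (identical
histories for identical seeds) exact rather than approximate.

### The tiny preset

`ScalingConfig.tiny()` (resolution 64, width 0.35, depth 0.5) exists so
end-to-end training runs on one CPU in minutes; it is a desk-scale testing
configuration, not one of the published variants. Sub-unit coefficients
are otherwise rejected; the preset opts in explicitly.

### Training defaults

Cross-entropy, Adam (lr 1e-3), batch 32, early stopping on validation
accuracy with patience 10, best-validation weights restored. These are
unremarkable defaults, fully recorded in the run history. Transfer
learning is supported by loading a named-parameter `.npz` archive; all
name+shape matches load, a mismatched classification head is
reinitialized, and `strict=True` turns any mismatch into an error. Both
full fine-tuning (default) and a frozen backbone are available.

## Synthetic data

The generator emulates a small seizure cohort. Interictal records are
colored Gaussian noise with power spectral density proportional to
f^(-noise_exponent) (default 1, the 1/f-like EEG background), scaled to a
common RMS. Ictal records add a rhythmic oscillation: one dominant
frequency per record drawn uniformly from the ictal band (default 8-12
Hz), random phase per channel, 20% sinusoidal amplitude modulation at
0.5 Hz, scaled so the oscillation RMS is `ictal_amplitude_ratio` times
the background RMS (default 4). Ictal records carry one seizure interval
covering their full duration.

The background noise stream is keyed by (seed, subject, record) only —
not by state — so at ratio 0 an ictal record is sample-for-sample
identical to its interictal counterpart. That makes the degenerate null
exact: the two classes share one distribution and any classifier must
fall back to chance. Streams are independent per (seed, subject, record),
so enlarging a cohort never perturbs existing records.

What the generator does *not* emulate: artifacts (muscle, eye movement,
electrode pop), non-stationary background, seizure evolution in frequency
and amplitude, inter-channel propagation delays, or realistic
seizure-to-background morphology. Passing end-to-end tests therefore
demonstrates that the pipeline's spectral front end and classifier recover
a band-limited rhythmic discharge at the stated signal-to-background
ratio — not clinical-grade performance on real EEG, which published
studies obtain only with the real corpora and far longer training.

## Numerical choices

- Window samples are `floor(window_s * fs)` (23.6 s at 173.61 Hz is
  non-integral); the step is `round(step_s * fs)` samples, at least 1.
- FFT features use a rectangular window (no taper) and remove the
  per-channel mean so the DC term does not bleed into the 1 Hz bin.
- Scalogram magnitudes (not real parts) are rendered; contouring uses 10
  equally spaced levels between the per-image min and max, computed on the
  min-max-normalized map, so rasters are exactly invariant to positive
  affine transforms of the feature values. A constant map renders as a
  uniform image rather than raising.
- Image resizing is bilinear; normalization constants default to the
  standard natural-image-corpus mean/std (matching pretrained backbones)
  and are switchable.
- The EDF writer quantizes to 16 bits with per-channel physical ranges
  and 1 s data records (integral sampling rates only); reading goes
  through `mne`, and amplitudes round-trip to ~0.002 uV over a ~200 uV
  span.
- Metrics with a zero denominator are `None` (undefined), never 0, and
  propagate as missing values in sweep tables so averages are not biased.

## Experiment designs

*Intrapatient*: all subjects pooled, optionally balanced 1:1 by random
down-sampling of the majority class, then a stratified random split into
train/validation/test with fractions (0.6, 0.2, 0.2) by default (the
split proportions are a package choice). *Interpatient*: entire subjects
held out; their slices form the test set, the rest are split into
train/validation; no subject appears on both sides, checked on every run.
`run_experiment` sweeps windows x bands x levels, repeats each cell with
seeds seed+0..repeats-1, reports mean metrics per cell, and isolates cell
failures (a failed cell carries NaN metrics and the reason).

Problem sizes used by the tests and the acceptance script: 5 subjects x 4
records (2 ictal, 2 interictal) x 23 channels x 30 s at 256 Hz, a 2 s
window with 50% overlap (~290 slices per class), the tiny network preset,
6 epochs. These sizes were chosen so the full suite runs comfortably on a
single CPU while leaving the classes' separability (at ratio 4) and
exchangeability (at ratio 0) intact.

## Known limitations

- The CWT scale axis is the raw integer scale 1..total_scale; no
  scale-to-frequency targeting is applied (the mapping depends on the
  wavelet's center frequency; `pywt.scale2frequency` can guide a custom
  choice of scales if frequency alignment matters).
- Levels 5-7 are constructible but untested end-to-end (their published
  counterparts were not evaluated either); training any published level
  at full resolution in NumPy is possible but slow — the engine is tuned
  for the tiny preset and for forward passes at level 0.
- The EDF writer covers the subset of the format the pipeline needs; EDF+
  event channels are out of scope.
- No post-hoc smoothing across consecutive slices: a slice is one case,
  and slice-level predictions are the final output.
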