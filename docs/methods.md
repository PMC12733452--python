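# Methods

## Problem and pipeline

`sonoseg` segments low-grade-glioma lesions in 2-D FLAIR-derived brain MRI
slices and renders the predictions through three perceptual channels: RGB
color maps, stereo audio, and symbolic MIDI. The chain is

1. **data** — index per-patient folders of slice/mask pairs, split by
   patient, normalize and crop/pad to the network input;
2. **segmentation** — one of four architectures produces a per-pixel tumor
   probability map;
3. **anomaly analysis** — z-scores against normal tissue plus
   connected-component morphology yield region descriptors and severity
   labels;
4. **sensory rendering** — regions are mapped to musical scales, dissonant
   intervals, stereo position and loudness.

## Data handling

Images are scaled to [0, 1] by the fixed 8-bit dtype range (divide by 255),
not per-image min–max. Per-image normalization would erase absolute
intensity differences between slices, and the downstream z-score stage
depends on intensities being comparable across slices. Masks are binarized
at >127, since 8-bit masks commonly store foreground as 255.

The patient-wise split floors each partition count from the fractions
(default 0.90/0.05/0.05) and assigns the remainder to the test partition,
so 110 patients split 99/5/6. Splitting is uniform at random per seed with
no stratification by tumor presence. The crop/pad to the 256×256 network
size is a center crop for larger inputs and symmetric zero-padding for
smaller ones; for same-resolution 2-D inputs, isotropic resampling is a
no-op. `preprocess` is idempotent: already-float unit-interval inputs pass
through unscaled.

Training-time augmentation applies, each through an independent Bernoulli
gate: horizontal flips (p = 0.5), rotations within ±7°, elastic
deformations (displacement amplitude 10 px, Gaussian-smoothed with width
4), Gaussian intensity noise (SD 0.02 on the unit interval), global
intensity shifts (±10%), and linear motion blur (kernel size 3–7,
horizontal/vertical/diagonal). Geometric transforms act identically on
image and mask, with nearest-neighbour resampling keeping the mask binary;
photometric transforms touch the image only. The gate probabilities other
than the flip's, and the elastic/noise magnitudes, are package defaults
exposed in `AugmentationConfig`. Validation and test data are never
augmented.

## Networks

All four models run on a small reverse-mode automatic-differentiation
engine written on NumPy (`sonoseg._nn`), providing stride-1 'same'
convolutions (dilated for ASPP), non-overlapping 2×2 transposed
convolutions and max-pooling, batch normalization, the elementwise
nonlinearities, row gathering/softmax for graph attention, and Adam. Every
operation's gradient is checked against central finite differences in the
test suite. Layout is NHWC, float32.

- **U-Net** — four encoder stages of two 3×3 conv (BatchNorm + ReLU) and
  2×2 max-pool, channels doubling from 64; a 1024-channel bottleneck;
  decoder with 2×2 transposed convolutions, skip concatenation and two
  convolutions per stage; 1×1 sigmoid head. With convolution biases and
  BatchNorm scale/shift counted (running statistics excluded) the default
  model has exactly 31,043,521 trainable parameters (31.04 M). The bias
  convention is pinned by that published total.
- **DeepLab variant** — four residual blocks (two 3×3 conv + BN + ReLU,
  additive skip with a 1×1 projection on channel change), each followed by
  a squeeze-excite channel-attention gate (bottleneck ratio 8) and 2×2
  max-pooling; an ASPP module with one dilated 3×3 branch per rate
  {6, 12, 18} plus a 1×1 branch; a transposed-convolution decoder and
  sigmoid head.
- **GAT / SGNN** — a convolutional stem downsamples to the node grid
  (default 16×16); a graph is built per sample from the stem features with
  cosine-similarity edges — dense for the GAT, each node's top-k most
  similar neighbors (ties broken by node index) for the SGNN, self-loops
  always included; two stacked multi-head attention layers (8 heads,
  8-dim heads, LeakyReLU slope 0.2, ELU between layers, identity before
  the decoder) refine node embeddings; embeddings reshape to the grid and
  transposed convolutions restore full resolution. The SGNN differs from
  the GAT only in graph construction, so a neighbor budget of N−1
  reproduces the dense model exactly — a property the tests exploit.
  Channel widths are chosen for the desk scale (tens of thousands of
  parameters); graph construction is treated as non-differentiable
  (gradients flow through the attention weights, not the topology), the
  standard practice for similarity-built graphs.

Initialization is He-truncated-normal for convolutions and Glorot-uniform
for dense/attention parameters, from a generator seeded through the model
spec, so builds are reproducible.

## Losses, metrics, training protocol

Training minimizes the smoothed soft Dice loss
`1 − (2Σpt + s)/(Σp + Σt + s)` (s = 1) and logs the smoothed Jaccard
distance `(1 − (I + s)/(U − I + s))·s` with s = 100 as an auxiliary; a
config weight can fold the auxiliary into the objective, but the default
optimizes Dice alone. The ×s scaling of the Jaccard distance follows the
widely circulated reference formulation; the unscaled complement is a flag
away. Hard metrics are Dice, IoU and binary accuracy at threshold 0.5
(probability exactly 0.5 counts positive); the both-empty convention is
1.0 for metrics and 0.0 for losses. Reported aggregates are means of
per-slice metrics.

The protocol: Adam at 1e−4, batch 32, up to 150 epochs in resumable
50-epoch sessions; ReduceLROnPlateau on validation Dice (maximize) with
factor 0.2 and patience 5; early stopping at patience 20; the best
validation-Dice weights retained plus periodic checkpoints every 5 epochs.
Within an epoch, batches are drawn in a seeded shuffled order, so runs are
bit-reproducible single-threaded.

## Phantoms

The generator emulates the statistical structure the pipeline needs from
FLAIR slices: a smooth elliptical brain (intensity 0.45) on a dark
background (0.05) with an optional hyperintense lesion disk (0.85) whose
support is the ground-truth mask, Gaussian texture (SD 0.03), and optional
sinusoidal boundary jitter so that small/complex-shape behaviour is
exercisable. It writes the exact per-patient `_mask` file layout the
indexer reads. It does **not** model MR physics, multi-tissue anatomy,
partial-volume boundaries, bias fields or pathology heterogeneity — so
passing desk-scale tests demonstrates that the pipeline's machinery is
correct and trainable, not that real-data accuracy figures transfer.

Desk-scale study conditions used by the test suite: 200 phantom slices
(20 patients × 10 slices, 64×64), split 70/15/15 by patient; U-Net at base
width 16 and the graph models with top-k = 8 on a 16×16 node grid; batch
16, learning rate 1e−3, 10 epochs, 3 seeds. Under this budget the U-Net
reaches median test Dice ≥ 0.85 and the mean-Dice ranking reproduces the
published ordering U-Net > SGNN > GAT. The learning rate is higher than
the full-scale protocol's 1e−4 because the budget is two orders of
magnitude smaller; it is applied identically to all three architectures.

## Anomaly analysis

The normal-tissue reference is the Otsu-thresholded brain foreground minus
the predicted lesion; z-scores are (I − μ_ref)/σ_ref with an all-zero map
(and a warning) when the reference is constant. Components are 8-connected;
the perimeter is the count of pixel edges bordering background, giving the
shape complexity perimeter²/(4π·area) ≥ 1 for a disk (up to rasterization).
Components under 5 px are dropped as speckle. Severity is a ladder on the
region's max z-score: high ≥ 3.0 SD, moderate ≥ 2.0 SD, both configurable.
No texture operator beyond complexity is defined; complexity serves as the
texture proxy wherever a "texture" cue is called for.

## Sensory mappings

Scale selection is a precedence ladder: small-and-complex regions → blues;
large regions → pentatonic; bright → major; dark → minor; otherwise major.
Morphology outranks size outranks intensity because shape anomalies are
the rarest and most diagnostic cue and must not be masked. Thresholds:
intensity high/low 0.66/0.33, large area 2% of image pixels, small 0.5%,
complexity 1.8 — all config-exposed. The small/complex gate is a
conjunction by default with a flag to switch to a disjunction.

Severity maps to harmonic dissonance rendered as simultaneous dyads: a
tritone (+6 semitones) for high, a minor seventh (+10) for moderate,
nothing for none.

Audio: regions are voiced in descending-area order, one slot of 2 s each
(an empty report renders one slot of exact silence). Melodies walk scale
degrees in ±1/±2 steps from an intensity-determined start, reflected into
a two-octave compass; note density scales with the region count (denser
pathology, denser rhythm). Synthesis is additive with 4 harmonics at 1/n
amplitude and 10 ms raised-cosine edges; voice amplitude is modulated by
the region's mean z-score; stereo position uses the constant-power
(cosine/sine) pan law on the centroid column, so mirroring the mask
horizontally swaps channel RMS exactly. Output is peak-normalized to 0.9
and written as 16-bit PCM stereo WAV at 44.1 kHz. All randomness comes
from a generator seeded per (config seed, region index), making renders
bit-identical under a fixed seed and invariant to pan position.

MIDI: one phrase per region — an 8-note melodic walk over the region's
scale, duration quantized from area into {1/4, 1/2, 1, 2} beats, velocity
an affine map of mean intensity into [40, 127] — followed by the severity
dyad. Files are Standard MIDI File format 0 at 480 PPQ with the tempo meta
event (default 90 BPM); the writer is self-contained and its output is
verified in the tests by an independently written parser.

The spectrogram helper (Hann-windowed short-time FFT of the channel mean)
exists for QC imagery and satisfies the per-frame Parseval identity.

## Numerical and design notes

- Cosine similarity guards zero-norm feature vectors (similarity 0); an
  all-zero feature grid is rejected as degenerate at the API, and the
  in-network construction falls back to a dense graph in that measure-zero
  case rather than aborting training.
- Max-pool backward routes gradient to the argmax (first index on exact
  ties); attention softmax is computed with max subtraction.
- The scaled-down test budgets (problem sizes above) were chosen so the
  whole suite runs comfortably on a single CPU; the full-protocol defaults
  (256×256, batch 32, 150 epochs) remain the documented configuration for
  real data.

## Known limitations

- The published absolute Dice/IoU on the TCGA-LGG collection are not a
  test surface here: they require the external download and GPU-scale
  training. The pipeline accepts that data unchanged via the same folder
  layout.
- GAT/SGNN channel widths are desk-scale; published parameter totals for
  those models (0.15 M / 0.28 M) are not replicated exactly since the
  source widths are unspecified.
- Sonification is rule-based; no perceptual-loudness calibration or
  psychoacoustic validation is claimed.
- 2-D slices only; no DICOM/NIfTI volumetric ingestion or skull-stripping
  (inputs are assumed already skull-stripped).
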