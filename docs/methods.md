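# Methods

This note records how each stage of the toolkit is defined, which
choices were genuinely open, and what the synthetic experiments do and
do not demonstrate.

## Synthetic lesion generator

The generator emulates the image properties the ABCDE rule measures,
nothing more.  A lesion is a filled radial polygon
`r(θ) = R·(1 + 0.6·irregularity·perturb(θ))`, where `perturb` is a
seeded sum of random-phase harmonics (orders 2–7, amplitude-normalized
to 1) — smooth, hole-free, single-component by construction.  Asymmetry
is imposed by scaling the radius in the upper half-plane by
`(1 − 0.75·asymmetry_level)`; the 0.75 ceiling keeps the blob from
degenerating at level 1.  The interior is partitioned into `n_colors`
contiguous patches (nearest seeded interior site) drawn from a
dark-brown band (RGB lows ≈ (50, 25, 15), highs ≈ (140, 90, 70)) that
is well separated in luminance from the default skin tone
(205, 170, 150), so Otsu thresholding recovers the truth mask reliably
(IoU ≥ 0.9 asserted over 50 seeds).  Additive Gaussian noise (default
sd 8 intensity units, a moderate sensor-noise level) is applied last
and clipped to [0, 255].

Per-image seeds derive from the master seed as successive 32-bit words
of `numpy.random.SeedSequence(master_seed)`, reduced mod 2³¹ — any
dataset is reproducible from `(class specs, n_per_class, seed)` alone,
and the JSON sidecar written next to the PNGs records all of it.

The built-in 3-class benchmark (`benchmark_class_specs`) separates
classes along diameter (radii 10/22/16 at 64×64), border irregularity
(0.1/0.8/0.4) and color count (1/2/4).  What passing tests on it show:
the full pipeline — generation, segmentation, encoding, training,
evaluation — is internally consistent and learnable signal flows end to
end.  What they do not show: performance on real dermoscopy, which has
hair and ruler artifacts, vignetting, heterogeneous illumination,
ambiguous boundaries and overlapping class morphologies that the
generator deliberately does not model.

## Morphometry

* **Segmentation** (no canonical recipe exists for this step):
  luminance → Otsu threshold → the polarity whose foreground is the
  minority region → largest 8-connected component → fill holes.
  Deterministic and testable against synthetic truth; uniform images
  raise a "no lesion" error.
* **Perimeter convention.** `P_L` is the Crofton 4-direction estimate
  (`skimage.measure.perimeter_crofton`).  Pixel-edge counting
  over-estimates a circle's perimeter by ~27% and the raw
  marching-squares polygon by ~5% (an error that does not shrink with
  resolution); the Crofton estimate converges, giving disk roundness
  1.0007 at radius 200 on a 512² grid with error decreasing
  monotonically over radii 25→200.  The convex-hull perimeter in the
  convexity variant of B uses the same estimator on the hull image, so
  convex masks score exactly 1.
* **Asymmetry index.** `AI = ΔAK/AL` with
  `ΔAK = ½·Σ_i |f(x_i,y_i) − f(x_i′,y_i′)|`.  The pairing map is
  reflection across a principal axis of the binary mask (eigenvectors
  of the second-order central moments; for isotropic masks this
  degenerates gracefully to the image axes).  `f` is luminance scaled
  to [0, 1], zero outside the mask; mirror points are sampled at the
  nearest pixel.  Both principal axes are scored and averaged, making
  the index rotation-invariant (verified under 90° rotation to 0.02).
  A shape symmetric in both axes with symmetric intensities scores
  exactly 0.
* **Border irregularity** has two non-equivalent definitions in the
  literature; both are exposed: `compactness = P_L²/(4π·AL)` (default —
  closed-form, hull-free) and `convexity = P_L / hull perimeter`.  The
  identity `roundness² · compactness = 1` holds to machine precision by
  construction and is asserted on random masks.
* **Color variation** is the population standard deviation (ddof 0) of
  lesion pixels per channel, averaged over the three channels.
* **Diameter** is reported in pixels; the clinical "> 6 mm" flag is
  only emitted when an `mm_per_px` calibration is supplied, since pixel
  pitch is unknowable from an image alone.

## Patch encoding

Non-overlapping `P×P` patches in row-major grid order, flattened
channel-last; `N·P² = H·W` is enforced and non-divisible sizes are a
hard error — silent padding or resampling would corrupt the morphometry
ground truth used in tests.  The embedding matrix has shape
`(D, P²·C)` so that `z_i = E·x_i` is well-typed.  `E`, `E_pos` and
`z_CLS` initialize uniform in `[−1/√D, +1/√D]` from a seed.  Defaults
`P = 10`, `D = 64` for 100×100 inputs (100 tokens); the 64×64 benchmark
uses `P = 8`, `D = 32`.  The CLS token is available (prepended at index
0, positions added after concatenation) but off by default: the LSTM
consumes the whole sequence, so a summary slot is unnecessary; it is
rejected for the `cnn_first` wiring where no embedded token sequence
exists.

## Network primitives and the training backend

`neural_reference` is the readable ground truth: LSTM gate recurrences,
valid cross-correlation (no kernel flip, stride 1, scalar bias per
output channel), max-pooling that drops partial trailing windows, dense
layers and max-stabilized softmax.  The trainable model runs on a
separate compact reverse-mode autodiff engine (`_autodiff`) written
over numpy in float64 — deliberately dependency-free so that training
is bit-reproducible on one CPU.  Dual-route testing pins the backend's
forward semantics to the references at 1e−5 (they agree to ~1e−15;
the looser bound allows for reordered summation), reference ops match
independent brute-force loop transcriptions at 1e−12, and all backend
gradients are checked numerically.  One representational difference:
backend weight matrices are stored transposed (`(in, out)` orientation,
`h·W`) relative to the references (`W·h`); the parity tests document
the mapping.

## Hybrid model

The open design question is how an LSTM hidden vector becomes a 2-D
"frame" for time-distributed convolution.  Chosen wiring
(`order="lstm_first"`, the default): `lstm_hidden` must be a perfect
square `d²` and each `h_t` is reshaped to `(d, d, 1)`; the same conv
stack then processes all `N` frames.  The alternative
(`order="cnn_first"`) applies the conv stack to raw `P×P×C` patches and
the LSTM to the resulting feature sequence, classifying from the final
hidden state.  Defaults: `lstm_hidden = 64` (`d = 8`), two conv blocks
of 16 then 32 3×3 kernels with 2×2/stride-2 max-pooling (the smallest
stack that exercises convolution and pooling twice on an 8×8 frame),
one 64-unit dense layer.  The benchmark configuration shrinks this to
one block of 8 kernels and `D = 32` to keep the CPU budget small; all
sizes are configurable.

Training choices where the design was open: Adam (LR 0.001, batch 32,
≤ 100 epochs) — the optimizer family is unstated for the hybrid, so the
settings published for the plain CNN baseline are reused; categorical
cross-entropy (standard for a softmax multiclass head); L2 factor
0.001 applied to weight matrices only; dropout rate constrained to
[0.3, 0.5] with default 0.4 (band midpoint), placed after the embedding
(before the LSTM) and after each dense activation, with a master
`use_dropout` switch so regularization ablations don't violate the
rate band; LR halved after each 5-epoch validation-loss plateau;
early stopping on validation loss (patience 10) with best-weight
restoration; a 0.99 validation-accuracy stopping threshold; forget-gate
bias initialized to +1 (standard recurrent-training aid); global
gradient-norm clipping at 5.  The internal validation split is a
stratified 20% of the training data, seeded from the model seed.
Augmentation (rotation ±20°, random H/V flips, scale 0.9–1.1 with
center crop/pad, brightness ±10%) is applied per batch with seeds drawn
from the training RNG, so the entire history is a pure function of
`(config, data, seed)`.

Class-imbalance weighting (inverse-frequency) exists but is off by
default.  The morphometry vector X = [A, B, C, D] is *not* fed to the
network — whether it should be is left ambiguous by the model's
description, and concatenating four scalars onto thousands of learned
features is untested territory; the feature CSV exists for anyone who
wants to try.

## Evaluation

Per class one-vs-rest: precision, recall, F1 and G-measure = √(P·R)
(the geometric mean — the standard definition).  Macro averages are
unweighted class means; accuracy is trace/total.  Zero denominators
yield 0 with the class flagged in `degenerate_classes`.  ROC curves are
per-class one-vs-rest (sklearn's threshold grouping handles ties), AUC
by the trapezoid rule; the test suite cross-checks AUC against the
Mann–Whitney rank statistic on 200 random score sets and asserts the
AM–GM inequality for G on 1000 random matrices.

## Numerical and degenerate-input conventions

Float64 throughout the numerics; 8-bit RGB rasters at the I/O
boundary, pixel values scaled to [0, 1] before encoding.  Softmax is
max-stabilized; outputs can underflow to exactly 0 when logit spreads
exceed ~700, which the tests acknowledge.  Masks smaller than 3 px
reject border scoring; empty masks, uniform images, single-class
datasets, non-divisible patch sizes, and misaligned mask/image pairs
all raise explicit errors rather than degrading silently.  NaN/inf
training loss aborts with a diagnostic.

## Problem sizes

The shipped experiments are desk-scale by design: the benchmark trains
on 480 images of 64×64 (≤ 12 epochs, ~1–2 min on one CPU) and the
regularization comparison re-trains twice at ≤ 8 epochs.  The
overfitting gap in that comparison is measured as
`max(0, train − val)` accuracy at the best epoch, both sides computed
in eval mode: a negative raw difference means validation outscored
training — no overfitting — and its magnitude is sampling noise of the
96-image validation split, not a regularization effect.

## Known limitations

* The generator's simplicity means benchmark accuracy says nothing
  quantitative about real dermoscopy performance.
* The asymmetry pairing (nearest-pixel reflection) is one of several
  defensible discretizations; scores are comparable within this
  package, not across implementations.
* The autodiff backend optimizes for clarity and reproducibility, not
  speed; wall-clock scales roughly linearly in tokens × hidden size and
  large configurations are slow.
* `E` (evolution over time) of the ABCDE rule is out of scope — no
  temporal feature is computed.
* Training determinism is guaranteed within a fixed numpy/BLAS build;
  across builds, summation order may differ in the last bits.
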