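# Methods

## The measurement this package models

A single-beam acoustic tweezer (SBAT) — a focused, high-frequency
ultrasound beam — traps a single suspended cell and presses it toward the
dish. The radiation force spreads the cell laterally, and the degree of
spreading reflects the cell's stiffness: invasive breast-cancer cells
(MDA-MB-231-like) are softer and deform visibly more than weakly invasive
ones (MCF-7-like). The classification task is therefore: given a pair of
gray-level photomicrographs of one cell — trap OFF and trap ON — decide
whether the cell belongs to the invasive class.

The pipeline has four stages:

1. **Change encoding** (`preprocess`). Each frame is min–max
   contrast-stretched to [0, 255] with round-half-up, then the pair is
   fused into a three-channel image: trap-ON in red, trap-OFF in green,
   and their per-pixel rounded mean in blue. Where nothing moved, red =
   green = blue and the pixel renders gray; where the boundary moved, a
   red/green fringe appears. The averaged blue channel deliberately
   preserves background structure — including reflected-light noise — so
   the classifier can learn to discount it. No denoising or segmentation
   is applied.
2. **Geometric augmentation** (`augment`). Each combined image is expanded
   into `n_augment_per_cell` rotated/shifted/zoomed variants plus the
   original (201 per cell at the canonical 200). One affine map is applied
   identically to all three channels, so the change encoding can never be
   decoupled. Photometric jitter is excluded by design: it would corrupt
   the change signal.
3. **Shallow CNN** (`cnn`). Three 3×3 same-padded convolutional layers
   (32, 64, 128 filters), each followed by 2×2 max-pooling; flatten; one
   128-unit fully connected layer with dropout 0.5; one sigmoid output.
   ReLU everywhere else. Loss is binary cross-entropy; labels are coded
   1 = invasive. The decision rule is score > 0.5 → invasive (a score of
   exactly 0.5 falls to the negative class). Only the first layer's width
   (32) is canonical; the remaining widths, same-padding, stride 1 and the
   128-unit hidden layer are this package's declared defaults, exposed in
   configuration.
4. **Grouped evaluation** (`evalkit`). Stratified grouped k-fold
   cross-validation at the cell level: all images of a cell stay on one
   side of every fold, and each class contributes equally to every test
   set (the 40-cell design gives 32 training / 8 test cells per fold, 4
   per class). Metrics use the set formulation — accuracy
   (|M*∩M| + |(M*∪M)ᶜ|)/|U|, precision |M*∩M|/|M|, recall |M*∩M|/|M*|,
   F1 = 2pr/(p+r) — computed at the image level (each augmented image is
   one element of U, matching the 1608-images-per-test-fold arithmetic of
   the 40-cell design). A cell-level majority-vote summary is reported as
   a secondary output. Leakage is asserted per fold, not assumed.

## The network implementation

No deep-learning framework is a dependency: the layers, backpropagation
and the five optimizers (SGD, RMSprop, Adagrad, Adadelta, Adam) are
implemented on NumPy, with convolutions as im2col patch extraction plus a
BLAS matrix product in float32. Optimizer hyper-parameters beyond the
learning rate use the canonical values from their original descriptions
(RMSprop decay 0.9; Adadelta decay 0.95, epsilon 1e-6; Adam 0.9/0.999).
Adadelta runs at its recommended initial learning rate of 1.00 and the
learning rate is not searched for it. Gradient correctness is established
in the test suite by float64 directional-derivative checks (single-
coordinate finite differences can straddle a rectifier kink, where any
subgradient is valid; a random direction through thousands of parameters
averages such kinks away). Max-pooling splits the gradient equally among
tied maxima; dropout is inverted (scaling at train time) and disabled at
inference, so predictions are deterministic and batch-composition
invariant. Weight initialisation is He-normal (Glorot-scaled for the
output unit), seeded; training is bit-reproducible under single-threaded
execution.

## Grid search

The hyper-parameter grids are learning rate {0.00025, 0.0025, 0.025,
0.25} (×10 steps), batch size {1, 2, 4, 8, 16, 32} (×2 steps) and epochs
{20, 40, …, 300} (+20 steps) — 360 configurations per optimizer, 90 for
Adadelta. Each (optimizer, learning rate, batch size) cell is trained once
per fold to the maximum epoch count with per-epoch validation, and every
epoch value on the grid is read off as a checkpoint rather than retrained;
this matches a per-epoch learning-curve protocol. The search is evaluated
with the same outer five-fold CV (no inner loop), a known optimistic-bias
simplification adopted deliberately. Best per optimizer = highest mean
validation accuracy, ties broken by lower mean validation loss, then
fewer epochs.

## The synthetic-data generator

The study's 40-cell image set was never deposited, so the package ships a
generator that reproduces the *statistical structure* the analysis relies
on, with ground truth:

* **Shape.** An ellipse (major semi-axis drawn from `radius_range`,
  aspect 0.8–1.0, random orientation) with a low-order radial Fourier
  perturbation (modes 2–5, amplitude `boundary_roughness`, falling off as
  1/m) giving a realistically irregular boundary.
* **Deformation.** Trapping scales the major axis by a per-cell area
  ratio drawn from a truncated normal (draws below 1 are redrawn —
  trapping never shrinks the projected area in this model). Because the
  boundary perturbation lives in the normalised ellipse frame, the
  analytic ON/OFF area ratio equals the drawn ratio exactly;
  pixel-counted masks agree to within ~2 % rasterisation error. Defaults:
  invasive (1.30, 0.05), non-invasive (1.08, 0.03) — chosen to mirror a
  clearly stronger deformation of the invasive class while keeping the
  distributions realistic rather than trivially separated (the largest
  weakly-deforming draws approach the smallest invasive ones).
* **Rendering.** Bright-field: mid-gray background with additive Gaussian
  noise (sd `noise_level` = 8 gray levels) and `n_noise_blobs` = 3 bright
  Gaussian spots imitating reflected-light artifacts; the cell has a
  mid-gray interior and a bright rim. Fluorescence mode: near-black
  background and a bright cell body, no blob artifacts. The background
  realisation is shared between OFF and ON renders — the trap moves the
  cell, not the dish — which the conservation test asserts.
* **Scale.** Default 128×128 px at 0.5 µm/px with major semi-axes of
  5–12 µm (cell bodies roughly 10–30 µm across, matching the 10 µm scale
  bars of typical SBAT photomicrographs). The pixel dimensions of the
  original photomicrographs are unknown; these are declared defaults, not
  reconstructions. Configuration validation requires the worst-case
  deformed cell (mean + 4 sd of the ratio, plus roughness headroom) to
  fit the field of view.

What the generator does **not** emulate: optical blur and depth-of-field,
intra-cell texture (organelles), illumination gradients, partial cells at
the image edge, or any correlation between cell size and class. Passing
tests therefore demonstrate that the pipeline recovers a
deformation-ratio difference under realistic noise, augmentation and
grouped evaluation — not that it would reach the same figures on real
photomicrographs.

## Benchmark problem sizes

The packaged benchmark protocols (`sonodeform.protocols`) run the study
design at desk scale: 20+20 cells rendered at 64×64 px (1 µm/px, major
semi-axes 5–12 µm), 50 augmented variants per cell, five-fold grouped CV
with Adadelta (learning rate 1.00, batch size 16), 10 epochs per fold.
The epoch budget comes from pilot training curves: training loss reaches
its plateau by epoch ~6 and held-out accuracy stabilises by ~10, so the
fixed budget trains every fold to its plateau while a full five-fold run
completes in minutes on one CPU. The zero-effect null control (both
classes drawing deformation ratios from the weak distribution) runs
smaller still — 32×32 px, 20 variants per cell, 8 epochs — because the
quantity of interest is only whether accuracy stays at chance. Its
acceptance band is ±2 binomial standard deviations around 0.5 with n = 40
*cells* as the independent unit: the ~200 augmented images of one cell
are near-perfectly correlated predictions, so counting images would
overstate the effective sample size roughly five-fold.

On the strong-effect benchmark the errors concentrate in genuinely
borderline cells — e.g. a large weakly-invasive cell whose absolute
boundary displacement matches that of a small invasive cell — which is
the expected behaviour of a classifier reading deformation: borderline
cells, not noise, set the error floor.

## Numerical choices and edge cases

* Contrast stretch of a constant image is undefined (max = min); it
  returns all zeros with a warning.
* All rounding of pixel values is round-half-up (`floor(x + 0.5)`).
* Channel order is a flag (`on_red` default, `off_red` available) because
  both conventions appear in practice.
* Contrast enhancement is per-image; a joint per-pair mode is not claimed
  to reproduce anyone's protocol and is out of scope.
* Precision with an empty detected set (and recall with an empty truth
  set) is defined as 0 with a warning; F1 is 0 when p + r = 0.
* Empty training sets, mismatched pair shapes, invalid optimizer names,
  inputs too small for three pooling halvings, and k exceeding the cell
  count all raise before any computation.
* Determinism: every stage takes a seed; per-cell and per-fold generators
  are spawned from seed sequences so results do not depend on iteration
  order. Training is deterministic only under single-threaded BLAS.

## Known limitations

* The CNN is CPU-bound NumPy; it is meant for cohorts of tens of cells at
  ≤128 px, not for large-scale training.
* Grid search at the full canonical grid retrains 24 CV runs per
  optimizer and is intended for reduced grids at desk scale.
* The cross-domain (fluorescence) evaluation shares the synthetic
  generator's geometry between domains; it probes appearance shift only.
* Stride > 1 convolutions are validated in configuration but not
  implemented; the canonical architecture uses stride 1.
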