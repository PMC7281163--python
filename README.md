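# sonodeform

Classify the invasiveness of single breast-cancer cells from paired
acoustic-trapping photomicrographs with a shallow convolutional network.

A single-beam acoustic tweezer (SBAT) traps a suspended cell and presses
it against the dish; soft, invasive cells (MDA-MB-231-like) spread
laterally more than stiff, weakly invasive ones (MCF-7-like). Given one
gray-level image with the trap **off** and one with it **on**, the
pipeline:

1. contrast-stretches each frame to [0, 255] and fuses the pair into a
   three-channel change image **I = ⟨B, A, N⟩** — trap-ON in red (A),
   trap-OFF in green (B), and their per-pixel mean in blue (N), so static
   background renders gray and the moved boundary renders as red/green
   fringes;
2. augments each combined image into 200 rotated/shifted/zoomed variants
   plus the original;
3. trains a shallow CNN — three 3×3 conv layers (32/64/128 filters) with
   2×2 max-pooling, a 128-unit FC layer with dropout 0.5, and a sigmoid
   output — with binary cross-entropy, predicting invasive iff the score
   exceeds 0.5;
4. evaluates with grouped, stratified five-fold cross-validation (all
   images of a cell stay on one side of each fold) and set-based metrics

   a = (|M\*∩M| + |(M\*∪M)ᶜ|)/|U|, p = |M\*∩M|/|M|, r = |M\*∩M|/|M\*|,
   F1 = 2pr/(p+r),

   plus a grid search over optimizer ∈ {SGD, RMSprop, Adagrad, Adadelta,
   Adam}, learning rate ρ, batch size β and epochs ε.

Because no real SBAT image set is publicly available, the package ships a
synthetic generator (`sonodeform.synth`) that renders paired
photomicrographs of boundary-perturbed elliptical cells whose ON/OFF
projected-area ratio is drawn per class (invasive 1.30 ± 0.05,
non-invasive 1.08 ± 0.03 by default), over a shared noisy background with
reflected-light artifacts — with ground-truth masks, so every stage is
testable end to end. The CNN, its backpropagation and all five optimizers
are implemented directly on NumPy; the model is exposed as the
scikit-learn estimator `ShallowCNNClassifier`.

## Worked example

```python
import sonodeform as sd

# a small synthetic cohort: 8+8 cells, 64x64 px at 1 µm/px
cfg = sd.SyntheticConfig(n_cells_per_class=8, image_size=(64, 64),
                         pixel_pitch=1.0, seed=7)
records = sd.generate_dataset(cfg)
images, manifest = sd.combine_dataset(records)       # change encoding
ds = sd.augment_dataset(images, manifest,
                        sd.AugmentConfig(n_augment_per_cell=30, seed=1))

result = sd.cross_validate(ds, k=4, seed=0,
                           clf_params=dict(optimizer="adadelta", epochs=12))
print(result.summary.round(3))
```

prints (machine-trained numbers for this exact seed; several minutes on
one CPU):

```
      accuracy  precision  recall     f1   loss
mean     0.901      0.951   0.859  0.882  0.450
sd       0.093      0.067   0.208  0.128  0.592
```

i.e. mean image-level accuracy 0.901 across the four folds (sd 0.093):
the network recovers the class difference in trapping-induced deformation
from the change images alone. Per-fold reports, cell-level majority
votes, and per-epoch training histories are available on the result
object, and `sd.grid_search` / `sd.cross_domain_evaluate` cover the
optimizer search and the fluorescence transfer test.

The same pipeline runs from the shell:

```bash
sonodeform show-config                      # every default, overridable
sonodeform run --out runs/demo --seed 7     # simulate -> preprocess ->
                                            # augment -> crossval
```

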