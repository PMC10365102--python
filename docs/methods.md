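# Methods

## Intensity harmonisation by grayscale truncation

Radiographs from different machines differ by (approximately) a positive
affine transform of the detector response.  The preprocessing estimates an
intensity window from the central quarter of the image — rows
`[⌊x/4⌋, ⌊3x/4⌋)` by columns `[⌊y/4⌋, ⌊3y/4⌋)`, where the thorax lies in a
frontal film — clips the full image to `[V_min, V_max]`, maps it affinely to
`[0, 1]` and resizes to `S×S`.  Properties and conventions:

* **Affine invariance.**  `preprocess(a·I + b) = preprocess(I)` for all
  `a > 0`: clipping against window bounds estimated from the same image and
  min–max normalisation both commute with positive affine maps.  This is the
  point of the procedure and is property-tested.
* **Odd dimensions** use floor-based half-open ranges; the window is
  non-empty for any image of at least 4×4.
* **Degenerate window** (`V_min = V_max`, e.g. a constant image) maps to all
  zeros instead of raising, so batch pipelines keep running.
* **Resizing** is bilinear for images and nearest-neighbour for masks
  (preserving binarity).  Non-square inputs are resized anisotropically to
  `S×S`; no letterboxing.
* **Photometric polarity.**  DICOM MONOCHROME1 images are flipped
  (`v ↦ max − v`) before windowing so that air is always dark.

## Network

`TransResUNet` is an encoder–decoder for two-class (lung/background)
per-pixel prediction.

**Residual blocks.**  `transform(x) + shortcut(x)`, the transform being two
3×3 convolution → batch-norm → ReLU stages; the shortcut is the identity when
shapes match, else a 1×1 projection.  The second batch-norm's scale starts at
zero, so every block begins as the identity — useful for stable training from
scratch on small data.

**Encoder.**  Three (residual block → 2×2 average-pool) stages produce the
pyramid `F1 (S/2, c1)`, `F2 (S/4, c2)`, `F3 (S/8, c3)`.  Average pooling was
chosen over strided convolution as the simplest downsampling operator with
exact, easily verified gradients.

**Transformer bottleneck.**  `F3` is cut into `p×p` patches (`p = 1` by
default, i.e. one token per `F3` cell), linearly projected to `K` dimensions,
and summed with a learned 1-D position table.  `L` pre-norm layers follow —
`x ← x + MSA(LN(x)); x ← x + MLP(LN(x))` with GELU in the MLP and dropout
0.1 — then a final layer norm.  Defaults `L = 12`, `K = 768`, 12 heads, MLP
width `4K` follow the ViT-B/R50 convention; at full `S = 512` and `p = 1` the
grid is 64×64 = 4096 tokens, which is memory-heavy on CPU — `p = 2` is the
practical full-scale setting, while the tiny test instance uses `S = 64`
(64 tokens).

**Decoder.**  The token output, reshaped to a `S/8` map, is concatenated with
`F3`, refined by a residual block, and 2×-upsampled (nearest-neighbour);
the same pattern repeats with `F2` and `F1`.  A third upsampling returns to
full resolution before a 1×1 two-logit head — per-pixel prediction at `S`
requires this final stage.  Per-pixel softmax yields the lung probability.

**Initialisation.**  He-normal for convolutions, truncated normal (σ = 0.02)
for projections and position tables, zero biases, zero final-norm scale in
residual branches.  Training is from scratch; no pretrained backbone weights
are bundled.

The layers run on `lungseg.nn`, a small reverse-mode autodiff engine over
numpy arrays.  Every operator's analytic gradient is tested against central
finite differences, and zero-weight configurations of the residual and
transformer layers are verified to be exact identities.

## Training protocol

RMSprop (lr 10⁻³, smoothing α = 0.99, ε = 10⁻⁸ — recorded in every run
manifest), batch size 2, 20 epochs, pixelwise cross-entropy by default (soft
Dice and combined losses are selectable).  The 70:10:20 split uses
`floor`/round-half-up/remainder rounding, reproducing 810/116/232 at
n = 1158.  The best-validation-Dice epoch is returned (last-epoch selection
is available).  No data augmentation and no learning-rate schedule.  All
randomness (shuffling, dropout, initialisation) flows from explicit seeds;
repeated runs are bitwise identical.

## Post-processing

`binarize (t = 0.5, ≥ convention) → component filter → hole filling →
opening (disk r = 3) → component re-filter`.  The component filter keeps at
most the 2 largest connected components (8-connectivity), dropping any below
10 % of the largest's area — the two-lung prior, with the fraction rule
tolerating a merged single-component lung field.  Opening alone cannot
restore a missing interior patch, so enclosed holes are filled first; both
stages can be disabled independently.  Because opening can split a thin
component, the component filter runs once more at the end so the ≤ 2
component guarantee always holds.  The filter never adds foreground; hole
filling adds pixels only inside enclosed background regions.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline must survive,
not anatomy: two jittered, tilted lung ellipses (union = ground truth) at
nominal intensity 0.30 inside a 0.75 thorax ellipse on a 0.10 background,
a 0.88 mediastinal band, 4–6 rib stripes at 0.95 (partially brightening lungs
they cross, +0.22), distractor blobs *at lung intensity* outside the lungs
(probability 0.5), Gaussian noise σ = 0.03, and a per-image machine transform
`a·I + b` with `a` log-uniform in [0.5, 4000] and `b` uniform in [0, 2000].
Masks depend on geometry only.  Everything is a pure function of
(seed, index), so manifests regenerate images bit-for-bit.

What passing on phantoms does **not** show: robustness to real anatomy
(costophrenic angles, cardiac borders, scapulae), pathology (effusions,
consolidations), rotation/inspiration variability, or annotation noise.
Phantom scores characterise the pipeline's mechanics, not clinical accuracy.

The `corrupt_mask` fixture injects exactly the two failure modes the clean-up
targets — an external speck (radius 3.5 % of the side) and an enclosed
interior hole (2.5 %) — to measure repair quality in isolation.

## Desk-scale study

The end-to-end study (`lungseg.train.run_phantom_study`, also run by
`scripts/acceptance.py` and the acceptance tests) uses 60 phantoms at model
side 64 with the tiny configuration (channels [8,16,32], `L = 2`, `K = 64`,
4 heads, ~0.18 M parameters) and the full training protocol.  These sizes
were chosen so the whole study runs in about a minute on a single core while
still exercising every stage; with seed 1 it reaches a held-out mean Dice of
0.93 raw and 0.94 after post-processing on 12 test phantoms.  Full-scale
training (S = 512, L = 12, K = 768) uses the identical code path but needs a
GPU-class budget and real data.

## Numerical conventions and edge cases

* Dice of two empty masks is defined as 1; metrics with empty denominators
  (no lung pixels for SE, none predicted-background for SP) return NaN and
  are excluded from aggregates.
* Binarisation uses `≥` at the threshold.
* Attention uses scaled dot-product (`1/√(K/h)`); softmax is computed with
  max-subtraction for stability; cross-entropy clips probabilities at
  10⁻¹².
* Batch-norm uses momentum 0.1 running statistics (unbiased variance in the
  running estimate); evaluation mode is fully deterministic.
* Checkpoints are `.npz` weight archives with the `ModelConfig` embedded as
  JSON, so a checkpoint is self-describing.

## Known limitations

* Pure-numpy execution is single-threaded per operator call and far slower
  than GPU frameworks; the full-size configuration is impractical to train
  here, though it constructs and runs forward correctly.
* Convolutions are stride-1 same-padded odd kernels only — sufficient for
  this architecture, not a general library.
* The phantom generator's simplicity means reported phantom metrics
  overestimate what any model would achieve on clinical films.
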