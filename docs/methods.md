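# Methods

## Scope and models

The package implements two cooperating methods for 2-D liver-CT slice
analysis and exercises them on synthetic phantoms.

**Segmentation (En–DeNet).** A UNet-shaped encoder–decoder. The encoder is
pluggable: the default `tiny5` is a plain stack of `encoder_depth` stages
(two 3×3 conv + batch-norm + ReLU layers per stage, 2×2 max-pool between
stages); an `effnet-b3-style` inverted-bottleneck encoder (1×1 expand →
3×3 → 1×1 project, no pretrained weights) is selectable. The decoder has
exactly `encoder_depth` blocks of two 3×3 convolutions each, channel
counts `(256, 128, 64, 32, 16)` by default, with nearest-neighbour ×2
upsampling and a skip connection from the mirror encoder stage
concatenated before each block. A 1×1 convolution plus sigmoid yields a
per-pixel foreground probability. Inputs must be divisible by
`2^encoder_depth`.

The loss is `BCE + α · DiceTerm` with `α = 0.2`. The Dice term is the
soft Dice *loss* `1 − DC` by default; adding the raw similarity (flag
`dice_as_loss=False`) is supported but rewards bad masks and exists only
for comparison. BCE is the standard negative mean form. A Hausdorff-based
loss term is deliberately not part of the objective; HD95 is provided as
an evaluation metric only, since no principled weighting for a contour
loss term was available.

Optimization: Adam, learning rate 0.001, weight decay 1e-8, batch 16, up
to 200 epochs, with a reduce-on-plateau schedule — when the validation
loss has gone 5 consecutive epochs without strict improvement the rate is
multiplied by 0.1; training stops when the rate falls below 1e-6.

Post-processing: probabilities are binarized at threshold 0.5 with ties
(exactly 0.5) mapped to foreground; then 8-connected components with area
*strictly below* `min_area` are removed, so a component of exactly
`min_area` pixels survives. The default `min_area = 1024` is defined at
512×512 resolution; at other resolutions `scaled_min_area` scales it by
the area ratio (64 at 128×128). A mask-union utility (`union_ensemble`)
combines several model predictions by pixel-wise OR.

**Classification (GraMNet).** Networks are grown from SubNets — short
stacks of conv → batch-norm → ReLU → max-pool layer groups (presets A–E,
see README). Growth operators:

- *series*: the new SubNet consumes the frozen network's final feature
  maps; layer count `L_A + L_B + 1` including the single fully connected
  head.
- *parallel*: the new SubNet reads the raw input; both branches' final
  feature maps are spatially aligned and concatenated along channels; the
  head sits at layer `max(L_A, L_B) + 1`.

Freezing is absolute: frozen SubNets' weights, biases, batch-norm affine
parameters *and batch-norm running statistics* never change afterwards
(frozen batch norm always runs in evaluation mode). The five-stage plan
trains A, then B on A's features, then C in parallel, then D in series on
the concatenation, then E in parallel — only the newest SubNet and a
fresh head backpropagate at each stage. Because the frozen part is
deterministic, its feature maps are precomputed once per stage for the
whole dataset, which realises the method's computational saving in
practice.

Per-stage policy: Adam with initial rate 0.001 (the growth protocol
itself fixes only the schedule, not the starting rate; 0.001 matches the
segmentation choice and the usual Adam default), rate ×0.1 once half the
epochs are done (drop epoch `max(2, ceil(E/2))`), validation every 50
iterations, early stop after 50 consecutive validation checks above the
running minimum, L2 regularization 1e-4 applied to the trainable
parameters only. An alternative iteration-based preset (`SECTION4_PRESET`:
rate 1e-4, 500 iterations, drop ×0.1 after 20 iterations, batch 16)
is available; the epoch-based policy is the default. The classification
risk is the empirical cross entropy normalized by the class count M
(a `normalize="samples"` flag switches to 1/N); under Adam the
normalization only rescales gradients and does not change trajectories
meaningfully.

The classification head is global average pooling followed by one fully
connected layer and softmax. Pooling keeps the head size independent of
input resolution; the alternative of flattening the feature map would tie
the head to one image size. A fresh head is created at every growth stage
by default; `warm_start_head` copies the previous head's weights into the
matching channel prefix at parallel joins.

## Design choices at genuinely open points

- **Parallel spatial alignment.** Branches that pooled different numbers
  of times disagree in spatial size; the smaller (deeper-pooled) size wins
  and the larger map is average-pooled down by the integer ratio before
  concatenation. Average pooling preserves feature magnitudes; the
  alternative (upsampling the smaller map) would inflate compute for no
  accuracy gain on these tasks.
- **Stage-4/5 wiring.** SubNet D consumes the concatenated `(A+B)‖C`
  features in series; SubNet E reads the raw input, mirroring C. Both are
  overridable by composing `combine_series` / `combine_parallel` manually.
- **Pooling saturation.** 2×2 max pooling runs in ceil mode and saturates
  at 1×1, so deep stacks on small inputs degrade gracefully instead of
  erroring (SubNet B applied to A's 4×4 maps reaches 1×1 after two pools).
- **Tie rules.** Binarization maps probability exactly 0.5 to foreground;
  class prediction breaks softmax ties toward the lower class index.
- **Metric edge cases.** 0/0 rates (e.g. precision with no positive
  predictions) are reported absent with a warning rather than coerced to
  0 or 1, so experiment means are not biased. JSI is the standard
  `|A∩B|/|A∪B|` and recall the standard `TP/(TP+FN)`; the identity
  `DC = 2·JSI/(1+JSI)` (hence `JSI ≤ DC`) is enforced by tests.
- **Split protocols.** Two presets: 63/17/20 (segmentation protocol) and
  72/8/20 (classification protocol, the default). Stratified splitting
  allocates per class by largest remainder, so per-class counts are exact
  to the nearest integer. A plain k-fold driver exists as well; neither
  is claimed to be canonical.
- **Augmentation family.** Horizontal/vertical flips, 90° rotations,
  integer translations up to 3 px (zero-filled), and image-only intensity
  jitter (scale 0.9–1.1, shift ±0.05), applied jointly to image and
  masks, seed-controlled. The first of `factor` versions is always the
  original. This family is sufficient to populate a ×32 expansion with
  distinct samples.

## The numpy engine

No deep-learning framework is used. `gramnet.nn` implements the layers
with explicit forward/backward passes: convolution as an im2col matrix
product (stride 1, odd kernels, 'same' zero padding; the input gradient
is itself a correlation with the flipped, channel-transposed kernel),
batch norm with running statistics, first-match 2×2 max-pool backward,
and Adam with plain L2 added to the gradient. Arrays are float32 in
training; layers preserve float64 inputs so tests can run finite-
difference checks at tight tolerances. All initialization is
Kaiming-normal from an explicit `numpy` Generator, making every training
run bit-reproducible for a fixed seed (single-threaded numpy).

## The phantom generator

Each phantom is an ellipse of "parenchyma" (intensity 0.60) with random
center, semi-axes (22–38 % of the image side) and orientation, on a 0.15
background, containing 0–2 circular tumors (radius 4–10 % of the side)
placed wholly inside the liver via a Euclidean distance transform. Tumor
contrast is drawn from −0.35 to −0.15 (hypodense by default; a positive
range gives hyperdense tumors). The image is smoothed (σ = 0.7), Gaussian
noise (σ = 0.03) is added, and intensities are clipped and quantized to
the 8-bit grid so PNG round-trips are bit-exact. Configuration validation
enforces `|contrast| > 2·noise_sd`, which guarantees the downstream
learning tasks are solvable — that is what the solvability tests verify,
and all they verify. A second channel (a smoothed contrast-stretched
copy) stands in for auxiliary perfusion-style inputs; it is a synthetic
placeholder, not a model of perfusion imaging.

With `n_tumors = (0, 2)` uniform, about one third of slices are benign,
comparable to the tumor prevalence of public liver-CT collections. The
default 2346 train + 392 test manifest mirrors the reference bookkeeping
(2738 slices total).

What the phantoms do **not** model: CT physics and Hounsfield units, 3-D
anatomical continuity across slices, organ-boundary ambiguity,
low-contrast lesions, scanner artifacts, or inter-patient variability.
Passing the phantom suites therefore demonstrates the pipeline's
correctness and trainability, not clinical segmentation or classification
performance; scores on real CT data will be substantially lower.

## Desk-scale problem sizes

The test and acceptance harnesses choose sizes that keep full runs in the
minutes range on one CPU core while remaining solvable and non-trivial:
classification uses 400 phantoms at 32×32 (288/32/80 split, 12 epochs per
stage, batch 16); segmentation uses 200 phantoms at 128×128
(160/20/20, 2 epochs, batch 8) with a reduced-width model
(`encoder_depth 3`, decoder channels 32/16/8). The full-width
five-stage decoder and 512×512 inputs are reachable through configuration.

## Known limitations

- Convolutions are stride-1 with odd kernels only; downsampling is by
  pooling. The engine favors clarity and testability over speed and has
  no GPU path.
- Table-style parameter accounting is reproducible only for SubNet B
  (387,520 ≈ 0.390 M with a 32-channel input, conv weights + biases);
  published totals for the other presets are not reconcilable with their
  printed filter banks under any obvious counting convention, and no
  reference multiply-add resolution is known, so `count_madd` documents
  its own convention (output pixels × kernel volume × channel product).
- The real-data loaders (per-slice DICOM, NIfTI volume pairs) follow the
  public dataset layouts but are exercised against synthetic files only.
- Graphs are nested series/parallel compositions with a single head;
  arbitrary DAGs and architecture search are out of scope.
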