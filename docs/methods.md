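# Methods

This note records the models, procedures and design choices implemented in
`lemonsurf`, including the decisions that were genuinely open and how they
were settled. Every number quoted here is computed by the package's tests
or by `scripts/acceptance.py`.

## 1. Detector family

### Baseline

The baseline is the public nano-scale layout of the YOLOv8-family
one-stage detector, reproduced layer by layer:

* backbone: stem conv (s2) → conv s2 → C2f×1 → conv s2 → C2f×2 → conv s2 →
  C2f×2 → conv s2 → C2f×1 → SPPF (5×5, three chained pools). Widths follow
  the 64/128/256/512/1024 template scaled by `width_multiple = 0.25`
  (rounded up to multiples of 8, capped at `max_channels = 1024` before
  scaling), giving 16/32/64/128/256 channels; repeats are scaled by
  `depth_multiple = 0.33`.
* neck: FPN top-down (upsample + concat + C2f) to stride 8, PAN bottom-up
  (stride-2 conv + concat + C2f) back to stride 32.
* head: decoupled per level. Box branch: two 3×3 conv blocks into a 1×1
  conv emitting 4×16 logits (distribution-focal regression, `reg_max`
  = 16, expectation decoding); class branch: two 3×3 conv blocks into a
  1×1 conv with one logit per class. Branch widths follow the public rule
  `c_box = max(16, ch₀/4, 64)`, `c_cls = max(ch₀, min(nc, 100))`.

Every conv block is conv (no bias) + BatchNorm (eps 1e-3, momentum 0.03)
+ SiLU. BatchNorm scale/shift are trainable and counted; running
statistics are buffers and are not. The fixed DFL projection
(0, 1, …, 15) is a constant, not a parameter. With two classes this
baseline has exactly **3,011,222** trainable parameters (3.01 M).

### Switchable atrous convolution (SAC)

A plain convolution with kernel `w` becomes

    y = S(x) · Conv(x, w, 1) + (1 − S(x)) · Conv(x, w + Δw, r)

with atrous rate `r = 3` by default (`r` is a config hyperparameter with
no canonical value; 3 gives a 2-cell dilation step inside 3×3 kernels).
Properties the implementation guarantees and the tests assert:

* **weight lock** — the dilated branch kernel is always `w + Δw`; there is
  no independent second kernel to drift during training;
* the switch is a 5×5 average pool → 1×1 conv → sigmoid, one channel,
  same spatial size, values strictly inside (0, 1); the output is an
  elementwise interpolation of the two branches;
* `Δw` is initialised to zero and the switch conv to zero weights and
  bias, so training starts from plain-conv behaviour at `S = 0.5`;
* stride is fixed at 1 and both branches use "same" padding
  (`r·(k−1)/2` on the dilated branch).

A full SAC convolution is pre-context → switched component →
post-context, where each global-context module is a global average pool →
channel-preserving 1×1 conv (bias, zero-initialised weights) → broadcast
residual add: the minimal form that injects image-global information
while starting as the identity.

**Placement.** C2f-SAC converts the two bottleneck 3×3 convolutions of a
C2f block to SAC; `use_sac` applies it to the deepest backbone stage
(stage 4, 256 channels). Placement was settled by the family's parameter
budget: converting only the 1×1 transition convolutions cannot reach the
budget (all four stages together add just 0.26 M), whereas the stage-4
bottlenecks add 0.361 M and land the full model on its printed 3.35 M
budget. The placement is recorded in the variant YAML (`sac_stages`).

### CBAM

Channel attention: shared bias-free two-layer MLP (C → C/8 → C, ReLU
between) applied to the global-average and global-max descriptors, summed,
sigmoid. Spatial attention: 3×3 conv (with bias) over the 2-channel
stack of channel-mean and channel-max maps, sigmoid. Applied channel gate
first, then spatial gate — the canonical order, pinned by a regression
test. Ratio 8 and the 3×3 spatial kernel are the family's stated values;
the bias-free MLP keeps the attention budget tight.

**Placement:** one CBAM after every C2f output (backbone and neck) and
after SPPF. On the baseline topology this adds 63,915 parameters
(→ 3.08 M); on the SOD topology 65,233 (the P2 neck has two more C2f
outputs).

### Small-object (P2 / SOD) path

The top-down pass is extended by one more upsample + concat with the
backbone's stride-4 tap (pre-scaling width 64; 160×160 at 640 px input)
and a C2f fuse producing the stride-4 head input (pre-scaling width 128,
i.e. 160×160×128 at 640). A stride-2 conv re-links P2 into the P3 fusion
and the bottom-up chain continues unchanged, so P3–P5 spatial sizes are
untouched. The four-level head re-derives its branch widths from the new
shallowest level (`c_cls` drops from 64 to 32 with two classes), which is
why the SOD variant is *smaller* than the baseline: 2,926,808 parameters
(2.93 M). Inputs must be divisible by 64 when SOD is on so the P2 grid
stays integral through the extra up/down path.

### Parameter budgets (all eight variants, nc = 2)

| sac | sod | cbam | parameters | M |
|-----|-----|------|-----------:|----:|
|     |     |      | 3,011,222 | 3.01 |
|     |     | ✓    | 3,075,137 | 3.08 |
|     | ✓   |      | 2,926,808 | 2.93 |
|     | ✓   | ✓    | 2,992,041 | 2.99 |
| ✓   |     |      | 3,372,440 | 3.37 |
| ✓   |     | ✓    | 3,436,355 | 3.44 |
| ✓   | ✓   |      | 3,288,026 | 3.29 |
| ✓   | ✓   | ✓    | 3,353,259 | 3.35 |

Counts are invariant to input size, batch size and seed; the three deltas
are additive by construction (SAC and CBAM live in or around blocks that
exist in every variant).

## 2. Decoding, NMS and letterboxing

Box decoding takes the softmax expectation of each 16-bin edge
distribution, scales by the level stride around cell centres, and clips to
the input canvas. NMS is class-wise greedy by descending confidence with
an IoU threshold; defaults are conf 0.25 / IoU 0.7 for prediction and
conf 0.001 / IoU 0.7 (max 300 detections per class and image) for mAP
evaluation — conventional operating points, all config-exposed.
Arbitrary images are letterboxed (aspect-preserving resize, grey padding
value 114, bilinear).

## 3. Training

AdamW with decoupled weight decay; "momentum 0.9" is read as beta1 (the
only coherent reading for an Adam-family optimizer), beta2 = 0.999.
Decay (5e-4) applies to convolution kernels only, not to norm scales or
biases. Defaults: lr₀ = 0.001667 decayed linearly to 1 % over the run,
batch 8, 200 epochs, 640 px input. Warmup, weight EMA and early stopping
are off (config-exposed). No mosaic or colour augmentation; horizontal
flip behind a flag, off by default.

Losses: binary cross-entropy on class logits against soft target scores;
complete-IoU on decoded boxes; distribution-focal cross-entropy against
the two bins bracketing each true edge distance. Weights 7.5 / 0.5 / 1.5
(box / cls / dfl), normalised by the summed target scores and scaled by
batch size. Targets come from a task-aligned assigner: candidate cells
must contain the box centre, are scored by `score^0.5 · IoU^6`, the top
10 per ground truth are kept, and a cell claimed twice goes to the
higher-IoU ground truth. Degenerate inputs (duplicate boxes, empty
images) assign without error; a non-finite loss aborts the step and a
loss above 1e4 aborts the run with the history dumped.

Per-epoch loss history is always recorded; mAP is evaluated every
`eval_interval` epochs (default: final epoch only — a full-set evaluation
per epoch would dominate CPU runtime at small scale).

Checkpoints are self-describing (`.npz` holding weights, BatchNorm
buffers, optimizer moments and the variant config); resuming an
interrupted run reproduces the uninterrupted run's next-epoch loss, which
the test suite asserts.

## 4. Dataset plumbing

**Label format.** One text file per image, `class cx cy w h` normalised to
[0, 1]; class 0 = healthy lemon, 1 = diseased. Pixel boxes are half-open
`[x_min, x_max)`, all internal math 0-based. Reads validate ranges and
report offending line numbers; a missing file is an empty image with a
warning. Round-trips are exact to 6 decimals.

**Tiling.** High-resolution images are cropped to 1024×1024 windows
centred on each target's centroid and clamped to the image bounds;
windows that clamp to an origin already emitted are merged, so co-located
targets share one tile. Labels are regenerated in window coordinates;
boxes clipped by a window edge keep their class, are edge-flagged, and are
kept only if ≥ 30 % visible (`min_visibility`, config-exposed — the
source procedure preserves clipped boxes but states no threshold).
Un-flagged boxes map back to source pixels exactly (asserted over 50
seeded 3000×2000 scenes). Images smaller than the tile pass through
untiled. Whether the original pipeline emitted overlapping or multiple
tiles per target is not recoverable from its description; the
one-window-per-distinct-origin rule is this package's choice.

**Folds.** Deterministic, seeded 5-fold plans: images are stratified by
presence of the diseased class (so every fold sees both classes, matching
the published split structure), shuffled within strata, and dealt
round-robin; fold sizes differ by at most one. Per-fold per-class
instance tables are provided for bookkeeping. Fold metrics are summarised
as μ = mean and σ = population (divide-by-5) standard deviation — the
population form is the definition used by the source protocol, not the
sample (divide-by-4) form.

## 5. Metrics

Greedy one-to-one matching by descending confidence; a detection is a TP
iff it shares the class of, and has IoU ≥ threshold with, an unmatched
ground truth (highest IoU wins, ties to the lower index). Precision =
TP/(TP+FP), Recall = TP/(TP+FN). AP integrates the precision–recall
curve with the monotone precision envelope (all-point interpolation;
101-point step grid available). mAP is the unweighted class mean; classes
with no ground truth are excluded rather than scored zero. mAP@50–95
averages over IoU 0.50:0.05:0.95. The AP implementation is checked
exactly against an independent brute-force enumerator on 500 random small
instances, and TP/FP/FN visualisation renders detections green (TP) or
red (FP) and missed ground truths blue.

## 6. Synthetic scenes

The generator emulates the statistics of the field dataset the detector
family was designed for: canvases from 640 to 3000 px, 1–6 fruit targets
per scene, a diseased-instance share of 14.3 % (the share in the
published per-fold instance tables), occasional leaf-like occluders
(probability 0.3 per fruit), and a global illumination gain of 0.65–1.25
with a mild vertical gradient. Fruits are shaded ellipses in a yellow hue
band that never occurs in the foliage background; diseased fruits carry
1–6 dark lesion blobs totalling 5–30 % of fruit area (disease is a
property of the whole fruit — there are no separate lesion boxes). Ground
truth tightly bounds the *visible* extent: occluded pixels are excluded,
and targets that would be > 95 % occluded are resampled. Everything is
deterministic under the spec seed.

Two deliberate simplifications keep ground truth verifiable: fruits never
touch (placement enforces a 5 px separation margin), and fruit/lesion
colours are chosen so an independent colour-mask detector recovers every
label with IoU ≥ 0.8 (a generator self-check in the suite). Real orchard
images violate both (fruit clusters, colour ambiguity with sunlit
foliage), and the renderer makes no attempt at photorealism or at
modelling specific lemon pathogens. Tests passing on these scenes
therefore demonstrate that the pipeline is mechanically and numerically
correct, not that the detector reaches field accuracy; the published
field accuracies require the original (non-deposited) orchard data and
GPU-scale training, and are out of scope here.

## 7. Numerical core and problem sizes

The network runs on a small reverse-mode autodiff engine over float32
NumPy arrays written for this package. Convolutions use one GEMM per
kernel tap (shift-accumulate) at stride 1, a plain GEMM for 1×1, and
im2col for strided convolutions; all gradients are verified against
central differences in the suite. Weight init is fan-in-scaled uniform
from a single seeded stream, so builds are bit-reproducible; head biases
start at the standard detection priors (box offsets near one stride unit,
class logits at log(5/nc/cells)).

The suite's training smoke test uses the full variant on 8 scenes at
256 px for 200 full-batch iterations with the default hyperparameters and
requires train-set mAP@50 ≥ 0.8 — the scale at which "the model can
memorise what it is shown" is a meaningful CPU-scale check of the whole
loop. BatchNorm running statistics (momentum 0.03) converge only near the
end of those 200 steps, so eval-mode accuracy appears late; that is
expected behaviour, not a plateau.

## 8. Known limitations

* Single-process, CPU-only training; no multi-GPU, EMA, AMP or export.
* The assigner is the task-aligned scheme in its plain form (no
  centre-radius prior beyond "inside the box").
* The σ reported for folds is the population form by definition; with 5
  folds it understates the sample standard deviation by √(5/4).
* SAC-only and SAC+CBAM budgets (3.37 / 3.44 M) are fixed consequences of
  the single backbone placement that pins the other six variants.
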