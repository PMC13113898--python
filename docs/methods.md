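# Methods

## Problem setting

One axis-aligned box per image over the tailhead region of a single beef
animal, with a 5-way ordinal class label (BCS 3–7 mapped to class ids 0–4).
The detector family is anchor-free with three prediction scales (strides
8/16/32) and distribution-focal box regression (`reg_max` = 16 bins per box
side, distances in stride units from the cell center).

## Architecture and its free dimensions

The baseline follows the published nano scaling of its donor family
(width ×0.25, depth ×0.50, channels 16/32/64/128/256; C3k2 stages, SPPF,
C2PSA, concatenation PAN neck, decoupled head with a depthwise-separable
classification branch). It has no free widths; our reconstruction counts
2,590,799 parameters at 5 classes.

The redesigned model replaces (i) neck concatenation with gated fusion at
one constant width, (ii) stage bottlenecks with star blocks, (iii) the head
with grouped convolutions. Two dimensions are genuinely free and were
calibrated once against the published complexity figures (the calibration
scan ships as `scripts/calibrate.py`):

- **Neck width 64.** "Constant channel dimensions" is read as a single
  width shared by all pyramid levels and fusion nodes; laterals reach it
  through 1×1 projections, resampling convs map onto it directly. This is
  the only reading whose parameter budget matches the published ablation
  ladder.
- **Star expansion (4, 4, 2, 1) through the backbone stages and 4 in the
  neck.** The branch width C′/C shrinks with depth: wide second-order
  texture mapping where spatial resolution (and texture) lives, narrow at
  the 20×20 stage where channels are many and FLOPs are cheap but
  parameters are not.

Decisions on points the design leaves open, all surfaced in config:

- Coordinate attention: reduction ratio 32 with an 8-channel floor on the
  shared transform; the shared 1×1 carries BN (hence no bias), the two
  restoring 1×1s carry bias and no BN; the pooled height descriptor
  precedes the width descriptor in the concatenation and the split follows
  the same order.
- Bias placement follows one rule everywhere: bias on convolutions not
  followed by BN, none where BN follows (star `W₁, W₂, W_out`, the output
  depthwise conv, gate convs and prediction convs carry bias).
- Gates in fusion nodes are full per-node 1×1 convolutions (not per-channel
  scalars); the gate always reads the resampled incoming stream; coordinate
  attention calibrates only the lateral stream.
- EGDH: α is a per-level scalar initialised to 1; the stem activations are
  SiLU; the refinement conv carries BN and no activation; prediction convs
  are unnormalised 1×1s. Channels not divisible by the group width 16 pass
  through a 1×1 adapter first (only relevant at the tiny test width).
- Head box encoding is the family's distribution-focal convention, since
  the redesign replaces the head of that family.

## Complexity accounting

GFLOPs = 2 × multiply-accumulates, summed layerwise over conv/matmul
kernels on the conv-BN-fused inference graph at a 640×640×3 input.
Elementwise work (activations, gates, residual sums) is excluded from the
headline figure; the profiler still tallies it separately. Serialized size
counts every learnable parameter plus the BN running statistics needed for
inference, at 2 bytes each (fp16), divided by 10⁶. Under these frozen
conventions the baseline profiles at 6.375 GFLOPs / 5.2 MB and the full
model at 4.690 GFLOPs / 3.3 MB; variant GFLOPs and sizes decrease
monotonically along the ablation ladder (5.438/3.9 with the gated neck,
5.621/3.7 adding star stages). Conv-BN fusion is exact (folded scale/shift
per output channel, groupwise for grouped convs) and is verified against
the unfused composite to 1e-5.

## Numerical engine

All layers run on a compact reverse-mode autograd over numpy arrays:
convolution via im2col/col2im (grouped via batched matmul), transposed
convolution as the adjoint scatter, max-pooling with argmax routing, batch
norm with batch statistics in training and running statistics (momentum
0.03, eps 1e-3) at inference. Every primitive's gradient is checked against
central finite differences in the test suite. Forward passes in inference
mode are deterministic bitwise; parameter initialisation draws from a
seeded generator, so builds with the same seed are identical.

## Data rules and the synthetic generator

The dataset-construction rules of the source protocol are implemented
exactly: stride-3 frame retention; directional motion blur by convolution
with a normalized line kernel (length uniform on 21–32 px at source
resolution, angle recorded per image; 35 px kept as an explicit stress
setting, never training augmentation; reflected borders); an 8:2
animal-level split drawn within each class (round-half-up, at least one
validation animal per class of ≥2 when the ratio is below 1), with every
image of an animal — clear or blurred — in one split.

The generator emulates the study material only structurally: one textured
ellipse per frame on a structured background, a tailhead sub-box whose
local texture amplitude rises monotonically with the class, bright/dim
sessions, optional blur, deterministic under a seed. It does not emulate
real cattle appearance, pose variation, occlusion, multi-animal scenes or
annotation noise — so green detection tests demonstrate that the pipeline
learns and evaluates correctly, not that field accuracy is reproduced. The
published mAP/precision/recall on the private UAV dataset are explicitly
not reproduction targets.

## Training

Defaults follow the study recipe: SGD, lr 0.01 with linear decay to 1%,
momentum 0.937, weight decay 5e-4, 3 warmup epochs, batch 16, 640 input,
HSV jitter 0.015/0.7/0.4, translate 0.1, scale 0.5, horizontal flip 0.5,
mosaic probability 1.0 for all 100 epochs, NMS IoU 0.7 at validation.
Gradient norms are clipped at 10. Mosaic composes four images on a 2× canvas
and rescales; the geometric jitter is scale+translation (no shear/rotation,
which the recipe does not use).

The loss is the family composite the redesign plugs into: task-aligned
assignment (top-10 candidates per truth among cells whose centers fall
inside it, ranked by `score^0.5 · IoU^6`, ties to the highest-overlap
truth), CIoU box loss, BCE classification against IoU-normalised soft
targets, and a distribution-focal term over the two bins bracketing each
target distance; weights 7.5/0.5/1.5. Because the soft targets are scaled
by the current best IoU, the reported loss is not monotone early in
training: it starts low, inflates while assignments bootstrap, then
descends.

Desk-scale runs (tiny width ×0.125, 128-px inputs, 32 images, 150 epochs,
batch 8) use the family trainer's small-dataset choice of AdamW at lr 2e-3:
at these step counts SGD at the full-scale lr is unstable. Such a run
memorises its training set to mAP@50 = 1.0 in about two minutes on one CPU;
this is the package's end-to-end sanity bar, chosen to keep the default
suite fast.

## Distillation

The focal branch builds, per neck level and image: a binary mask (cell
center inside any truth box), a scale mask weighting foreground cells by
the inverse cell-area of their smallest covering box and background cells
by the inverse background area, and spatial/channel attention maps as
tempered softmaxes (T = 0.5) of the teacher's mean absolute activations,
normalised to sum to H·W and C. The loss weights the squared
teacher–student feature difference by all of these, separately for
foreground (1.6e-3) and background (8e-4), adds an L1 attention-transfer
term (8e-4) between student and teacher attentions, and a global term
(8e-6) matching a shared trainable global-context aggregation of both
features. This loss algebra is the largest reconstruction-from-citation in
the package: the source describes the scheme qualitatively and the exact
algebra follows the cited distillation method, with every weight and the
temperature exposed in `DistillConfig`. Teacher features are computed with
batch statistics (buffers frozen) so teacher and student normalisation
behave identically; all distillation parameters (adapter, context block)
live outside the detector and never affect its inference graph or
complexity report.

## Evaluation conventions

IoU on half-open pixel boxes; class-aware greedy NMS (descending
confidence, earlier index on ties, suppression strictly above the
threshold, default 0.7); matching greedy by confidence with best-IoU
tie-breaking, each truth used once; AP by 101-point interpolated
precision-recall (chosen where the source prints only the integral);
mAP@50:95 averages the 10-cut IoU grid; precision/recall reported as
percentages; theoretical FPS = 1000 / latency(ms) to two decimals. With no
detections precision is reported as 0 and flagged undefined rather than
raising.

## Known limitations

- The numpy engine is single-threaded-BLAS fast, not GPU fast: full-scale
  640-px training is out of reach; training is validated at desk scale.
- The baseline profiles at 6.375 GFLOPs against the published 6.3 (+1.2%);
  the baseline topology has no free widths to calibrate, so the residual is
  documented rather than tuned away.
- ONNX export and engine compilation are not implemented.
- The synthetic class signal (texture amplitude) is far cleaner than real
  fat-cover cues; expect every detection metric on it to be optimistic.
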