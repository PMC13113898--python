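# edgebcs

Lightweight tailhead detection and body-condition scoring (BCS) for beef
cattle, built as a from-scratch, fully tested reconstruction of an
edge-oriented single-stage detector.

Body condition scoring grades the subcutaneous fat reserves of cattle on a
9-point scale by inspecting anatomical regions — above all the tailhead at
the base of the tail. Automating it from overhead RGB imagery turns a slow,
contact-based, subjective assessment into a camera task, but farm deployment
demands models small enough for embedded hardware and robust to motion blur
and changing illumination. This package implements such a detector family
end to end: the network blocks, the dataset-construction rules, training
with optional feature distillation, complexity accounting and the full
detection-metric stack — all in numpy, with no deep-learning framework
dependency, so every operation is inspectable and exactly testable.

## The model

The detector is an anchor-free, three-scale (strides 8/16/32) network in the
YOLO11-nano mould, with three redesigned components:

- **PSFF (position-sensitive feature fusion).** The neck abandons channel
  concatenation. At every fusion node the lateral stream `L` is calibrated
  by coordinate attention and gated multiplicatively by the resampled deep
  stream `U`:

  `F = CA(L) ⊙ σ(Conv1×1(U)) + U`

  with coordinate attention `y_c(i,j) = x_c(i,j) · g^h_c(i) · g^w_c(j)`
  built from direction-wise average pooling
  `z^h_c(h) = (1/W) Σ_i x_c(h,i)`, `z^w_c(w) = (1/H) Σ_j x_c(j,w)`.
  Channel width stays constant (64) through every node; upsampling is a
  learned stride-2 transposed convolution.

- **TASM (texture-aware star module).** Backbone and neck stages keep the
  C3k2 split/merge skeleton but replace each bottleneck with a star block:
  `Y = DWConv7×7(W_out · (relu6(W₁X_pre + b₁) ⊙ (W₂X_pre + b₂))) + X` on
  `X_pre = BN(DWConv7×7(X))`. The elementwise product of two linear
  projections generates second-order terms `x_i x_j` — an implicit
  high-dimensional map that keeps low-contrast fat texture separable — and
  the output depthwise conv deliberately carries no BN so the refined
  high-frequency response reaches the residual sum undistorted.

- **EGDH (efficient grouped detection head).** Per level: a stem of two
  grouped 3×3 convolutions at fixed group width 16 (`g = C/16`), fused with
  the identity through a learnable scalar α, one grouped refinement conv,
  and two plain 1×1 prediction convs (classes; 4·16 distribution-focal box
  bins). Grouping cuts head FLOPs by exactly `1/g`:
  `FLOPs_GC = H·W·K²·C²/g`.

Training uses the family's composite loss (task-aligned assignment, CIoU +
BCE + distribution-focal terms) and, optionally, focal+global feature
distillation from a frozen larger teacher: ground-truth boxes rasterize into
binary/scale masks, teacher-derived attention focuses a foreground/background
feature-matching loss, and a shared global-context block matches long-range
structure — none of which touches the inference graph.

## Worked example

```python
from edgebcs import ModelConfig, build_model, complexity_report

for variant in ("baseline", "psff", "psff-tasm", "full"):
    print(complexity_report(build_model(ModelConfig(variant=variant)), 640))
```

prints

```
baseline: 2,590,799 params, 6.4 GFLOPs, 5.2 MB (fp16)
psff: 1,922,351 params, 5.4 GFLOPs, 3.9 MB (fp16)
psff-tasm: 1,824,319 params, 5.6 GFLOPs, 3.7 MB (fp16)
full: 1,656,898 params, 4.7 GFLOPs, 3.3 MB (fp16)
```

— the ablation ladder at a 640×640 input: GFLOPs are multiply-accumulates
×2 counted layerwise on the conv-BN-fused inference graph, and the size is
every learnable parameter plus BN statistic serialized at fp16. The gated
neck removes most of the parameters; the grouped head most of the remaining
FLOPs (unrounded: 6.375 → 4.690 GFLOPs baseline → full).

The `examples/` directory holds one short script per capability
(complexity ladder, synthetic data + blur rules, end-to-end tiny training,
distillation mechanics), and the `edgebcs` CLI exposes
`synth / train / eval / profile / blur`:

```bash
edgebcs synth --animals 10 --out data/ --seed 0
edgebcs train --variant full --scale t --data data/ --imgsz 128 --epochs 50
edgebcs profile --variant full
```

## Scope

The private UAV dataset of the source study is out of reach, so detection
quality is exercised on the package's deterministic synthetic imagery
(texture-encoded class signal), not reproduced on real cattle; TensorRT
engine building and on-device latency are likewise out of scope. See
`docs/methods.md` for the model assumptions, parameter choices, and what the
synthetic results do and do not show.
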