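"""Complexity accounting across the ablation ladder.

Builds the four model variants — the nano baseline, the gated-fusion neck
(PSFF), plus star-operation stages (TASM), plus the grouped head (EGDH) —
and prints parameters, GFLOPs at 640x640 (multiply-accumulates x 2 on the
conv-BN-fused graph) and the fp16 checkpoint size.  The ladder shows where
the lightweighting comes from: the neck sheds most of the parameters, the
head most of the remaining FLOPs.
"""

from edgebcs import ModelConfig, build_model, complexity_report

for variant in ("baseline", "psff", "psff-tasm", "full"):
    model = build_model(ModelConfig(variant=variant, scale="n", nc=5))
    print(complexity_report(model, 640))
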