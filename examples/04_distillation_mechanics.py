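"""Focal+global feature distillation mechanics on one feature pair.

Builds the distillation masks from a ground-truth box (binary foreground
mask, inverse-area scale mask, teacher-derived spatial/channel attention)
and evaluates the loss for a random student against a random teacher and at
teacher equality.  The loss is zero exactly when the student matches the
teacher, and only the training graph carries distillation parameters.
"""

import numpy as np

from edgebcs import DistillConfig, build_focal_masks, FGDLoss
from edgebcs.autograd import Tensor

rng = np.random.default_rng(0)
teacher = rng.standard_normal((64, 20, 20)).astype(np.float32)
student = rng.standard_normal((64, 20, 20)).astype(np.float32)

masks = build_focal_masks([(40, 48, 96, 120)], (64, 20, 20), teacher,
                          stride=8)
print(f"foreground cells: {int(masks.binary.sum())} / 400, "
      f"spatial attention sums to {masks.spatial.sum():.1f} (= H*W)")

loss_mod = FGDLoss(64, 64, DistillConfig())
total, parts = loss_mod(Tensor(teacher), Tensor(student), masks)
print("random student :", {k: round(v, 6) for k, v in parts.items()})
total, parts = loss_mod(Tensor(teacher), Tensor(teacher), masks)
print("perfect student:", {k: round(v, 6) for k, v in parts.items()})
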