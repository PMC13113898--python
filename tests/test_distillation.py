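"""Focal/global feature distillation: masks, loss algebra, contracts."""

import numpy as np
import pytest

from edgebcs import DistillConfig, build_focal_masks, FGDLoss
from edgebcs.autograd import Tensor


@pytest.fixture()
def teacher_feature(rng):
    return rng.standard_normal((4, 8, 8)).astype(np.float32)


class TestMasks:
    def test_full_image_box(self, teacher_feature):
        masks = build_focal_masks([(0, 0, 64, 64)], (4, 8, 8),
                                  teacher_feature, stride=8)
        assert np.all(masks.binary == 1.0)
        np.testing.assert_allclose(masks.scale, 1.0 / 64)

    def test_uniform_teacher_gives_flat_attention(self):
        masks = build_focal_masks([(0, 0, 32, 32)], (4, 8, 8),
                                  np.ones((4, 8, 8)), stride=8)
        np.testing.assert_allclose(masks.spatial, 1.0, atol=1e-6)
        np.testing.assert_allclose(masks.channel, 1.0, atol=1e-6)
        assert abs(masks.spatial.sum() - 64) < 1e-4
        assert abs(masks.channel.sum() - 4) < 1e-4

    def test_two_disjoint_boxes_match_rasterization_oracle(self,
                                                           teacher_feature):
        boxes = [(0, 0, 24, 16), (40, 40, 64, 64)]
        masks = build_focal_masks(boxes, (4, 8, 8), teacher_feature, stride=8)
        want = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                cx, cy = (j + 0.5) * 8, (i + 0.5) * 8
                for (x1, y1, x2, y2) in boxes:
                    if x1 <= cx < x2 and y1 <= cy < y2:
                        want[i, j] = 1
        np.testing.assert_array_equal(masks.binary, want)

    def test_empty_image(self, teacher_feature):
        masks = build_focal_masks([], (4, 8, 8), teacher_feature, stride=8)
        assert np.all(masks.binary == 0)
        np.testing.assert_allclose(masks.scale, 1.0 / 64)

    def test_scale_uses_smallest_covering_box(self, teacher_feature):
        big = (0, 0, 64, 64)
        small = (0, 0, 16, 16)
        masks = build_focal_masks([big, small], (4, 8, 8), teacher_feature, 8)
        assert masks.scale[0, 0] == pytest.approx(1.0 / 4)    # 2x2 cells
        assert masks.scale[7, 7] == pytest.approx(1.0 / 64)


class TestLoss:
    def test_zero_at_teacher_equality(self, rng, teacher_feature):
        masks = build_focal_masks([(8, 8, 40, 40)], (4, 8, 8),
                                  teacher_feature, 8)
        loss_mod = FGDLoss(4, 4)
        f = Tensor(teacher_feature)
        total, parts = loss_mod(f, f, masks)
        assert parts["focal_fg"] == 0 and parts["focal_bg"] == 0
        assert parts["attention"] == pytest.approx(0, abs=1e-6)
        assert parts["global"] == 0
        assert total.item() == pytest.approx(0, abs=1e-6)

    def test_all_weights_zero(self, rng, teacher_feature):
        cfg = DistillConfig(alpha_fg=0, beta_bg=0, gamma_at=0, lambda_gl=0)
        masks = build_focal_masks([(8, 8, 40, 40)], (4, 8, 8),
                                  teacher_feature, 8, cfg)
        loss_mod = FGDLoss(4, 4, cfg)
        student = Tensor(rng.standard_normal((4, 8, 8)).astype(np.float32))
        total, _ = loss_mod(Tensor(teacher_feature), student, masks)
        assert total.item() == 0.0

    def test_linear_in_weights(self, rng, teacher_feature):
        student = rng.standard_normal((4, 8, 8)).astype(np.float32)
        masks = build_focal_masks([(8, 8, 40, 40)], (4, 8, 8),
                                  teacher_feature, 8)
        cfg1 = DistillConfig()
        cfg2 = DistillConfig(alpha_fg=2 * cfg1.alpha_fg,
                             beta_bg=2 * cfg1.beta_bg,
                             gamma_at=2 * cfg1.gamma_at,
                             lambda_gl=2 * cfg1.lambda_gl)
        m1, m2 = FGDLoss(4, 4, cfg1), FGDLoss(4, 4, cfg2)
        m2.load_state_dict(m1.state_dict())
        t1, _ = m1(Tensor(teacher_feature), Tensor(student), masks)
        t2, _ = m2(Tensor(teacher_feature), Tensor(student), masks)
        assert t2.item() == pytest.approx(2 * t1.item(), rel=1e-5)

    def test_focal_terms_match_loop_transcription(self, rng, teacher_feature):
        """Straight-line recomputation of the focal feature terms."""
        student = rng.standard_normal((4, 8, 8)).astype(np.float32)
        masks = build_focal_masks([(8, 8, 40, 40)], (4, 8, 8),
                                  teacher_feature, 8)
        cfg = DistillConfig()
        mod = FGDLoss(4, 4, cfg)
        _, parts = mod(Tensor(teacher_feature), Tensor(student), masks)
        fg = bg = 0.0
        for c in range(4):
            for i in range(8):
                for j in range(8):
                    d2 = (teacher_feature[c, i, j] - student[c, i, j]) ** 2 \
                        * masks.spatial[i, j] * masks.channel[c] \
                        * masks.scale[i, j]
                    if masks.binary[i, j]:
                        fg += d2
                    else:
                        bg += d2
        assert parts["focal_fg"] == pytest.approx(cfg.alpha_fg * fg, rel=1e-4)
        assert parts["focal_bg"] == pytest.approx(cfg.beta_bg * bg, rel=1e-4)

    def test_channel_adapter_bridges_mismatch(self, rng, teacher_feature):
        masks = build_focal_masks([(8, 8, 40, 40)], (4, 8, 8),
                                  teacher_feature, 8)
        mod = FGDLoss(student_channels=6, teacher_channels=4)
        student = Tensor(rng.standard_normal((6, 8, 8)).astype(np.float32))
        total, _ = mod(Tensor(teacher_feature), student, masks)
        assert np.isfinite(total.item()) and total.item() >= 0

    def test_shape_mismatch_without_adapter_raises(self, rng,
                                                   teacher_feature):
        masks = build_focal_masks([], (4, 8, 8), teacher_feature, 8)
        mod = FGDLoss(4, 4)
        with pytest.raises(ValueError):
            mod(Tensor(teacher_feature),
                Tensor(np.zeros((4, 4, 4), np.float32)), masks)


def test_inference_graph_free_of_distillation():
    """Distillation parameters never enter the detector's parameter list or
    its complexity report."""
    from edgebcs import ModelConfig, build_model, complexity_report
    model = build_model(ModelConfig(variant="full", scale="t", nc=5))
    before = {id(p) for p in model.parameters()}
    n_before = model.num_parameters()
    mod = FGDLoss(model.neck.out_channels[0], 32)
    assert all(id(p) not in before for p in mod.parameters())
    assert model.num_parameters() == n_before
    r1 = complexity_report(model, 64)
    r2 = complexity_report(model, 64)
    assert r1.gflops == r2.gflops and r1.params == r2.params
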