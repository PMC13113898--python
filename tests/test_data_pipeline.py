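"""Dataset rules: frame downsampling, blur, splitting, synthetic fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from edgebcs import (downsample_frames, motion_blur_kernel, apply_motion_blur,
                     animal_level_split, generate_synthetic_dataset)
from edgebcs.data import (BCS_CLASSES, STUDY_CLASS_COUNTS,
                          STUDY_IMAGES_PER_SESSION, STUDY_SESSIONS,
                          read_yolo_labels, load_image)


class TestFrameDownsampling:
    def test_stride_three(self):
        assert len(downsample_frames(range(90))) == 30
        assert downsample_frames(range(10)) == [0, 3, 6, 9]

    def test_single_frame(self):
        assert downsample_frames([42]) == [42]

    def test_study_arithmetic(self):
        """494 animals x 8 images x 2 sessions = 7904 retained images;
        merging 2658 blurred copies gives 10562."""
        n_animals = sum(STUDY_CLASS_COUNTS.values())
        assert n_animals == 494
        clear = n_animals * STUDY_IMAGES_PER_SESSION * len(STUDY_SESSIONS)
        assert clear == 7904
        assert clear + 2658 == 10562


class TestMotionBlur:
    def test_kernel_impulse_response(self):
        k = motion_blur_kernel(21, 0.0)
        row = k[(k.shape[0] - 1) // 2]
        assert np.count_nonzero(k) == 21
        np.testing.assert_allclose(row[row > 0], 1 / 21)

    @given(length=st.integers(1, 35), angle=st.floats(0, 180))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_kernel_always_normalized(self, length, angle):
        assert motion_blur_kernel(length, angle).sum() == pytest.approx(1.0)

    def test_constant_image_preserved(self):
        img = np.full((48, 64), 100.0)
        out = apply_motion_blur(img, 21, 33.0)
        np.testing.assert_allclose(out, 100.0, atol=1e-9)

    def test_matches_convolution_loop_oracle(self, rng):
        img = rng.random((12, 12))
        k = motion_blur_kernel(5, 30.0)
        got = apply_motion_blur(img, 5, 30.0)
        want = ndimage.convolve(img, k, mode="reflect")
        # independent dense loop on the interior (away from borders)
        kh = k.shape[0] // 2
        for i in range(kh, 12 - kh):
            for j in range(kh, 12 - kh):
                acc = sum(img[i + u - kh, j + v - kh] * k[u, v]
                          for u in range(k.shape[0]) for v in range(k.shape[0]))
                assert abs(got[i, j] - acc) <= 1e-6
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            apply_motion_blur(np.zeros((8, 8)), 50, 0.0)


def _manifest(counts):
    rows = []
    animal = 0
    for cls, n in counts.items():
        for _ in range(n):
            for img in range(3):
                rows.append(dict(image=f"a{animal}_{img}.png",
                                 animal_id=animal, session="morning",
                                 blurred=img == 2, bcs_class=cls, split=""))
            animal += 1
    return pd.DataFrame(rows)


class TestAnimalSplit:
    def test_exact_ratio_ten_animals(self):
        out = animal_level_split(_manifest({5: 10}), 0.8, seed=0)
        per_animal = out.groupby("animal_id")["split"].first()
        assert (per_animal == "train").sum() == 8
        assert (per_animal == "val").sum() == 2

    def test_seventeen_animals_rounding(self):
        out = animal_level_split(_manifest({3: 17}), 0.8, seed=0)
        per_animal = out.groupby("animal_id")["split"].first()
        assert (per_animal == "train").sum() == 14
        assert (per_animal == "val").sum() == 3

    def test_no_leakage_exhaustive(self):
        out = animal_level_split(_manifest(STUDY_CLASS_COUNTS), 0.8, seed=3)
        for animal, group in out.groupby("animal_id"):
            assert group["split"].nunique() == 1
        splits = set(out["split"])
        assert splits == {"train", "val"}

    def test_blurred_images_inherit_split(self):
        out = animal_level_split(_manifest({4: 6}), 0.8, seed=1)
        for _, g in out.groupby("animal_id"):
            assert g[g["blurred"]]["split"].iloc[0] \
                == g[~g["blurred"]]["split"].iloc[0]

    def test_deterministic_under_seed(self):
        m = _manifest({5: 9, 6: 7})
        a = animal_level_split(m, 0.8, seed=11)
        b = animal_level_split(m, 0.8, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestSyntheticGenerator:
    def test_counts_and_manifest_consistency(self, tiny_dataset):
        root, manifest = tiny_dataset
        clear = manifest[~manifest["blurred"]]
        assert len(clear) == 6 * 2 * 1           # animals x sessions x shots
        n_blur = manifest["blurred"].sum()
        assert n_blur == round(len(clear) / 3)
        assert set(manifest["session"]) == set(STUDY_SESSIONS)
        # labels parse and stay inside the unit square
        for _, row in manifest.iterrows():
            labels = read_yolo_labels(root / "labels" / row["split"]
                                      / (row["image"][:-4] + ".txt"))
            assert len(labels) == 1
            assert labels[0][0] == BCS_CLASSES.index(row["bcs_class"])

    def test_bitwise_deterministic(self, tmp_path):
        m1 = generate_synthetic_dataset(tmp_path / "a", n_animals=5,
                                        images_per_session=1, seed=9,
                                        image_size=(96, 96))
        m2 = generate_synthetic_dataset(tmp_path / "b", n_animals=5,
                                        images_per_session=1, seed=9,
                                        image_size=(96, 96))
        pd.testing.assert_frame_equal(m1, m2)
        for _, row in m1.iterrows():
            a = load_image(tmp_path / "a" / "images" / row["split"]
                           / row["image"])
            b = load_image(tmp_path / "b" / "images" / row["split"]
                           / row["image"])
            np.testing.assert_array_equal(a, b)

    def test_class_texture_contrast_monotone(self, tmp_path):
        """Local variance inside the labeled tailhead box grows with the
        class index — the signal that encodes body condition."""
        root = tmp_path / "mono"
        manifest = generate_synthetic_dataset(
            root, n_animals=10, images_per_session=2, blur_fraction=0.0,
            seed=5, image_size=(320, 240))
        var_by_class = {}
        for _, row in manifest.iterrows():
            img = load_image(root / "images" / row["split"] / row["image"])
            cls, cx, cy, w, h = read_yolo_labels(
                root / "labels" / row["split"]
                / (row["image"][:-4] + ".txt"))[0]
            H, W = img.shape[:2]
            x1, x2 = int((cx - w / 2) * W), int((cx + w / 2) * W)
            y1, y2 = int((cy - h / 2) * H), int((cy + h / 2) * H)
            patch = img[y1:y2, x1:x2, 0].astype(float)
            if row["session"] == "evening":
                patch = patch / 0.55             # undo the dim illumination
            var_by_class.setdefault(cls, []).append(patch.var())
        means = [np.mean(var_by_class[c]) for c in sorted(var_by_class)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_rejects_too_few_animals(self, tmp_path):
        with pytest.raises(ValueError):
            generate_synthetic_dataset(tmp_path, n_animals=3)
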