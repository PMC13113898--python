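"""Dataset construction rules and the synthetic fixture generator.

Implements the acquisition pipeline of the study this package reconstructs:
stride-3 frame downsampling of 30-FPS footage, directional motion-blur
augmentation with normalized line kernels of length 21-32, animal-level
8:2 train/validation splitting stratified by body-condition class (all
images of one animal, clear and blurred, share a split), YOLO-format label
I/O, and a deterministic synthetic image generator that emulates the study
material: one textured elliptical animal per frame viewed from above, a
labeled tailhead region whose texture amplitude encodes the class, two
illumination sessions (bright morning, dim evening) and optional motion
blur.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

# class id 0..4 maps to BCS 3..7
BCS_CLASSES = (3, 4, 5, 6, 7)
# cattle per class in the source study (sums to 494)
STUDY_CLASS_COUNTS = {3: 17, 4: 82, 5: 174, 6: 198, 7: 23}
STUDY_IMAGES_PER_SESSION = 8
STUDY_SESSIONS = ("morning", "evening")
BLUR_KERNEL_RANGE = (21, 32)
STRESS_BLUR_KERNEL = 35


def downsample_frames(frame_indices) -> list:
    """Keep one frame in every three (indices 0, 3, 6, ...)."""
    return list(frame_indices)[::3]


def motion_blur_kernel(length: int, angle_degrees: float) -> np.ndarray:
    """Normalized line kernel of ``length`` pixels at the given angle.

    The kernel sums to one, so blurring preserves the image mean.
    """
    if length < 1:
        raise ValueError("kernel length must be >= 1")
    size = int(length)
    k = np.zeros((size, size), dtype=np.float64)
    c = (size - 1) / 2.0
    theta = math.radians(angle_degrees)
    dx, dy = math.cos(theta), -math.sin(theta)
    half = (length - 1) / 2.0
    for t in np.linspace(-half, half, 4 * size + 1):
        i = int(round(c + t * dy))
        j = int(round(c + t * dx))
        if 0 <= i < size and 0 <= j < size:
            k[i, j] = 1.0
    return k / k.sum()


def apply_motion_blur(image: np.ndarray, kernel_length: int,
                      angle_degrees: float) -> np.ndarray:
    """Directional motion blur with reflected borders; shape-preserving."""
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape[:2]
    if kernel_length > math.hypot(h, w):
        raise ValueError("kernel longer than the image diagonal")
    k = motion_blur_kernel(kernel_length, angle_degrees)
    if img.ndim == 2:
        out = ndimage.convolve(img, k, mode="reflect")
    else:
        out = np.stack([ndimage.convolve(img[..., c], k, mode="reflect")
                        for c in range(img.shape[2])], axis=-1)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(np.asarray(image).dtype)
    return out.astype(np.asarray(image).dtype)


def animal_level_split(manifest: pd.DataFrame, ratio: float = 0.8,
                       seed: int = 0) -> pd.DataFrame:
    """Assign every animal (hence all its images) to train or val.

    Within each class the animal ids are shuffled deterministically and
    ``round(ratio * n)`` (half-up) go to train, with at least one animal in
    val whenever the class has two or more.  Returns a copy of the manifest
    with the ``split`` column filled.
    """
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = ""
    for cls, group in manifest.groupby("bcs_class"):
        animals = sorted(group["animal_id"].unique())
        if len(animals) == 0:
            continue
        order = rng.permutation(len(animals))
        n_train = int(math.floor(ratio * len(animals) + 0.5))
        if ratio < 1.0 and len(animals) >= 2 and n_train >= len(animals):
            n_train = len(animals) - 1   # at least one validation animal
        train_ids = {animals[i] for i in order[:n_train]}
        mask = out["bcs_class"] == cls
        out.loc[mask, "split"] = [
            "train" if a in train_ids else "val"
            for a in out.loc[mask, "animal_id"]]
    return out


def write_yolo_labels(path, boxes) -> None:
    """One line per box: ``class cx cy w h`` normalized to [0, 1]."""
    lines = []
    for cls, cx, cy, w, h in boxes:
        lines.append(f"{int(cls)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path) -> list[tuple]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
        for v, name in ((cx, "cx"), (cy, "cy"), (w, "w"), (h, "h")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1] in {path}")
        if cx - w / 2 < -1e-6 or cx + w / 2 > 1 + 1e-6 \
                or cy - h / 2 < -1e-6 or cy + h / 2 > 1 + 1e-6:
            raise ValueError(f"box extends outside the image in {path}")
        boxes.append((cls, cx, cy, w, h))
    return boxes


def _render_frame(rng, width, height, bcs_class, session):
    """One synthetic dorsal view: textured ellipse + tailhead patch.

    Returns the uint8 RGB image and the normalized tailhead box
    (cx, cy, w, h).  The local texture amplitude inside the tailhead box
    increases monotonically with the class index, which is the signal the
    detector has to pick up.
    """
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    # structured background: smooth illumination gradient + coarse clutter
    bg = 90 + 30 * (xx / width) + 20 * (yy / height)
    clutter = ndimage.gaussian_filter(rng.normal(0, 1, (height, width)), 12)
    bg = bg + 25 * clutter / max(np.abs(clutter).max(), 1e-9)

    # animal body: ellipse with a random center and orientation
    cx = rng.uniform(0.35, 0.65) * width
    cy = rng.uniform(0.35, 0.65) * height
    a = rng.uniform(0.22, 0.30) * width     # semi-major
    b = rng.uniform(0.13, 0.18) * height    # semi-minor
    phi = rng.uniform(0, np.pi)
    xr = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    yr = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    body = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    base = rng.uniform(140, 170)
    img = np.where(body, base, bg)
    # coat texture over the whole body
    coat = ndimage.gaussian_filter(rng.normal(0, 1, (height, width)), 2)
    img = img + np.where(body, 12 * coat, 0.0)

    # tailhead patch at one end of the major axis, texture amplitude ~ class
    class_idx = BCS_CLASSES.index(bcs_class)
    tail_t = rng.choice([-1.0, 1.0])
    tcx = cx + tail_t * 0.72 * a * np.cos(phi)
    tcy = cy + tail_t * 0.72 * a * np.sin(phi)
    tw = rng.uniform(0.16, 0.20) * width
    th = rng.uniform(0.16, 0.20) * height
    x1 = np.clip(tcx - tw / 2, 0, width - 2)
    y1 = np.clip(tcy - th / 2, 0, height - 2)
    x2 = np.clip(tcx + tw / 2, x1 + 1, width - 1)
    y2 = np.clip(tcy + th / 2, y1 + 1, height - 1)
    patch = (slice(int(y1), int(y2)), slice(int(x1), int(x2)))
    amp = 6.0 + 9.0 * class_idx
    tex = rng.normal(0, 1, img[patch].shape)
    img[patch] = img[patch] + amp * tex

    if session == "evening":       # dim illumination
        img = img * 0.55
    img = np.clip(img, 0, 255)
    rgb = np.stack([img, img * 0.96, img * 0.90], axis=-1)
    box = (((x1 + x2) / 2) / width, ((y1 + y2) / 2) / height,
           (x2 - x1) / width, (y2 - y1) / height)
    return np.clip(rgb, 0, 255).astype(np.uint8), box


def generate_synthetic_dataset(out_dir, n_animals: int = 10,
                               images_per_session: int = 2,
                               blur_fraction: float = 1 / 3,
                               seed: int = 0,
                               image_size: tuple = (640, 480),
                               split_ratio: float = 0.8) -> pd.DataFrame:
    """Deterministic synthetic stand-in for the private study data.

    Writes ``images/{train,val}`` and ``labels/{train,val}`` under
    ``out_dir`` plus a ``manifest.csv``; returns the manifest.  Every
    animal gets ``images_per_session`` clear frames per session (morning
    bright, evening dim); ``blur_fraction`` of the clear images, sampled
    from both sessions, are duplicated with directional motion blur
    (kernel length uniform on 21..32, angle uniform per image) and merged
    into the set, inheriting their animal's split.
    """
    if n_animals < len(BCS_CLASSES):
        raise ValueError("need at least one animal per class")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    width, height = image_size

    records = []
    frames = {}
    classes = [BCS_CLASSES[i % len(BCS_CLASSES)] for i in range(n_animals)]
    for animal in range(n_animals):
        for session in STUDY_SESSIONS:
            for shot in range(images_per_session):
                img, box = _render_frame(rng, width, height,
                                         classes[animal], session)
                name = f"a{animal:03d}_{session}_{shot:02d}"
                frames[name] = (img, box)
                records.append(dict(image=name + ".png", animal_id=animal,
                                    session=session, blurred=False,
                                    bcs_class=classes[animal], split=""))
    manifest = pd.DataFrame(records)

    # blur augmentation: sample from both sessions
    n_blur = int(round(blur_fraction * len(manifest)))
    order = rng.permutation(len(manifest))
    chosen, seen_sessions = [], set()
    for i in order:
        if len(chosen) >= n_blur:
            break
        chosen.append(i)
        seen_sessions.add(manifest.iloc[i]["session"])
    blur_rows = []
    for i in chosen:
        row = manifest.iloc[i]
        src = row["image"][:-4]
        length = int(rng.integers(BLUR_KERNEL_RANGE[0],
                                  BLUR_KERNEL_RANGE[1] + 1))
        angle = float(rng.uniform(0, 180))
        img, box = frames[src]
        frames[src + "_blur"] = (apply_motion_blur(img, length, angle), box)
        blur_rows.append(dict(image=src + "_blur.png",
                              animal_id=row["animal_id"],
                              session=row["session"], blurred=True,
                              bcs_class=row["bcs_class"], split="",
                              blur_length=length, blur_angle=angle))
    manifest = pd.concat([manifest, pd.DataFrame(blur_rows)],
                         ignore_index=True)
    manifest = animal_level_split(manifest, split_ratio, seed)

    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    for _, row in manifest.iterrows():
        split = row["split"]
        img, box = frames[row["image"][:-4]]
        Image.fromarray(img).save(out_dir / "images" / split / row["image"])
        cls_id = BCS_CLASSES.index(row["bcs_class"])
        write_yolo_labels(
            out_dir / "labels" / split / (row["image"][:-4] + ".txt"),
            [(cls_id, *box)])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
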