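"""Synthetic two-class image population for end-to-end testing.

Real data for this task — photographs of healthy and diseased animals —
cannot ship with the package, so the generator emulates the structure the
pipeline relies on: a bright, mildly textured elliptical body ("animal")
on a black backdrop, with the unhealthy class carrying a handful of dark
circular lesion-like blobs inside the body. Per-image base brightness is
drawn from a wide range so the fuzzy enhancement stage is exercised
across its whole linguistic universe (Very Dark through Very Bright), and
the black backdrop guarantees the background-substitution step is
observably active on every image.

Classes are separable by construction (lesion presence), so any sound
classifier can beat chance; the ground-truth table records the lesion
count per image as an oracle. A configurable fraction of images carries a
label; the remainder forms the unlabeled pool for semi-supervised
training. Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_preprocess import LabeledRecord, write_image


@dataclass(frozen=True)
class SynthSpec:
    n_images: int = 600
    image_side: int = 32
    class_balance: float = 0.5          #: fraction of images that are unhealthy
    lesion_count_range: tuple[int, int] = (2, 4)
    lesion_radius_range: tuple[int, int] = (2, 4)
    base_brightness_range: tuple[int, int] = (40, 220)
    labeled_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must lie in (0, 1]")
        if not 0 <= self.class_balance <= 1:
            raise ValueError("class_balance must lie in [0, 1]")
        if self.lesion_radius_range[1] >= self.image_side / 2:
            raise ValueError("lesion radius must be smaller than half the image side")
        lo, hi = self.base_brightness_range
        if not (0 <= lo <= hi <= 255):
            raise ValueError("base_brightness_range must lie within [0, 255]")


@dataclass
class SynthDataset:
    """In-memory product of :func:`generate`."""

    images: np.ndarray                  #: (n, side, side, 3) uint8
    labels: np.ndarray                  #: (n,) int, 0 healthy / 1 unhealthy
    labeled_mask: np.ndarray            #: (n,) bool, True = label revealed
    truth: pd.DataFrame                 #: per-image oracle (lesion count, brightness)
    spec: SynthSpec

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labeled_mask)

    @property
    def unlabeled_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.labeled_mask)


def _render_image(
    rng: np.random.Generator,
    side: int,
    unhealthy: bool,
    spec: SynthSpec,
) -> tuple[np.ndarray, int, int]:
    """Draw one body ellipse (plus lesions if unhealthy) on black."""
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    cy = side / 2 + rng.uniform(-0.05, 0.05) * side
    cx = side / 2 + rng.uniform(-0.05, 0.05) * side
    ay = rng.uniform(0.30, 0.42) * side
    ax = rng.uniform(0.30, 0.42) * side
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    body = (u / ax) ** 2 + (v / ay) ** 2 <= 1.0

    brightness = int(rng.integers(spec.base_brightness_range[0], spec.base_brightness_range[1] + 1))
    img = np.zeros((side, side), dtype=float)
    texture = 1.0 + 0.06 * rng.standard_normal((side, side))
    img[body] = brightness * texture[body]

    n_lesions = 0
    if unhealthy:
        lo, hi = spec.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1))
        placed = 0
        attempts = 0
        while placed < n_lesions and attempts < 200:
            attempts += 1
            r = int(rng.integers(spec.lesion_radius_range[0], spec.lesion_radius_range[1] + 1))
            ly = rng.uniform(cy - 0.7 * ay, cy + 0.7 * ay)
            lx = rng.uniform(cx - 0.7 * ax, cx + 0.7 * ax)
            uu = (lx - cx) * ct + (ly - cy) * st
            vv = -(lx - cx) * st + (ly - cy) * ct
            if (uu / ax) ** 2 + (vv / ay) ** 2 > 0.6:  # keep blob well inside the body
                continue
            blob = (xx - lx) ** 2 + (yy - ly) ** 2 <= r * r
            img[blob & body] *= rng.uniform(0.2, 0.45)
            placed += 1
        n_lesions = placed

    # slight per-channel tint so the raster is genuinely RGB
    tint = rng.uniform(0.92, 1.08, size=3)
    rgb = np.clip(img[..., None] * tint[None, None, :], 0, 255)
    return rgb.astype(np.uint8), brightness, n_lesions


def generate(spec: SynthSpec) -> SynthDataset:
    """Generate the full two-class population described by ``spec``.

    Class counts are exact (``round(n * class_balance)`` unhealthy), the
    labeled subset is a stratified random ``labeled_fraction`` of each
    class, and the returned ground-truth table records per-image class,
    base brightness and lesion count.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_images
    n_unhealthy = int(round(n * spec.class_balance))
    labels = np.zeros(n, dtype=int)
    labels[:n_unhealthy] = 1
    rng.shuffle(labels)

    images = np.empty((n, spec.image_side, spec.image_side, 3), dtype=np.uint8)
    rows = []
    for i in range(n):
        img, brightness, n_lesions = _render_image(
            rng, spec.image_side, bool(labels[i]), spec
        )
        images[i] = img
        rows.append(
            {
                "image_id": f"synth_{i:05d}",
                "label": int(labels[i]),
                "base_brightness": brightness,
                "n_lesions": n_lesions,
            }
        )

    labeled_mask = np.zeros(n, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        k = int(round(len(idx) * spec.labeled_fraction))
        if len(idx) and spec.labeled_fraction > 0:
            k = max(k, 1)
        chosen = rng.choice(idx, size=min(k, len(idx)), replace=False)
        labeled_mask[chosen] = True

    truth = pd.DataFrame(rows)
    return SynthDataset(images=images, labels=labels, labeled_mask=labeled_mask,
                        truth=truth, spec=spec)


def brightness_histogram(images: np.ndarray) -> np.ndarray:
    """Pooled 256-bin intensity histogram over all pixels and channels."""
    images = np.asarray(images)
    if images.size == 0:
        raise ValueError("histogram of an empty image set is undefined")
    return np.bincount(images.astype(np.uint8).ravel(), minlength=256)


def save_dataset(
    ds: SynthDataset,
    out_dir: str | Path,
) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    """Write PNGs plus the manifest layout the real-data path consumes.

    Returns ``(labeled_records, unlabeled_records)``; the manifest CSV at
    ``out_dir/manifest.csv`` covers the labeled subset, and
    ``out_dir/truth.csv`` stores the full oracle table.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    labeled, unlabeled = [], []
    for i in range(ds.spec.n_images):
        image_id = ds.truth.image_id[i]
        path = img_dir / f"{image_id}.png"
        write_image(ds.images[i], path)
        rec = LabeledRecord(image_id, str(path), int(ds.labels[i]))
        (labeled if ds.labeled_mask[i] else unlabeled).append(rec)
    pd.DataFrame(
        {
            "image_id": [r.image_id for r in labeled],
            "path": [r.path for r in labeled],
            "label": [r.label for r in labeled],
        }
    ).to_csv(out_dir / "manifest.csv", index=False)
    ds.truth.to_csv(out_dir / "truth.csv", index=False)
    return labeled, unlabeled


def write_coco_annotations(ds: SynthDataset, out_path: str | Path) -> None:
    """Emit COCO-style annotations (labeled images only) for the loader."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    categories = [
        {"id": 1, "name": "healthy"},
        {"id": 2, "name": "unhealthy"},
    ]
    images, annotations = [], []
    ann_id = 1
    for i in np.flatnonzero(ds.labeled_mask):
        image_id = int(i) + 1
        images.append(
            {
                "id": image_id,
                "file_name": f"images/{ds.truth.image_id[i]}.png",
                "width": ds.spec.image_side,
                "height": ds.spec.image_side,
            }
        )
        annotations.append(
            {
                "id": ann_id,
                "image_id": image_id,
                "category_id": 2 if ds.labels[i] else 1,
            }
        )
        ann_id += 1
    with open(out_path, "w") as fh:
        json.dump(
            {"images": images, "annotations": annotations, "categories": categories},
            fh,
        )
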