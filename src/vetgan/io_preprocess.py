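"""Image and label I/O plus the fixed pre-processing steps.

Every stage of the pipeline consumes and produces 8-bit RGB rasters
(``H x W x 3`` uint8 arrays). Two deterministic pre-processing steps are
applied before enhancement and augmentation:

* resizing to a square working resolution (256 px in production, smaller
  for desk-scale experiments), stretching rather than padding;
* substituting the black backdrop with white, so that artefacts introduced
  by the generative model are easier to spot by eye.

Class labels come either from the synthetic generator or from a COCO-style
annotation JSON in which each image carries a single binary
healthy/unhealthy category.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage, UnidentifiedImageError

logger = logging.getLogger("vetgan")

WORKING_SIDE = 256  #: production working resolution (px)

HEALTHY = 0
UNHEALTHY = 1


@dataclass(frozen=True)
class LabeledRecord:
    """One image with its binary class label (healthy=0, unhealthy=1)."""

    image_id: str
    path: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (HEALTHY, UNHEALTHY):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def _validate_image(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 array, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        if pixels.min() < 0 or pixels.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        pixels = pixels.astype(np.uint8)
    return pixels


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as an ``H x W x 3`` uint8 array.

    Grayscale inputs are broadcast to three identical channels; alpha
    channels are dropped.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with PILImage.open(path) as im:
            im = im.convert("RGB")
            return np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"cannot decode image file: {path}") from exc


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an ``H x W x 3`` uint8 array as PNG (lossless) or JPEG."""
    pixels = _validate_image(pixels)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    PILImage.fromarray(pixels, mode="RGB").save(path)


def resize_to_working(pixels: np.ndarray, side: int = WORKING_SIDE) -> np.ndarray:
    """Stretch an image to ``side x side`` with bilinear interpolation.

    Aspect ratio is deliberately not preserved: the classifier expects a
    fixed square input and the augmentation stage already randomizes scale.
    """
    if side < 8:
        raise ValueError(f"working side must be >= 8 px, got {side}")
    pixels = _validate_image(pixels)
    if pixels.shape[0] == side and pixels.shape[1] == side:
        return pixels.copy()
    im = PILImage.fromarray(pixels, mode="RGB")
    return np.asarray(im.resize((side, side), PILImage.Resampling.BILINEAR))


def replace_background(pixels: np.ndarray, black_threshold: int = 10) -> np.ndarray:
    """Substitute the black backdrop with white.

    A pixel counts as backdrop only when *all three* channels fall below
    ``black_threshold``; this joint test avoids bleaching dark fur, which is
    dark in some channels but rarely in all of them at once.
    """
    if not 0 <= black_threshold <= 255:
        raise ValueError("black_threshold must lie in [0, 255]")
    pixels = _validate_image(pixels)
    out = pixels.copy()
    mask = np.all(pixels < black_threshold, axis=2)
    out[mask] = 255
    return out


def read_coco_binary_labels(
    annotation_json: str | Path,
    class_map: Mapping[str, int],
) -> list[LabeledRecord]:
    """Extract one binary label per image from a COCO annotation file.

    Each annotation's category name is mapped through ``class_map`` (e.g.
    ``{"healthy": 0, "unhealthy": 1}``). Images with no annotations are
    omitted with a warning; an image whose annotations map to both classes
    is an error, because the task assumes a single binary label per image.
    """
    annotation_json = Path(annotation_json)
    with open(annotation_json) as fh:
        coco = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in coco:
            raise ValueError(f"COCO file missing required array {key!r}")

    cat_names = {c["id"]: c["name"] for c in coco["categories"]}
    labels_per_image: dict[int, set[int]] = {}
    for ann in coco["annotations"]:
        name = cat_names.get(ann["category_id"])
        if name is None:
            raise ValueError(f"annotation references unknown category id {ann['category_id']}")
        if name not in class_map:
            raise KeyError(f"category {name!r} absent from class_map")
        labels_per_image.setdefault(ann["image_id"], set()).add(int(class_map[name]))

    records: list[LabeledRecord] = []
    base = annotation_json.parent
    for img in coco["images"]:
        labels = labels_per_image.get(img["id"])
        if not labels:
            logger.warning("image %s has no annotations; omitted", img["id"])
            continue
        if len(labels) > 1:
            raise ValueError(
                f"image {img['id']} has annotations mapping to both classes"
            )
        records.append(
            LabeledRecord(
                image_id=str(img["id"]),
                path=str(base / img["file_name"]),
                label=labels.pop(),
            )
        )
    return records


def write_manifest(records: Sequence[LabeledRecord], path: str | Path) -> None:
    """Write a ``image_id,path,label`` CSV manifest for downstream stages."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "path": [r.path for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[LabeledRecord]:
    """Read a manifest written by :func:`write_manifest`."""
    df = pd.read_csv(path, dtype={"image_id": str, "path": str, "label": int})
    return [
        LabeledRecord(image_id=r.image_id, path=r.path, label=int(r.label))
        for r in df.itertuples()
    ]
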