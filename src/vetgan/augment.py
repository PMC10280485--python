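"""Offline combinatorial image augmentation.

The dataset is expanded by applying a sampled combination of one to four
distinct geometric transforms to each image: horizontal flip, vertical
flip, rotation (0-358 degrees in 2-degree steps), scale-up (factors
1.0-2.0 in 0.1 steps) and scale-down (factors 1.0-0.5 in 0.1 steps).
Combinations containing both scale-up and scale-down are excluded, since
the net effect would collapse to whichever scale dominates. Of the 30
subsets of size 1-4 of the five transform kinds, 7 contain both scale
kinds, leaving 23 valid combinations.

Within a plan, ops apply in a fixed canonical order (flips, then rotation,
then scaling) so a manifest row fully determines the output image.
Rotation fills exposed corners with white, matching the white backdrop
substitution; scaled images are mapped back onto the working canvas
(center crop after scale-up, centered white padding after scale-down) so
every augmented output keeps the working resolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .io_preprocess import LabeledRecord, read_image, write_image

KINDS = ("hflip", "vflip", "rotate", "scale_up", "scale_down")
#: canonical application order inside a plan
_CANONICAL_ORDER = {k: i for i, k in enumerate(KINDS)}

ROTATION_GRID = tuple(range(0, 360, 2))
SCALE_DOWN_GRID = tuple(round(1.0 - 0.1 * i, 1) for i in range(6))   # 1.0 .. 0.5
SCALE_UP_GRID = tuple(round(1.0 + 0.1 * i, 1) for i in range(11))    # 1.0 .. 2.0

WHITE = 255


@dataclass(frozen=True)
class TransformOp:
    kind: str
    param: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "rotate" and self.param not in ROTATION_GRID:
            raise ValueError(f"rotation angle {self.param} not on the 2-degree grid")
        if self.kind == "scale_up" and self.param not in SCALE_UP_GRID:
            raise ValueError(f"scale-up factor {self.param} not on the 0.1 grid")
        if self.kind == "scale_down" and self.param not in SCALE_DOWN_GRID:
            raise ValueError(f"scale-down factor {self.param} not on the 0.1 grid")
        if self.kind in ("hflip", "vflip") and self.param is not None:
            raise ValueError(f"{self.kind} takes no parameter")


@dataclass(frozen=True)
class AugmentPlan:
    """An ordered set of 1-4 distinct transform ops with sampled parameters."""

    ops: tuple[TransformOp, ...]
    seed_state: int | None = None

    def __post_init__(self) -> None:
        kinds = [op.kind for op in self.ops]
        if not 1 <= len(kinds) <= 4:
            raise ValueError("a plan holds between 1 and 4 ops")
        if len(set(kinds)) != len(kinds):
            raise ValueError("a plan may not repeat a transform kind")
        if "scale_up" in kinds and "scale_down" in kinds:
            raise ValueError("a plan may not combine scale-up and scale-down")

    def describe(self) -> str:
        parts = []
        for op in sorted(self.ops, key=lambda o: _CANONICAL_ORDER[o.kind]):
            parts.append(op.kind if op.param is None else f"{op.kind}({op.param})")
        return "+".join(parts)


def enumerate_valid_combinations() -> list[tuple[str, ...]]:
    """All size 1-4 subsets of the five kinds without both scale kinds.

    Deterministic lexicographic order (by subset size, then kind order).
    """
    combos: list[tuple[str, ...]] = []
    for r in range(1, 5):
        for subset in itertools.combinations(KINDS, r):
            if "scale_up" in subset and "scale_down" in subset:
                continue
            combos.append(subset)
    return combos


def sample_plan(rng: np.random.Generator) -> AugmentPlan:
    """Uniformly pick a valid kind-set and sample each op's parameter."""
    combos = enumerate_valid_combinations()
    subset = combos[int(rng.integers(len(combos)))]
    ops = []
    for kind in subset:
        if kind == "rotate":
            param = float(ROTATION_GRID[int(rng.integers(len(ROTATION_GRID)))])
        elif kind == "scale_up":
            param = SCALE_UP_GRID[int(rng.integers(len(SCALE_UP_GRID)))]
        elif kind == "scale_down":
            param = SCALE_DOWN_GRID[int(rng.integers(len(SCALE_DOWN_GRID)))]
        else:
            param = None
        ops.append(TransformOp(kind, param))
    return AugmentPlan(ops=tuple(ops))


def _rotate(pixels: np.ndarray, angle: float) -> np.ndarray:
    """Rotate counter-clockwise, white fill; right angles are exact."""
    angle = float(angle) % 360.0
    if angle == 0.0:
        return pixels.copy()
    if angle in (90.0, 180.0, 270.0):
        return np.ascontiguousarray(np.rot90(pixels, k=int(angle // 90)))
    im = PILImage.fromarray(pixels, mode="RGB")
    out = im.rotate(
        angle,
        resample=PILImage.Resampling.BILINEAR,
        expand=False,
        fillcolor=(WHITE, WHITE, WHITE),
    )
    return np.asarray(out)


def _scale(pixels: np.ndarray, factor: float) -> np.ndarray:
    """Resample by ``factor`` and map back to the original canvas size."""
    if factor == 1.0:
        return pixels.copy()
    side = pixels.shape[0]
    new_side = max(1, int(round(side * factor)))
    im = PILImage.fromarray(pixels, mode="RGB")
    resized = np.asarray(im.resize((new_side, new_side), PILImage.Resampling.BILINEAR))
    if new_side >= side:  # center crop
        off = (new_side - side) // 2
        return np.ascontiguousarray(resized[off : off + side, off : off + side])
    out = np.full((side, side, 3), WHITE, dtype=np.uint8)  # centered white pad
    off = (side - new_side) // 2
    out[off : off + new_side, off : off + new_side] = resized
    return out


def apply_plan(pixels: np.ndarray, plan: AugmentPlan) -> np.ndarray:
    """Apply a plan's ops in canonical order to a square image."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    if pixels.ndim != 3 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"expected a square H x H x 3 image, got {pixels.shape}")
    out = pixels
    for op in sorted(plan.ops, key=lambda o: _CANONICAL_ORDER[o.kind]):
        if op.kind == "hflip":
            out = np.ascontiguousarray(out[:, ::-1, :])
        elif op.kind == "vflip":
            out = np.ascontiguousarray(out[::-1, :, :])
        elif op.kind == "rotate":
            out = _rotate(out, op.param)
        else:
            out = _scale(out, op.param)
    return out


def augment_dataset(
    records: Sequence[LabeledRecord],
    out_dir: str | Path,
    n_per_image: int,
    seed: int,
) -> tuple[list[LabeledRecord], pd.DataFrame]:
    """Emit ``n_per_image`` augmented copies of every input image.

    Returns the combined record list (originals first, then augmented) and
    a manifest DataFrame recording, for each augmented image, its source,
    label, the plan description and the seed. Labels are inherited
    unchanged. One seeded RNG drives all sampling so reruns are identical.
    """
    if n_per_image < 0:
        raise ValueError("n_per_image must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    augmented: list[LabeledRecord] = []
    rows = []
    for rec in records:
        pixels = read_image(rec.path)
        for j in range(n_per_image):
            plan = sample_plan(rng)
            out_id = f"{rec.image_id}_aug{j}"
            out_path = out_dir / f"{out_id}.png"
            write_image(apply_plan(pixels, plan), out_path)
            augmented.append(LabeledRecord(out_id, str(out_path), rec.label))
            rows.append(
                {
                    "source_id": rec.image_id,
                    "out_id": out_id,
                    "label": rec.label,
                    "ops": plan.describe(),
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows, columns=["source_id", "out_id", "label", "ops", "seed"])
    return list(records) + augmented, manifest
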