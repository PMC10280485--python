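"""End-to-end pipeline: simulate -> preprocess -> enhance -> augment -> train -> evaluate.

Each stage reads its inputs from the previous stage's subdirectory of the
run directory and writes into its own, so a run is inspectable and any
prefix of the stage list can be executed alone. A single root seed derives
one named substream per stage, making the whole run a pure function of
(config, seed): rerunning with the same configuration reproduces the
machine-readable ``summary.json`` byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import augment as aug
from . import fuzzy_enhance as fe
from . import io_preprocess as iop
from . import metrics as met
from . import sgan
from . import synthetic_data as sd

logger = logging.getLogger("vetgan")

ALL_STAGES = ("simulate", "preprocess", "enhance", "augment", "train", "evaluate")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    return int(
        np.random.SeedSequence(
            entropy=root_seed, spawn_key=(zlib.crc32(stage.encode()),)
        ).generate_state(1)[0]
        % 2**31
    )


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    ``synth`` fields configure the simulated dataset; ``working_side``
    is the square resolution all stages operate at; ``sgan`` holds
    keyword overrides applied on top of :func:`sgan.desk_scale_config`.
    """

    out_dir: str = "runs/synthetic"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    working_side: int = 32
    n_images: int = 600
    n_test: int = 200
    labeled_fraction: float = 0.1
    class_balance: float = 0.5
    base_brightness_range: tuple[int, int] = (40, 220)
    enhance_channel_mode: str = "luminance"
    enhance_delta_max: float = 64.0
    fis: dict | None = None  #: full FIS override (MF shapes, rules, ...)
    augment_per_image: int = 2
    val_fraction: float = 0.2
    sgan: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "base_brightness_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _setup_logging(level: str) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s [%(name)s] %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


def _stage_simulate(cfg: RunConfig, run_dir: Path, summary: dict) -> None:
    out = run_dir / "simulate"
    seed = stage_seed(cfg.seed, "simulate")
    train_spec = sd.SynthSpec(
        n_images=cfg.n_images,
        image_side=cfg.working_side,
        class_balance=cfg.class_balance,
        base_brightness_range=cfg.base_brightness_range,
        labeled_fraction=cfg.labeled_fraction,
        seed=seed,
    )
    ds = sd.generate(train_spec)
    labeled, unlabeled = sd.save_dataset(ds, out)
    iop.write_manifest(unlabeled, out / "unlabeled.csv")
    sd.write_coco_annotations(ds, out / "annotations.json")

    test_spec = dataclasses.replace(
        train_spec, n_images=cfg.n_test, labeled_fraction=1.0,
        seed=stage_seed(cfg.seed, "simulate-test"),
    )
    test_ds = sd.generate(test_spec)
    sd.save_dataset(test_ds, out / "test")

    summary["simulate"] = {
        "n_images": cfg.n_images,
        "n_labeled": len(labeled),
        "n_unlabeled": len(unlabeled),
        "n_test": cfg.n_test,
        "class_counts": {
            "healthy": int((ds.labels == 0).sum()),
            "unhealthy": int((ds.labels == 1).sum()),
        },
    }


def _process_split(src_dir: Path, dst_dir: Path, side: int) -> None:
    """Resize + background substitution for every manifest in a split dir."""
    dst_dir.mkdir(parents=True, exist_ok=True)
    for name in ("manifest.csv", "unlabeled.csv"):
        src_manifest = src_dir / name
        if not src_manifest.is_file():
            continue
        records = iop.read_manifest(src_manifest)
        out_records = []
        for rec in records:
            img = iop.read_image(rec.path)
            img = iop.replace_background(iop.resize_to_working(img, side))
            out_path = dst_dir / "images" / f"{rec.image_id}.png"
            iop.write_image(img, out_path)
            out_records.append(iop.LabeledRecord(rec.image_id, str(out_path), rec.label))
        iop.write_manifest(out_records, dst_dir / name)


def _stage_preprocess(cfg: RunConfig, run_dir: Path, summary: dict) -> None:
    _process_split(run_dir / "simulate", run_dir / "preprocess", cfg.working_side)
    _process_split(run_dir / "simulate" / "test", run_dir / "preprocess" / "test",
                   cfg.working_side)
    summary["preprocess"] = {"working_side": cfg.working_side}


def _stage_enhance(cfg: RunConfig, run_dir: Path, summary: dict) -> None:
    out = run_dir / "enhance"
    if cfg.fis is not None:
        fis = fe.FISConfig.from_dict(cfg.fis)
    else:
        fis = fe.default_fis_config(
            delta_max=cfg.enhance_delta_max, channel_mode=cfg.enhance_channel_mode
        )
    lut = fe.build_lut(fis)
    rows = []
    for split in ("", "test"):
        src = run_dir / "preprocess" / split if split else run_dir / "preprocess"
        dst = out / split if split else out
        dst.mkdir(parents=True, exist_ok=True)
        for name in ("manifest.csv", "unlabeled.csv"):
            src_manifest = src / name
            if not src_manifest.is_file():
                continue
            records = iop.read_manifest(src_manifest)
            out_records = []
            for rec in records:
                img = iop.read_image(rec.path)
                enhanced = fe.enhance_image(img, fis, lut)
                out_path = dst / "images" / f"{rec.image_id}.png"
                iop.write_image(enhanced, out_path)
                out_records.append(
                    iop.LabeledRecord(rec.image_id, str(out_path), rec.label)
                )
                rows.append(
                    {"image_id": rec.image_id, "split": split or "train",
                     "psnr_db": fe.psnr(img, enhanced)}
                )
            iop.write_manifest(out_records, dst / name)
    report = pd.DataFrame(rows)
    finite = report.psnr_db[np.isfinite(report.psnr_db)]
    report.to_csv(out / "psnr.csv", index=False)
    summary["enhance"] = {
        "n_images": len(report),
        "mean_psnr_db": round(float(finite.mean()), 4) if len(finite) else None,
        "min_psnr_db": round(float(finite.min()), 4) if len(finite) else None,
    }


def _stage_augment(cfg: RunConfig, run_dir: Path, summary: dict) -> None:
    out = run_dir / "augment"
    src = run_dir / "enhance"
    records = iop.read_manifest(src / "manifest.csv")
    combined, manifest = aug.augment_dataset(
        records, out / "images", cfg.augment_per_image,
        seed=stage_seed(cfg.seed, "augment"),
    )
    iop.write_manifest(combined, out / "manifest.csv")
    manifest.to_csv(out / "augment_manifest.csv", index=False)
    summary["augment"] = {
        "n_original": len(records),
        "n_per_image": cfg.augment_per_image,
        "n_augmented": len(combined) - len(records),
        "n_total": len(combined),
    }


def _load_set(manifest: Path) -> sgan.ImageSet:
    records = iop.read_manifest(manifest)
    images = np.stack([iop.read_image(r.path) for r in records])
    return sgan.ImageSet(images, np.array([r.label for r in records]))


def _stage_train(cfg: RunConfig, run_dir: Path, summary: dict) -> None:
    out = run_dir / "train"
    out.mkdir(parents=True, exist_ok=True)
    aug_manifest = run_dir / "augment" / "manifest.csv"
    src_manifest = (
        aug_manifest if aug_manifest.is_file() else run_dir / "enhance" / "manifest.csv"
    )
    if not src_manifest.is_file():
        raise FileNotFoundError(
            f"train stage needs a labeled manifest at {src_manifest}; "
            "run the earlier stages first"
        )
    labeled_all = _load_set(src_manifest)
    unlabeled = _load_set(run_dir / "enhance" / "unlabeled.csv")

    seed = stage_seed(cfg.seed, "train")
    rng = np.random.default_rng(seed)
    n = len(labeled_all)
    n_val = max(2, int(round(n * cfg.val_fraction)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    labeled = sgan.ImageSet(labeled_all.images[train_idx], labeled_all.labels[train_idx])
    validation = sgan.ImageSet(labeled_all.images[val_idx], labeled_all.labels[val_idx])

    if cfg.working_side <= 64:
        overrides = {**sgan.BENCHMARK_OVERRIDES, **cfg.sgan}
        config = sgan.desk_scale_config(image_side=cfg.working_side, **overrides)
    else:
        config = sgan.SGANConfig(image_side=cfg.working_side, **cfg.sgan)
    model = sgan.train(labeled, unlabeled, validation, config, seed=seed)
    history = pd.DataFrame(model.state.history_rows())
    history.to_csv(out / "history.csv", index=False)
    sgan.save_checkpoint(model, out / "checkpoint.npz")

    summary["train"] = {
        "n_labeled_train": len(labeled),
        "n_validation": len(validation),
        "n_unlabeled": len(unlabeled),
        "epochs_run": model.state.stopped_epoch,
        "best_epoch": model.state.best_epoch,
        "final_loss_discriminator": round(model.state.loss_discriminator[-1], 6),
        "final_loss_generator": round(model.state.loss_generator[-1], 6),
        "best_val_loss": round(min(model.state.val_loss), 6),
    }


def _stage_evaluate(cfg: RunConfig, run_dir: Path, summary: dict) -> None:
    out = run_dir / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    model = sgan.load_checkpoint(run_dir / "train" / "checkpoint.npz")
    test = _load_set(run_dir / "enhance" / "test" / "manifest.csv")
    probs, fake_probs = sgan.predict(model, test.images)
    pred = probs.argmax(axis=1)
    summ = met.summary(met.confusion(pred, test.labels))
    summ["auc_roc"] = met.auc_roc(probs[:, 1], test.labels)
    met.write_report(summ, out / "metrics.csv")
    met.roc_points(probs[:, 1], test.labels).to_csv(out / "roc_points.csv", index=False)
    summary["evaluate"] = {
        "n_test": len(test),
        **{k: round(float(v), 6) for k, v in summ.items()},
        "mean_fake_probability": round(float(fake_probs.mean()), 6),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "enhance": _stage_enhance,
    "augment": _stage_augment,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the summary.

    The summary contains no timestamps or absolute paths, so two runs with
    the same configuration and seed produce identical ``summary.json``
    files. Stage failures abort the run with the stage name attached;
    completed stages' outputs are left in place for inspection.
    """
    _setup_logging(cfg.log_level)
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("out_dir", "log_level")
        },
        "seed": cfg.seed,
    }
    for stage in cfg.stages:
        t0 = time.time()
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, run_dir, summary)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
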