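"""Shared I/O: image reading/writing, manifests, run configuration and
the end-to-end pipeline orchestrator.

All artifacts use plain, diffable formats — PNG for images, CSV for
manifests and reports, YAML/JSON for configuration — and every run
directory carries a snapshot of the exact configuration and seed that
produced it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .core import LaneBox, LaneImage, StripImage
from .errors import FormatError, InvalidSpecError, IOFailure

logger = logging.getLogger("hbscreen")

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_image(path: str | Path) -> StripImage:
    """Read a PNG/TIFF/JPEG as an 8-bit RGB strip image.

    Grayscale files are promoted to three channels (noted in the log);
    alpha channels are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"image file not found: {path}")
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I;16", "I"):
                logger.info("promoting grayscale image %s to RGB", path)
            if im.mode != "RGB":
                im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOFailure(f"cannot read image {path}: {exc}") from exc
    return StripImage(pixels=pixels, meta={"path": str(path)})


def write_image(pixels: np.ndarray, path: str | Path) -> Path:
    """Write an HxWx3 (or HxW) uint8 array losslessly where possible."""
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    try:
        Image.fromarray(arr).save(path)
    except OSError as exc:
        raise IOFailure(f"cannot write image {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# manifests

from .synthetic import MANIFEST_COLUMNS  # noqa: E402  (shared schema)


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a lane manifest CSV.

    Relative ``strip_path`` entries resolve against the manifest's
    directory; the resolved absolute path is stored in ``strip_path``.
    """
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns {sorted(missing)}")
    bad = set(df["label"].unique()) - {"normal", "thalassaemia"}
    if bad:
        raise FormatError(f"manifest has unknown labels {sorted(bad)}")
    if (df["row0"] >= df["row1"]).any() or (df["col0"] >= df["col1"]).any():
        raise FormatError("manifest contains degenerate boxes")
    root = path.parent
    df = df.copy()
    df["strip_path"] = [
        str(p if Path(p).is_absolute() else root / p)
        for p in df["strip_path"]
    ]
    if check_paths:
        for p in df["strip_path"].unique():
            if not Path(p).exists():
                raise IOFailure(f"manifest references missing strip: {p}")
    return df


def lanes_from_manifest(manifest: pd.DataFrame) -> list[LaneImage]:
    """Crop every manifest row from its strip into a 150x30 lane image."""
    from .lanes import crop_and_resize

    lanes: list[LaneImage] = []
    cache: dict[str, StripImage] = {}
    for row in manifest.itertuples(index=False):
        strip = cache.get(row.strip_path)
        if strip is None:
            strip = cache[row.strip_path] = read_image(row.strip_path)
        box = LaneBox(int(row.row0), int(row.row1),
                      int(row.col0), int(row.col1))
        lane = crop_and_resize(strip, box)
        lane.strip_id = row.strip_path
        lane.lane_index = int(row.lane_index)
        lane.label = row.label
        lanes.append(lane)
    return lanes


# ---------------------------------------------------------------------------
# run configuration

_SECTION_KEYS = {
    "simulate": {"n_strips", "class_balance", "strip", "population"},
    "extract": {
        "enabled", "kernel_size", "sigma", "small_scale", "large_scale",
        "min_area_frac", "margin", "merge_tol", "expected_lanes",
        "split_fallback",
    },
    "augment": {
        "enabled", "rotation_deg_range", "scale_frac_range",
        "translate_frac_range", "n_variants",
    },
    "train": {
        "model", "k", "val_per_class", "batch_size", "learning_rate",
        "max_epochs", "lr_patience", "stop_patience", "lr_factor",
    },
    "evaluate": {"z"},
    "explain": {"enabled", "n_examples", "alpha"},
}


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys anywhere in a run configuration."""
    allowed_top = set(_SECTION_KEYS) | {"seed"}
    unknown = set(cfg) - allowed_top
    if unknown:
        raise InvalidSpecError(f"unknown config sections: {sorted(unknown)}")
    for section, keys in _SECTION_KEYS.items():
        sub = cfg.get(section, {})
        if not isinstance(sub, dict):
            raise InvalidSpecError(f"config section {section!r} must be a map")
        bad = set(sub) - keys
        if bad:
            raise InvalidSpecError(
                f"unknown keys in config section {section!r}: {sorted(bad)}"
            )
    strip_cfg = cfg.get("simulate", {}).get("strip", {})
    from .synthetic import strip_spec_from_dict

    strip_spec_from_dict({**strip_cfg, "seed": 0})  # key check only
    return cfg


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        cfg = yaml.safe_load(text) or {}
    else:
        cfg = json.loads(text)
    return validate_config(cfg)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute simulate -> extract -> train -> evaluate -> explain.

    Every artifact lands under ``out_dir`` together with a snapshot of
    the configuration and a log; reruns with the same config and seed
    reproduce the metric report exactly.
    """
    from dataclasses import fields as dc_fields

    from .augment import AugmentSpec
    from .classify import ModelSpec, TrainConfig, cross_validate, save_model
    from .evaluate import (
        average_roc,
        confusion,
        metric_report,
        save_confusion_png,
        save_roc_png,
        write_metric_csv,
        write_summary_json,
    )
    from .lanes import ExtractConfig, extract_lanes
    from .scorecam import overlay, scorecam_map
    from .synthetic import (
        DEFAULT_POPULATION,
        WELL_SEPARATED_POPULATION,
        StripSpec,
        generate_dataset,
    )

    config = validate_config(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seed = int(config.get("seed", 0))
    try:
        with open(out / "config.json", "w") as fh:
            json.dump(config, fh, indent=2, default=str)
        logger.info(
            "pipeline defaults: erosion scales 3x3+5x5, gaussian 5x5 "
            "sigma 1.0, Otsu on blurred complement, CI N = pooled for "
            "accuracy / per-class for macro metrics"
        )

        sim = config.get("simulate", {})
        strip_spec = StripSpec(
            **{**sim.get("strip", {}), "seed": seed}
        )
        population = (
            WELL_SEPARATED_POPULATION
            if sim.get("population") == "well_separated"
            else DEFAULT_POPULATION
        )
        strips_dir = out / "strips"
        manifest = generate_dataset(
            int(sim.get("n_strips", 10)),
            float(sim.get("class_balance", 0.5)),
            strip_spec,
            strips_dir,
            population=population,
        )
        manifest = load_manifest(strips_dir / "manifest.csv")
        logger.info("simulated %d lanes", len(manifest))

        ext = dict(config.get("extract", {}))
        extract_enabled = ext.pop("enabled", True)
        if extract_enabled:
            ext_cfg = ExtractConfig(**ext)
            lanes = _extract_and_label(manifest, ext_cfg)
        else:
            lanes = lanes_from_manifest(manifest)
        logger.info("collected %d labeled lanes", len(lanes))

        aug_cfg = dict(config.get("augment", {}))
        aug_enabled = aug_cfg.pop("enabled", False)
        for key in ("rotation_deg_range", "scale_frac_range",
                    "translate_frac_range"):
            if key in aug_cfg:
                aug_cfg[key] = tuple(aug_cfg[key])
        aug = AugmentSpec(**aug_cfg, seed=seed + 1) if aug_enabled else None

        tr = dict(config.get("train", {}))
        model_spec = ModelSpec(name=tr.pop("model", "tinycnn"))
        k = int(tr.pop("k", 5))
        val_per_class = tr.pop("val_per_class", None)
        train_keys = {f.name for f in dc_fields(TrainConfig)}
        cfg_train = TrainConfig(
            **{k2: v for k2, v in tr.items() if k2 in train_keys},
            seed=seed + 2,
        )
        result = cross_validate(
            lanes, model_spec=model_spec, cfg=cfg_train, k=k,
            val_per_class=val_per_class, augment=aug,
        )
        pd.DataFrame(
            [
                {"id": r.lane_id, "true": r.true_label,
                 "pred": r.predicted_label, "score": r.score,
                 "fold": r.fold_id}
                for r in result.records
            ]
        ).to_csv(out / "predictions.csv", index=False)
        for f, hist in enumerate(result.histories, start=1):
            pd.DataFrame(hist).to_csv(out / f"history_fold{f}.csv",
                                      index=False)
        for f, trained in enumerate(result.trained_models, start=1):
            save_model(trained, out / f"model_fold{f}.npz")

        z = float(config.get("evaluate", {}).get("z", 1.96))
        cm = confusion(result.records)
        rows = metric_report(cm, z=z)
        write_metric_csv(rows, out / "report.csv")
        per_fold = [
            [r for r in result.records if r.fold_id == f]
            for f in sorted({r.fold_id for r in result.records})
        ]
        mean_curve = average_roc(per_fold)
        write_summary_json(
            rows,
            out / "summary.json",
            extra={
                "auc_mean": mean_curve.auc,
                "confusion": {"tp": cm.tp, "tn": cm.tn,
                              "fp": cm.fp, "fn": cm.fn},
                "seed": seed,
            },
        )
        save_confusion_png(cm, out / "confusion.png")
        save_roc_png({"fold-averaged": mean_curve}, out / "roc.png")
        logger.info("pooled accuracy %.2f%%", rows[0].value)

        exp = config.get("explain", {})
        if exp.get("enabled", True) and result.trained_models:
            n_examples = int(exp.get("n_examples", 2))
            alpha = float(exp.get("alpha", 0.4))
            trained = result.trained_models[0]
            fold1 = result.folds[0]
            for j, idx in enumerate(fold1.test_ids[:n_examples]):
                lane = lanes[idx]
                sal = scorecam_map(trained, lane, target="thalassaemia")
                write_image(overlay(sal, lane, alpha=alpha),
                            out / f"scorecam_{j}.png")
        return out
    except Exception as exc:
        logger.error("pipeline halted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _extract_and_label(manifest: pd.DataFrame, ext_cfg) -> list[LaneImage]:
    """Run lane extraction per strip and inherit labels from the
    ground-truth boxes by maximum column IoU (>= 0.5 required)."""
    from .lanes import extract_lanes

    lanes: list[LaneImage] = []
    for strip_path, group in manifest.groupby("strip_path", sort=True):
        strip = read_image(strip_path)
        detected, warnings = extract_lanes(strip, ext_cfg)
        for msg in warnings:
            logger.warning("%s: %s", strip_path, msg)
        gt_boxes = [
            LaneBox(int(r.row0), int(r.row1), int(r.col0), int(r.col1))
            for r in group.itertuples(index=False)
        ]
        gt_labels = list(group["label"])
        for lane in detected:
            ious = [lane.box.column_iou(b) for b in gt_boxes]
            best = int(np.argmax(ious))
            if ious[best] >= 0.5:
                lane.label = gt_labels[best]
                lanes.append(lane)
            else:
                logger.warning(
                    "%s: dropping detected lane with max IoU %.2f",
                    strip_path, ious[best],
                )
    return lanes
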