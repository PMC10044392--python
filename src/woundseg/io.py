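"""On-disk formats: images, masks, manifests, decisions, configs, overlays.

Conventions
-----------
* images: 8-bit RGB PNG (JPEG optional, quality 90); grayscale inputs
  are promoted to three identical channels; EXIF orientation is honored.
* masks: single-channel PNG with values {0, 255}; on read, values > 127
  map to foreground (a warning reports any other coerced values).
  Masks are never stored as JPEG — lossy compression corrupts labels.
* manifest: CSV with columns sample_id, image_path, mask_path,
  camera_tag, split_status.
* configs: YAML (or JSON) with the ASSLConfig schema; unknown keys are
  rejected, missing keys take defaults.
* round history: JSON, one record per round.

Every artifact written here reads back to an equal in-memory object.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageOps

from .assl import ASSLConfig, RoundState
from .metrics import FocalLossParams
from .model import TrainingConfig
from .synthetic import ImageSample
from .validation import ValidationThresholds

__all__ = [
    "read_image", "write_image", "read_mask", "write_mask",
    "read_manifest", "write_manifest", "write_dataset", "load_dataset",
    "render_overlay", "load_config", "save_config",
    "save_history", "load_history",
]

MANIFEST_COLUMNS = ["sample_id", "image_path", "mask_path", "camera_tag", "split_status"]


# ---------------------------------------------------------------------------
# images and masks


def read_image(path: str | Path) -> np.ndarray:
    """8-bit RGB raster from PNG/JPEG; grayscale promoted to 3 channels."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            im = im.convert("RGB")
            return np.asarray(im, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc


def write_image(pixels: np.ndarray, path: str | Path, jpeg_quality: int = 90) -> None:
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8 or arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected uint8 HxWx3 pixels, got {arr.dtype} {arr.shape}")
    img = Image.fromarray(arr, mode="RGB")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        img.save(path, quality=jpeg_quality)
    else:
        img.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Binary 0/1 mask from a single-channel PNG ({0,255} expected)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    coerced = int(np.count_nonzero((arr != 0) & (arr != 255)))
    if coerced:
        warnings.warn(
            f"mask {path} has {coerced} non-binary pixels; thresholding at 127",
            stacklevel=2,
        )
    return (arr > 127).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() not in (".png",):
        raise ValueError("masks must be written as PNG")
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


# ---------------------------------------------------------------------------
# manifest / dataset directories


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest has duplicate sample ids")
    bad = df[(df["split_status"] == "labeled") & (df["mask_path"] == "")]
    if len(bad):
        raise ValueError(f"labeled rows without mask_path: {list(bad['sample_id'])}")
    return df


def write_dataset(samples: list[ImageSample], out_dir: str | Path,
                  image_format: str = "png") -> pd.DataFrame:
    """Write images + masks + manifest.csv under a directory."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    rows = []
    for s in samples:
        img_rel = f"images/{s.sample_id}.{image_format}"
        write_image(s.pixels, out / img_rel)
        mask_rel = ""
        if s.truth_mask is not None:
            mask_rel = f"masks/{s.sample_id}.png"
            write_mask(s.truth_mask, out / mask_rel)
        rows.append({
            "sample_id": s.sample_id, "image_path": img_rel, "mask_path": mask_rel,
            "camera_tag": s.camera_tag,
            "split_status": "labeled" if mask_rel else "unlabeled",
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_manifest(manifest, out / "manifest.csv")
    return manifest


def load_dataset(dataset_dir: str | Path) -> list[ImageSample]:
    root = Path(dataset_dir)
    manifest = read_manifest(root / "manifest.csv")
    samples = []
    for row in manifest.itertuples(index=False):
        mask = read_mask(root / row.mask_path) if row.mask_path else None
        samples.append(ImageSample(
            sample_id=row.sample_id, pixels=read_image(root / row.image_path),
            truth_mask=mask, camera_tag=row.camera_tag,
        ))
    return samples


# ---------------------------------------------------------------------------
# overlays


def render_overlay(pixels: np.ndarray, mask: np.ndarray,
                   color: tuple[int, int, int] = (0, 200, 0),
                   fill_alpha: float = 0.35) -> np.ndarray:
    """Contour + translucent fill of a mask over its image.

    Pixels outside the mask's interior and a 2-px contour band are left
    untouched.  Pure function of its inputs.
    """
    img = np.asarray(pixels)
    m = np.asarray(mask).astype(bool)
    if img.shape[:2] != m.shape:
        raise ValueError(f"image {img.shape[:2]} and mask {m.shape} misaligned")
    out = img.astype(np.float64).copy()
    col = np.array(color, dtype=np.float64)
    interior = m
    out[interior] = (1.0 - fill_alpha) * out[interior] + fill_alpha * col
    from scipy import ndimage  # local import keeps module import light

    band = ndimage.binary_dilation(m, iterations=2) & ~ndimage.binary_erosion(m)
    out[band] = col
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# config


def _check_keys(cls, data: dict, where: str) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> ASSLConfig:
    """ASSLConfig from YAML/JSON; empty file means all defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    th = data.pop("thresholds", None) or {}
    tr = data.pop("training", None) or {}
    loss = tr.pop("loss", None) or {}
    _check_keys(ASSLConfig, data, "top level")
    _check_keys(ValidationThresholds, th, "thresholds")
    _check_keys(TrainingConfig, tr, "training")
    _check_keys(FocalLossParams, loss, "training.loss")
    return ASSLConfig(
        thresholds=ValidationThresholds(**th),
        training=TrainingConfig(loss=FocalLossParams(**loss), **tr),
        **data,
    )


def save_config(cfg: ASSLConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# round history


def save_history(history: list[RoundState], path: str | Path) -> None:
    records = [st.to_dict() for st in history]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def load_history(path: str | Path) -> list[RoundState]:
    records = json.loads(Path(path).read_text())
    return [RoundState.from_dict(r) for r in records]
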