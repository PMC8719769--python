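"""Dataset I/O: manifests, raster loading, FOV synthesis and resizing.

Dataset manifests are CSV files with header ``id,image,truth,fov,split``
(the layout of the public fundus benchmarks: one row per sample naming
the photograph, the manual vessel segmentation and, where available, the
binary field-of-view mask; the FOV column may be empty, in which case a
FOV is synthesised from the image).  Masks use {0, 1} with 1 = vessel;
coordinates are 0-based row-major.

Geometry policy: inputs are resized to the configured network size
(default 640x640) with bilinear interpolation for images and
nearest-neighbour for masks; predictions are mapped back to the native
resolution with nearest-neighbour before evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import binary_fill_holes
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("davsnet")

__all__ = [
    "ManifestRecord",
    "read_manifest",
    "write_manifest",
    "load_image",
    "load_mask",
    "load_sample",
    "synthesize_fov",
    "write_sample_triplet",
    "resize_image",
    "resize_mask",
    "segment_native",
    "load_config",
    "save_config",
    "setup_logging",
    "DEFAULT_CONFIG",
]

MANIFEST_COLUMNS = ["id", "image", "truth", "fov", "split"]

DEFAULT_CONFIG = {
    "network_size": 640,
    "learning_rate": 1e-3,
    "first_moment_decay": 0.9,
    "batch_size": 10,
    "epochs": 1,
    "seed": 0,
    "rotation_step": 1.0,
    "rotation_count": 360,
    "brightness_low": 0.8,
    "brightness_high": 1.2,
    "brightness_count": 20,
}


@dataclass(frozen=True)
class ManifestRecord:
    """One dataset sample: image, ground truth, optional FOV, split tag."""

    sample_id: str
    image: str
    truth: str
    fov: Optional[str] = None
    split: str = "train"


def read_manifest(path, check_files: bool = True) -> list[ManifestRecord]:
    """Read a dataset manifest CSV; ids must be unique and referenced
    files must exist (paths are resolved relative to the manifest)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate sample ids in manifest: {dupes}")
    root = path.parent
    records = []
    for _, row in df.iterrows():
        rec = ManifestRecord(
            sample_id=row["id"],
            image=str(root / row["image"]),
            truth=str(root / row["truth"]),
            fov=str(root / row["fov"]) if row["fov"] else None,
            split=row["split"] or "train",
        )
        if check_files:
            for f in (rec.image, rec.truth, rec.fov):
                if f is not None and not Path(f).exists():
                    raise FileNotFoundError(f"manifest {path}: missing file {f}")
        records.append(rec)
    return records


def write_manifest(records: Sequence[ManifestRecord], path) -> None:
    """Write a manifest CSV with paths stored relative to the manifest."""
    path = Path(path)
    root = path.parent

    def rel(p):
        if p is None:
            return ""
        try:
            return str(Path(p).relative_to(root))
        except ValueError:
            return str(p)

    df = pd.DataFrame(
        [
            {"id": r.sample_id, "image": rel(r.image), "truth": rel(r.truth),
             "fov": rel(r.fov), "split": r.split}
            for r in records
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_image(path) -> np.ndarray:
    """Read a raster image as (H, W, 3) uint8.

    Grayscale inputs are replicated to 3 channels; an alpha channel is
    dropped.  Supported formats: PNG, TIFF, PPM, GIF, JPEG.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 4:  # animated GIF: first frame
        arr = arr[0]
    if arr.dtype != np.uint8:
        arr = np.clip(arr.astype(np.float64) / arr.max() * 255, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr


def load_mask(path) -> np.ndarray:
    """Read a mask image as binary {0, 1}, thresholding grayscale at the
    midpoint of its dtype range; warns if the stored mask was not binary."""
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    levels = np.unique(arr)
    if len(levels) > 2:
        warnings.warn(f"mask {path} is not binary ({len(levels)} levels); thresholding at midpoint")
        logger.warning("mask %s is not binary (%d levels)", path, len(levels))
    mid = 127.5 if arr.dtype == np.uint8 else (arr.max() + arr.min()) / 2.0
    return (arr > mid).astype(np.uint8)


def synthesize_fov(image: np.ndarray, threshold_fraction: float = 0.15) -> np.ndarray:
    """Estimate a field-of-view mask from the image itself.

    Some benchmark datasets ship no FOV masks; the bright imaged disc is
    recovered by intensity thresholding, morphological closing, hole
    filling, and keeping the largest connected region.
    """
    gray = np.asarray(image, dtype=np.float64)
    if gray.ndim == 3:
        gray = gray.mean(axis=-1)
    binary = gray > threshold_fraction * gray.max()
    binary = closing(binary, disk(3))
    lab = label(binary)
    if lab.max() == 0:
        raise ValueError("cannot synthesise FOV: no bright region found")
    largest = max(regionprops(lab), key=lambda r: r.area).label
    return binary_fill_holes(lab == largest).astype(np.uint8)


def load_sample(record: ManifestRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a manifest record as (image, truth mask, FOV mask).

    A missing FOV entry triggers :func:`synthesize_fov` on the image.
    """
    image = load_image(record.image)
    truth = load_mask(record.truth)
    if truth.shape != image.shape[:2]:
        raise ValueError(
            f"{record.sample_id}: truth mask {truth.shape} does not match "
            f"image {image.shape[:2]}"
        )
    if record.fov is not None:
        fov = load_mask(record.fov)
        if fov.shape != image.shape[:2]:
            raise ValueError(
                f"{record.sample_id}: FOV mask {fov.shape} does not match "
                f"image {image.shape[:2]}"
            )
    else:
        fov = synthesize_fov(image)
    return image, truth, fov


def write_sample_triplet(out_dir, sample_id: str, image, truth, fov):
    """Write a sample as PNG triplet; returns (id, image, truth, fov) paths."""
    out_dir = Path(out_dir)
    paths = (
        out_dir / f"{sample_id}.png",
        out_dir / f"{sample_id}_truth.png",
        out_dir / f"{sample_id}_fov.png",
    )
    iio.imwrite(paths[0], np.asarray(image, dtype=np.uint8))
    iio.imwrite(paths[1], (np.asarray(truth, dtype=np.uint8) * 255))
    if fov is not None:
        iio.imwrite(paths[2], (np.asarray(fov, dtype=np.uint8) * 255))
    return (sample_id, str(paths[0]), str(paths[1]), str(paths[2]) if fov is not None else None)


def resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to (height, width), staying uint8."""
    out = _sk_resize(image, size + image.shape[2:], order=1, preserve_range=True,
                     anti_aliasing=False)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize; the result stays strictly binary."""
    out = _sk_resize(mask.astype(np.uint8), size, order=0, preserve_range=True,
                     anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def segment_native(model, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment an image of any size with a fixed-size model.

    The image is resized to the model's input size, segmented, and the
    probability/mask pair is mapped back to the native resolution with
    nearest-neighbour so evaluation happens against the original ground
    truth.  Returns (vessel probability map, binary mask), both at
    native size.
    """
    s = model.graph.input_shape
    native = image.shape[:2]
    resized = resize_image(image, (s.height, s.width))
    probs = model.forward(resized)
    vessel_prob = probs[..., 0]
    if native != (s.height, s.width):
        vessel_prob = _sk_resize(vessel_prob, native, order=0, preserve_range=True)
    mask = (vessel_prob > 0.5).astype(np.uint8)
    return vessel_prob, mask


def load_config(path) -> dict:
    """Read a YAML key/value config, filling unspecified keys with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def setup_logging(log_file=None, level=logging.INFO) -> None:
    """Timestamped, leveled logging to console and optionally a file."""
    handlers = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
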