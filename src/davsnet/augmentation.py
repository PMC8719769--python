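"""Training-set augmentation: rotations and brightness perturbation.

The recipe rotates each training image in 1-degree steps and perturbs
brightness multiplicatively, "randomly increasing and decreasing" it, so
the factor interval must straddle 1.  Images are interpolated smoothly
(bilinear); vessel and FOV masks are rotated with nearest-neighbour so
they remain strictly binary.  The standard preset — 360 rotations plus
20 brightness variants per image — yields 7,600 variants from a
20-image training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "AugmentationConfig",
    "rotate_pair",
    "brightness_perturb",
    "build_augmented_set",
    "preset_rotation360_brightness20",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Augmentation recipe.

    ``rotation_count`` rotations at multiples of ``rotation_step``
    degrees plus ``brightness_count`` brightness variants with factors
    drawn uniformly from ``brightness_range`` are produced per source
    image.
    """

    rotation_step: float = 1.0
    rotation_count: int = 360
    brightness_range: tuple[float, float] = (0.8, 1.2)
    brightness_count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_step <= 0:
            raise ValueError("rotation_step must be > 0")
        if self.rotation_count < 0 or self.brightness_count < 0:
            raise ValueError("variant counts must be >= 0")
        lo, hi = self.brightness_range
        if self.brightness_count and not (0 < lo < 1 < hi):
            raise ValueError(
                "brightness_range must be positive and contain factors both "
                f"below and above 1 (randomly increasing and decreasing), got {self.brightness_range}"
            )

    @property
    def variants_per_image(self) -> int:
        return self.rotation_count + self.brightness_count


def preset_rotation360_brightness20(seed: int = 0) -> AugmentationConfig:
    """The published recipe's consistent reading: 360 one-degree rotations
    and 20 brightness variants per image (7,600 variants from 20 images)."""
    return AugmentationConfig(rotation_step=1.0, rotation_count=360,
                              brightness_range=(0.8, 1.2), brightness_count=20, seed=seed)


def rotate_pair(
    image: np.ndarray,
    mask: Optional[np.ndarray],
    fov: Optional[np.ndarray],
    angle: float,
) -> tuple[np.ndarray, Optional[np.ndarray], Optional[np.ndarray]]:
    """Rotate an image and its masks consistently about the image centre.

    The canvas size is preserved and exposed corners fill with 0.  The
    image is interpolated bilinearly at its native dtype range; masks use
    nearest-neighbour and stay binary.
    """
    if not np.isfinite(angle):
        raise ValueError(f"rotation angle must be finite, got {angle}")
    img = np.asarray(image)
    out = _sk_rotate(img.astype(np.float64), angle, resize=False, order=1,
                     mode="constant", cval=0.0, preserve_range=True)
    if img.dtype == np.uint8:
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    else:
        out = out.astype(img.dtype)

    def _rot_mask(m):
        if m is None:
            return None
        m = np.asarray(m)
        r = _sk_rotate(m.astype(np.float64), angle, resize=False, order=0,
                       mode="constant", cval=0.0, preserve_range=True)
        return (r > 0.5).astype(m.dtype)

    return out, _rot_mask(mask), _rot_mask(fov)


def brightness_perturb(image: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative brightness scaling, clipped to the valid intensity
    range (0..255 for uint8, 0..1 for floats).  Masks are never touched
    by brightness changes."""
    if not (np.isfinite(factor) and factor > 0):
        raise ValueError(f"brightness factor must be finite and > 0, got {factor}")
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return np.clip(np.rint(img.astype(np.float64) * factor), 0, 255).astype(np.uint8)
    return np.clip(img.astype(np.float64) * factor, 0.0, 1.0).astype(img.dtype)


def build_augmented_set(
    samples: Sequence[tuple],
    config: AugmentationConfig,
    out_dir=None,
):
    """Produce the augmented variants and their manifest.

    ``samples`` is a sequence of ``(source_id, image, mask, fov)`` tuples
    (``fov`` may be None).  Returns ``(variants, manifest)`` where
    ``manifest`` is a DataFrame with one row per variant recording the
    source id, transform kind and parameter; identical config and seed
    give identical manifests and variants.  With ``out_dir`` set, the
    variants are written as PNG triplets instead of kept in memory and
    the returned list holds their paths.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    variants = []
    writer = None
    if out_dir is not None:
        from . import data as _data  # local import: io layer depends on nothing here

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        writer = _data.write_sample_triplet

    for source_id, image, mask, fov in samples:
        for k in range(1, config.rotation_count + 1):
            angle = k * config.rotation_step
            var_id = f"{source_id}_rot{k:03d}"
            img, m, f = rotate_pair(image, mask, fov, angle)
            rows.append({"variant_id": var_id, "source_id": source_id,
                         "transform": "rotation", "angle": angle,
                         "factor": np.nan, "seed": config.seed})
            variants.append(writer(out_dir, var_id, img, m, f) if writer else (var_id, img, m, f))
        factors = rng.uniform(*config.brightness_range, size=config.brightness_count)
        for k, factor in enumerate(factors, start=1):
            var_id = f"{source_id}_bri{k:03d}"
            img = brightness_perturb(image, float(factor))
            rows.append({"variant_id": var_id, "source_id": source_id,
                         "transform": "brightness", "angle": np.nan,
                         "factor": float(factor), "seed": config.seed})
            variants.append(writer(out_dir, var_id, img, mask, fov) if writer else (var_id, img, mask, fov))

    manifest = pd.DataFrame(
        rows, columns=["variant_id", "source_id", "transform", "angle", "factor", "seed"]
    )
    if out_dir is not None:
        manifest.to_csv(out_dir / "augmentation_manifest.csv", index=False)
    return variants, manifest
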