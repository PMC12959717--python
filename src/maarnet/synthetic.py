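"""Synthetic PAS-style kidney tiles with paired microvessel masks.

Real inputs to the segmentation model are 512x512 RGB tiles cut from
PAS-stained whole-slide kidney images, with single-channel PNG masks
marking microvascular structures.  This module emulates that format so the
full pipeline (training, evaluation, compression) is exercisable without
any download: a pink-purple textured background (smoothed correlated
noise, mimicking stained tissue) over which thin curvilinear tubes
(random-walk centerlines of varying width) and ring-shaped vessel walls
with brighter lumina are rendered at configurable low contrast.  The mask
is the exact foreground support.

Everything is deterministic given ``(config, seed)``: a single
``numpy.random.default_rng(seed)`` drives the sample and values are drawn
in a fixed order (background field, vessel count, then per-vessel
geometry), so pairs are bit-identical across platforms.

Images and masks are written as PNG — RGB 8-bit and 8-bit grayscale with
foreground stored as 255 — and binarized (``> 0``) on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

__all__ = ["SynthConfig", "SamplePair", "SampleIOError", "generate_sample",
           "generate_dataset", "read_sample", "write_sample", "split_sizes"]

# PAS palette: light pink tissue, purple-magenta stained structures
_BACKGROUND_RGB = np.array([232.0, 205.0, 220.0])
_TINT_RGB = np.array([-40.0, -55.0, -25.0])       # scaled by the texture field
_VESSEL_RGB = np.array([150.0, 80.0, 140.0])      # target color at contrast 1
_LUMEN_RGB = np.array([245.0, 235.0, 242.0])      # bright lumen interior


class SampleIOError(IOError):
    """Raised when an image/mask pair cannot be read or is inconsistent."""


@dataclass(frozen=True)
class SynthConfig:
    tile_size: int = 512
    n_vessels: tuple[int, int] = (4, 10)        # inclusive range per tile
    vessel_width: tuple[float, float] = (2.0, 12.0)
    ring_fraction: float = 0.3                  # proportion of ring structures
    contrast: float = 0.45                      # 0 = invisible .. 1 = full stain
    noise_sd: float = 0.5                       # background texture amplitude

    def __post_init__(self):
        if self.tile_size % 32:
            raise ValueError("tile_size must be divisible by 32")
        if self.n_vessels[0] > self.n_vessels[1] or self.n_vessels[0] < 0:
            raise ValueError("invalid n_vessels range")
        if self.vessel_width[0] > self.vessel_width[1] or self.vessel_width[0] <= 0:
            raise ValueError("invalid vessel_width range")
        if not 0.0 <= self.ring_fraction <= 1.0:
            raise ValueError("ring_fraction must be in [0, 1]")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")


@dataclass
class SamplePair:
    image: np.ndarray   # (H, W, 3) uint8
    mask: np.ndarray    # (H, W) uint8 in {0, 1}

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask spatial dimensions differ")


def _background(rng: np.random.Generator, size: int, noise_sd: float) -> np.ndarray:
    """Smoothed correlated noise tinted to the PAS palette, float RGB."""
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=12)
    field = field / (field.std() + 1e-9) * noise_sd
    fine = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=2)
    fine = fine / (fine.std() + 1e-9) * (0.3 * noise_sd)
    tex = np.clip(field + fine, -1.5, 1.5)
    return _BACKGROUND_RGB + tex[..., None] * _TINT_RGB


def _tube_support(rng: np.random.Generator, size: int,
                  width_range: tuple[float, float]) -> np.ndarray:
    """Distance-based support of one random-walk tube, bool (H, W)."""
    n_steps = int(rng.integers(size // 2, size * 2))
    pos = rng.uniform(0.1 * size, 0.9 * size, size=2)
    angle = rng.uniform(0, 2 * np.pi)
    width = rng.uniform(*width_range)
    pts = np.empty((n_steps, 2))
    for i in range(n_steps):
        pts[i] = pos
        angle += rng.normal(0.0, 0.15)
        pos = pos + np.array([np.cos(angle), np.sin(angle)])
    pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < size)
              & (pts[:, 1] >= 0) & (pts[:, 1] < size)]
    canvas = np.zeros((size, size), dtype=bool)
    if len(pts) == 0:
        return canvas
    canvas[pts[:, 0].astype(int), pts[:, 1].astype(int)] = True
    dist = ndimage.distance_transform_edt(~canvas)
    return dist <= width / 2.0


def _ring_support(rng: np.random.Generator, size: int,
                  width_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Annular vessel wall plus its lumen interior, both bool (H, W)."""
    radius = rng.uniform(4.0, max(8.0, 0.08 * size))
    thickness = np.clip(rng.uniform(*width_range) / 2.0, 1.0, radius - 1.0)
    cy, cx = rng.uniform(0.1 * size, 0.9 * size, size=2)
    yy, xx = np.ogrid[:size, :size]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    wall = np.abs(dist - radius) <= thickness / 2.0
    lumen = dist < radius - thickness / 2.0
    return wall, lumen


def generate_sample(config: SynthConfig, seed: int) -> SamplePair:
    """One deterministic image/mask pair for ``(config, seed)``."""
    rng = np.random.default_rng(seed)
    size = config.tile_size
    img = _background(rng, size, config.noise_sd)

    n = int(rng.integers(config.n_vessels[0], config.n_vessels[1] + 1))
    mask = np.zeros((size, size), dtype=bool)
    lumen_all = np.zeros((size, size), dtype=bool)
    for _ in range(n):
        if rng.uniform() < config.ring_fraction:
            wall, lumen = _ring_support(rng, size, config.vessel_width)
            mask |= wall
            lumen_all |= lumen
        else:
            mask |= _tube_support(rng, size, config.vessel_width)
    lumen_all &= ~mask

    # render at configured contrast: the exact support is stained uniformly
    # (the mask stays recoverable from the image) with a soft halo outside
    halo = ndimage.gaussian_filter(mask.astype(float), sigma=1.0) * 0.5
    alpha = np.where(mask, 1.0, np.clip(halo, 0.0, 1.0)) * config.contrast
    img = img * (1 - alpha[..., None]) + _VESSEL_RGB * alpha[..., None]
    lum_alpha = lumen_all.astype(float) * config.contrast
    img = img * (1 - lum_alpha[..., None]) + _LUMEN_RGB * lum_alpha[..., None]

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SamplePair(image=image, mask=mask.astype(np.uint8))


def split_sizes(n_total: int, ratios=(6, 2, 2)) -> tuple[int, ...]:
    """Split ``n_total`` in the given ratio (train, val, test).

    The validation and test sizes round to the nearest integer and the
    training split takes the remainder, which reproduces the canonical
    6:2:2 splits (10 -> 6/2/2, 1633 -> 979/327/327).
    """
    total = sum(ratios)
    tail = [round(n_total * r / total) for r in ratios[1:]]
    head = n_total - sum(tail)
    if head < 0:
        raise ValueError("ratio rounding exceeded the total")
    return (head, *tail)


def write_sample(pair: SamplePair, image_path, mask_path) -> None:
    Image.fromarray(pair.image, mode="RGB").save(image_path)
    Image.fromarray(pair.mask * np.uint8(255), mode="L").save(mask_path)


def read_sample(image_path, mask_path) -> SamplePair:
    """Load an RGB tile and its mask; masks binarize at ``> 0``."""
    try:
        image = np.asarray(Image.open(image_path).convert("RGB"))
        mask_raw = np.asarray(Image.open(mask_path).convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise SampleIOError(f"cannot read sample: {exc}") from exc
    mask = (mask_raw > 0).astype(np.uint8)
    if image.shape[:2] != mask.shape:
        raise SampleIOError(
            f"size mismatch: image {image.shape[:2]} vs mask {mask.shape}")
    return SamplePair(image=image, mask=mask)


def generate_dataset(config: SynthConfig, n_total: int, seed: int,
                     out_dir) -> list[dict]:
    """Write ``n_total`` pairs split 6:2:2 into train/val/test; return manifest.

    The manifest (also written as ``manifest.tsv``) has one row per sample:
    index, split, image path and mask path (relative to ``out_dir``).
    """
    out = Path(out_dir)
    n_train, n_val, n_test = split_sizes(n_total)
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    manifest = []
    for split in ("train", "val", "test"):
        (out / split).mkdir(parents=True, exist_ok=True)
    for i, split in enumerate(splits):
        pair = generate_sample(config, seed=(seed + i) % (2 ** 31))
        img_rel = f"{split}/img_{i:05d}.png"
        mask_rel = f"{split}/mask_{i:05d}.png"
        write_sample(pair, out / img_rel, out / mask_rel)
        manifest.append({"index": i, "split": split, "image": img_rel,
                         "mask": mask_rel})
    with open(out / "manifest.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["index", "split", "image", "mask"],
                                delimiter="\t")
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
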