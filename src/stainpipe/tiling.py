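"""Magnification handling, tissue segmentation, tiling, and geometric
augmentation for large histology images."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Literal, Optional, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import downscale_local_mean, rotate as _sk_rotate

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "TileSpec",
    "Tile",
    "pre_rotation_side",
    "rescale_to_magnification",
    "segment_tissue",
    "plan_tiles",
    "extract_tiles",
    "rotate_and_crop",
    "maybe_reflect",
]

#: Rec.601 luminance weights used for grayscale conversion before Otsu.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Intensity range below which an image is treated as blank (no tissue).
BLANK_RANGE_FLOOR = 1.0


def pre_rotation_side(crop_side: int = 224) -> int:
    """Side of the oversized tile extracted before random rotation:
    the crop side scaled by sqrt(2), truncated to whole pixels."""
    return int(math.floor(crop_side * math.sqrt(2.0)))


@dataclass(frozen=True)
class TileSpec:
    """Tiling geometry and retention policy."""

    tile_size: int = 224
    stride: int = 112  # inference stride; training uses training_stride
    training_stride: int = 56
    min_tissue_fraction: float = 0.10
    training_tile_size: int = 316
    target_magnification: int = 10

    def __post_init__(self):
        if not (0 < self.stride <= self.tile_size):
            raise ConfigurationError("need 0 < stride <= tile_size")
        if not (0 < self.training_stride <= self.training_tile_size):
            raise ConfigurationError("need 0 < training_stride <= training_tile_size")
        if not (0.0 <= self.min_tissue_fraction <= 1.0):
            raise ConfigurationError("min_tissue_fraction must be in [0, 1]")
        if self.training_tile_size < self.tile_size:
            raise ConfigurationError("training_tile_size must be >= tile_size")


@dataclass
class Tile:
    """A square patch cut from a slide on the sliding-window grid.

    ``row``/``col`` are the 0-based top-left coordinates of the half-open
    window ``[row, row+size) x [col, col+size)`` in source-image pixels.
    """

    pixels: np.ndarray
    row: int
    col: int
    tissue_fraction: float
    slide_id: str = ""

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def rescale_to_magnification(
    img: np.ndarray, native_mag: int, spec: TileSpec = TileSpec()
) -> np.ndarray:
    """Downsample from the native objective power to the working one using
    block (local-mean) resampling.  Identity when the powers match."""
    if native_mag not in (10, 20, 40):
        raise ConfigurationError(f"unsupported magnification x{native_mag}")
    target = spec.target_magnification
    if native_mag < target:
        raise ConfigurationError(
            f"cannot upsample from x{native_mag} to x{target}"
        )
    if native_mag == target:
        return img
    factor = native_mag // target
    arr = np.asarray(img)
    h = (arr.shape[0] // factor) * factor
    w = (arr.shape[1] // factor) * factor
    trimmed = arr[:h, :w].astype(np.float64)
    if trimmed.ndim == 3:
        out = downscale_local_mean(trimmed, (factor, factor, 1))
    else:
        out = downscale_local_mean(trimmed, (factor, factor))
    if np.issubdtype(arr.dtype, np.integer):
        return np.clip(np.rint(out), 0, np.iinfo(arr.dtype).max).astype(arr.dtype)
    return out


def _luminance(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        return arr @ LUMA_WEIGHTS
    return arr


def segment_tissue(img: np.ndarray) -> np.ndarray:
    """Boolean tissue mask: pixels darker than the Otsu threshold of the
    luminance histogram.  Near-constant images yield an all-false mask."""
    lum = _luminance(img)
    if float(lum.max() - lum.min()) < BLANK_RANGE_FLOOR:
        return np.zeros(lum.shape, dtype=bool)
    thr = threshold_otsu(lum)
    return lum < thr


def plan_tiles(
    height: int, width: int, size: int, stride: int
) -> List[Tuple[int, int]]:
    """Row-major sliding-window positions; windows that would extend past
    the image are dropped, not padded."""
    if size <= 0 or stride <= 0:
        raise InvalidInputError("size and stride must be positive")
    rows = range(0, max(height - size, -1) + 1, stride)
    cols = range(0, max(width - size, -1) + 1, stride)
    return [(r, c) for r in rows for c in cols]


def extract_tiles(
    img: np.ndarray,
    mask: np.ndarray,
    spec: TileSpec = TileSpec(),
    mode: Literal["training", "inference"] = "inference",
    slide_id: str = "",
) -> List[Tile]:
    """Cut tiles on the mode-specific grid and keep those whose window
    tissue fraction is at least ``min_tissue_fraction`` (inclusive)."""
    arr = np.asarray(img)
    m = np.asarray(mask)
    if m.shape != arr.shape[:2]:
        raise InvalidInputError(
            f"mask shape {m.shape} does not match image {arr.shape[:2]}"
        )
    if mode == "training":
        size, stride = spec.training_tile_size, spec.training_stride
    elif mode == "inference":
        size, stride = spec.tile_size, spec.stride
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    tiles = []
    for r, c in plan_tiles(arr.shape[0], arr.shape[1], size, stride):
        frac = float(m[r : r + size, c : c + size].mean())
        if frac >= spec.min_tissue_fraction:
            tiles.append(
                Tile(
                    pixels=arr[r : r + size, c : c + size].copy(),
                    row=r,
                    col=c,
                    tissue_fraction=frac,
                    slide_id=slide_id,
                )
            )
    return tiles


def rotate_and_crop(
    tile: Tile, angle_degrees: float, crop_size: int = 224, fill: float = 255.0
) -> Tile:
    """Rotate an oversized training tile about its centre (bilinear, white
    fill outside the support) and centre-crop to ``crop_size``."""
    px = tile.pixels
    if px.shape[0] != px.shape[1]:
        raise InvalidInputError("rotation expects a square tile")
    side = px.shape[0]
    if side < crop_size:
        raise InvalidInputError(
            f"tile side {side} smaller than crop size {crop_size}"
        )
    angle = angle_degrees % 360.0
    if angle % 90.0 == 0.0:
        rotated = np.rot90(px, k=int(angle // 90))
    else:
        rotated = _sk_rotate(
            px.astype(np.float64),
            angle,
            resize=False,
            order=1,
            mode="constant",
            cval=fill,
            preserve_range=True,
        )
        if np.issubdtype(px.dtype, np.integer):
            rotated = np.clip(np.rint(rotated), 0, np.iinfo(px.dtype).max)
        rotated = rotated.astype(px.dtype)
    off = (side - crop_size) // 2
    cropped = rotated[off : off + crop_size, off : off + crop_size].copy()
    return replace(tile, pixels=cropped)


def maybe_reflect(
    tile: Tile, p: float = 0.5, rng: Optional[np.random.Generator] = None
) -> Tile:
    """With probability ``p`` reverse the column order (reflection over the
    vertical axis); seeded-reproducible via ``rng``."""
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError("p must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    if rng.random() < p:
        return replace(tile, pixels=tile.pixels[:, ::-1].copy())
    return tile
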