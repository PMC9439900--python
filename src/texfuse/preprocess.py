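"""Image loading and canonical preprocessing.

Every image entering the pipeline is reduced to a single-channel float
grid in ``[0, 1]`` (a :class:`GrayImage`), then optionally cropped,
min–max normalized and resized to a fixed square (224×224 by default,
matching the VGG input convention).  All texture operators and the
network consume this canonical form; 8-bit quantisation only happens at
file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Tuple

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

__all__ = [
    "GrayImage",
    "PreprocessConfig",
    "load_gray",
    "crop",
    "normalize_minmax",
    "resize",
    "preprocess_image",
]

_MIN_EXTENT = 3  # texture operators need a full 3x3 neighborhood

CROP_MODES = ("none", "center_square", "fixed_margin")


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale intensity grid with provenance.

    ``pixels`` is a float64 array; after normalization values lie in
    ``[0, 1]``.  ``source_id`` is an opaque provenance string (usually
    the file path or a synthetic-generator tag).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        if px.shape[0] < _MIN_EXTENT or px.shape[1] < _MIN_EXTENT:
            raise ValueError(
                f"GrayImage must be at least {_MIN_EXTENT}x{_MIN_EXTENT}, got {px.shape}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class PreprocessConfig:
    """Resolved preprocessing parameters.

    crop_mode
        ``none`` | ``center_square`` | ``fixed_margin``.  Radiographs
        commonly carry lateral background bands; the default
        ``center_square`` keeps the largest centered square.
    margin_fraction
        Fraction of each side removed by ``fixed_margin`` (in [0, 0.45]).
    target_size
        Output (height, width) of :func:`resize`; components >= 8.
    """

    crop_mode: str = "center_square"
    margin_fraction: float = 0.0
    target_size: Tuple[int, int] = (224, 224)

    def __post_init__(self) -> None:
        if self.crop_mode not in CROP_MODES:
            raise ValueError(f"crop_mode must be one of {CROP_MODES}, got {self.crop_mode!r}")
        if not (0.0 <= self.margin_fraction <= 0.45):
            raise ValueError(f"margin_fraction must lie in [0, 0.45], got {self.margin_fraction}")
        th, tw = self.target_size
        if th < 8 or tw < 8:
            raise ValueError(f"target_size components must be >= 8, got {self.target_size}")


def load_gray(path: str | Path) -> GrayImage:
    """Load a PNG/JPEG file as a [0, 1] grayscale image.

    Color inputs are converted with the standard ITU-R 601 luminance
    weighting (Pillow mode ``L`` for 8-bit, ``F`` after conversion).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("F") if im.mode in ("F", "I", "I;16") else im.convert("L")
            arr = np.asarray(im, dtype=np.float64)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    # 8-bit (mode L) data scales by 255; float inputs are assumed pre-scaled
    if arr.max() > 1.0:
        arr = arr / 255.0
    return GrayImage(np.clip(arr, 0.0, 1.0), source_id=str(path))


def crop(img: GrayImage, cfg: PreprocessConfig) -> GrayImage:
    """Crop per ``cfg.crop_mode`` (identity for ``none``)."""
    h, w = img.height, img.width
    if cfg.crop_mode == "none":
        return img
    if cfg.crop_mode == "center_square":
        side = min(h, w)
        top = (h - side) // 2
        left = (w - side) // 2
        out = img.pixels[top : top + side, left : left + side]
    else:  # fixed_margin
        mh = int(round(cfg.margin_fraction * h))
        mw = int(round(cfg.margin_fraction * w))
        out = img.pixels[mh : h - mh, mw : w - mw]
    if out.shape[0] < _MIN_EXTENT or out.shape[1] < _MIN_EXTENT:
        raise ValueError(
            f"crop of {h}x{w} with mode={cfg.crop_mode} leaves {out.shape}, "
            f"smaller than {_MIN_EXTENT}x{_MIN_EXTENT}"
        )
    return GrayImage(out.copy(), source_id=img.source_id)


def normalize_minmax(img: GrayImage) -> GrayImage:
    """Min–max normalize to [0, 1]; a constant image maps to all zeros."""
    px = img.pixels
    lo = px.min()
    hi = px.max()
    if hi == lo:
        return GrayImage(np.zeros_like(px), source_id=img.source_id)
    return GrayImage((px - lo) / (hi - lo), source_id=img.source_id)


def resize(img: GrayImage, cfg: PreprocessConfig) -> GrayImage:
    """Bilinear resize to ``cfg.target_size``, clipped to [0, 1]."""
    th, tw = cfg.target_size
    if (img.height, img.width) == (th, tw):
        return img
    out = _sk_resize(
        img.pixels, (th, tw), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    return GrayImage(np.clip(out, 0.0, 1.0), source_id=img.source_id)


def preprocess_image(path: str | Path, cfg: PreprocessConfig | None = None) -> GrayImage:
    """Full pipeline: load → crop → min–max normalize → resize."""
    cfg = cfg or PreprocessConfig()
    return resize(normalize_minmax(crop(load_gray(path), cfg)), cfg)
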