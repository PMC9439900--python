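"""Histogram-of-oriented-gradients (HOG) feature images.

Gradients are plain central differences, Fx = H(x+1,y) - H(x-1,y) and
Fy = H(x,y+1) - H(x,y-1) (no 1/2 factor), with replicate-padded
borders.  Gradient magnitude is sqrt(Fx^2 + Fy^2); the orientation is
the quadrant-aware angle of (Fy, Fx), optionally folded to [0, 180)
for unsigned gradients.  The image is tiled into non-overlapping
square cells; every pixel votes its magnitude into the two orientation
bins nearest its angle with linear interpolation, so the per-cell
histogram mass equals the cell's total gradient magnitude.  The
descriptor is rendered back to a grayscale image either as the
dominant bin magnitude per cell (default, preserves cell resolution)
or as oriented line glyphs.

``orientation_formula="as_printed"`` swaps the arctangent arguments
(angle of (Fx, Fy) instead of (Fy, Fx)), which mirrors every angle
about the 45-degree diagonal; it exists so both conventions can be
compared, the conventional form being the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage.draw import line as _draw_line

from .preprocess import GrayImage

__all__ = [
    "HogConfig",
    "GradientField",
    "HogDescriptor",
    "gradients",
    "cell_histograms",
    "render_hog_image",
    "hog_feature_image",
]

CELL_SIZES = (2, 4, 8, 16, 32)
RENDER_MODES = ("dominant", "glyph")


@dataclass(frozen=True)
class HogConfig:
    cell_size: int = 2
    n_bins: int = 9
    signed_gradients: bool = False
    render_mode: str = "dominant"
    orientation_formula: str = "conventional"  # or "as_printed"

    def __post_init__(self) -> None:
        if self.cell_size not in CELL_SIZES:
            raise ValueError(f"cell_size must be one of {CELL_SIZES}, got {self.cell_size}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if self.render_mode not in RENDER_MODES:
            raise ValueError(f"render_mode must be one of {RENDER_MODES}")
        if self.orientation_formula not in ("conventional", "as_printed"):
            raise ValueError("orientation_formula must be 'conventional' or 'as_printed'")

    @property
    def angle_range(self) -> float:
        return 360.0 if self.signed_gradients else 180.0


@dataclass(frozen=True)
class GradientField:
    """Central-difference gradients, their magnitude and orientation.

    ``orientation`` is in degrees in [0, 180) (unsigned) or [0, 360)
    (signed); it is arbitrary (set to 0) where the magnitude is 0.
    """

    fx: np.ndarray
    fy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray


@dataclass(frozen=True)
class HogDescriptor:
    """(cells_y, cells_x, n_bins) grid of unnormalized vote histograms."""

    cell_histograms: np.ndarray
    config: HogConfig

    def __post_init__(self) -> None:
        h = np.asarray(self.cell_histograms, dtype=np.float64)
        if h.ndim != 3 or h.size == 0:
            raise ValueError(f"cell_histograms must be non-empty 3-D, got shape {h.shape}")
        object.__setattr__(self, "cell_histograms", h)


def gradients(img: GrayImage, cfg: HogConfig | None = None) -> GradientField:
    """Central differences with replicate-padded borders."""
    cfg = cfg or HogConfig()
    px = img.pixels
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError(f"image {px.shape} too small for gradients (need >= 3x3)")
    padded = np.pad(px, 1, mode="edge")
    fx = padded[1:-1, 2:] - padded[1:-1, :-2]   # H(x+1,y) - H(x-1,y), x = column
    fy = padded[2:, 1:-1] - padded[:-2, 1:-1]   # H(x,y+1) - H(x,y-1), y = row
    mag = np.hypot(fx, fy)
    if cfg.orientation_formula == "as_printed":
        ang = np.degrees(np.arctan2(fx, fy))
    else:
        ang = np.degrees(np.arctan2(fy, fx))
    ang = np.mod(ang, cfg.angle_range)
    ang[mag == 0] = 0.0
    return GradientField(fx=fx, fy=fy, magnitude=mag, orientation=ang)


def cell_histograms(g: GradientField, cfg: HogConfig) -> HogDescriptor:
    """Accumulate per-cell orientation histograms by bilinear bin voting.

    Bin i is centered at (i + 0.5) * angle_range / n_bins; each pixel
    splits its magnitude between the two nearest bin centers (circular
    wrap), so total votes per cell equal total magnitude per cell.
    Trailing rows/columns that do not fill a cell are dropped.
    """
    cs = cfg.cell_size
    h, w = g.magnitude.shape
    cy, cx = h // cs, w // cs
    if cy == 0 or cx == 0:
        raise ValueError(f"cell_size {cs} larger than image extent {(h, w)}")
    mag = g.magnitude[: cy * cs, : cx * cs]
    ang = g.orientation[: cy * cs, : cx * cs]
    nb = cfg.n_bins
    width = cfg.angle_range / nb
    f = ang / width - 0.5
    lo = np.floor(f)
    frac = f - lo
    b0 = lo.astype(np.int64) % nb
    b1 = (b0 + 1) % nb
    v0 = mag * (1.0 - frac)
    v1 = mag * frac

    hist = np.zeros((cy, cx, nb), dtype=np.float64)
    cell_r = (np.arange(cy * cs) // cs)[:, None] * cx
    cell_c = (np.arange(cx * cs) // cs)[None, :]
    flat_cell = (cell_r + cell_c).ravel()
    np.add.at(hist.reshape(-1, nb), (flat_cell, b0.ravel()), v0.ravel())
    np.add.at(hist.reshape(-1, nb), (flat_cell, b1.ravel()), v1.ravel())
    return HogDescriptor(cell_histograms=hist, config=cfg)


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    return np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)


def render_hog_image(d: HogDescriptor, out_size: Tuple[int, int]) -> GrayImage:
    """Render the descriptor as a [0, 1] grayscale image of ``out_size``."""
    cy, cx, nb = d.cell_histograms.shape
    oh, ow = out_size
    if d.config.render_mode == "dominant":
        cell_img = _minmax(d.cell_histograms.max(axis=2))
        ry = (np.arange(oh) * cy) // oh
        rx = (np.arange(ow) * cx) // ow
        out = cell_img[np.ix_(ry, rx)]
        return GrayImage(np.clip(out, 0.0, 1.0), source_id="hog:dominant")
    # glyph rendering: one oriented line per bin per cell, weighted by its vote
    sy, sx = oh / cy, ow / cx
    out = np.zeros((oh, ow), dtype=np.float64)
    half = min(sy, sx) / 2.0 - 0.5
    centers = (np.arange(nb) + 0.5) * d.config.angle_range / nb
    rad = np.radians(centers)
    for iy in range(cy):
        for ix in range(cx):
            votes = d.cell_histograms[iy, ix]
            if not votes.any():
                continue
            c_r = (iy + 0.5) * sy
            c_c = (ix + 0.5) * sx
            for b in range(nb):
                if votes[b] == 0:
                    continue
                dr = -np.sin(rad[b]) * half
                dc = np.cos(rad[b]) * half
                rr, cc = _draw_line(
                    int(round(c_r - dr)), int(round(c_c - dc)),
                    int(round(c_r + dr)), int(round(c_c + dc)),
                )
                ok = (rr >= 0) & (rr < oh) & (cc >= 0) & (cc < ow)
                out[rr[ok], cc[ok]] += votes[b]
    return GrayImage(np.clip(_minmax(out), 0.0, 1.0), source_id="hog:glyph")


def hog_feature_image(img: GrayImage, cfg: HogConfig | None = None) -> GrayImage:
    """Full HOG pipeline: gradients → cell histograms → rendered image
    at the input's extent."""
    cfg = cfg or HogConfig()
    d = cell_histograms(gradients(img, cfg), cfg)
    return render_hog_image(d, (img.height, img.width))
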