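"""Local binary pattern (LBP) texture images.

Each pixel is compared against its P neighbors; the sign bits
s(q_p - q_c) (with ties counting as 1) weighted by 2^i form the LBP
code.  Six variants are supported:

``default``
    raw P-bit code, grid 3x3 neighborhood at R=1, P=8.
``ror``
    rotation-invariant code: minimum over all circular bit rotations.
``uniform``
    rotation-invariant uniform relabeling: codes with at most two 0<->1
    transitions map to their popcount (0..P), all others to P+1.
``nri_uniform``
    non-rotation-invariant uniform relabeling: each of the 58 uniform
    patterns (P=8) keeps its own label 0..57, non-uniform patterns map
    to 58.
``var``
    the binary code is replaced by the population variance of the P
    neighbor intensities (a contrast measure; the operating point that
    performs best for radiograph texture).
``circular``
    raw code from P points sampled on a circle of radius R with
    bilinear interpolation, no post-mapping.

Bit order is fixed throughout the package: neighbor 0 is the east
neighbor and enumeration proceeds counter-clockwise; bit i carries
weight 2^i.  The rendered feature image divides integer codes by the
largest possible code; the unbounded ``var`` map is min-max normalized
per image.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .preprocess import GrayImage

__all__ = ["LbpConfig", "LbpCodeMap", "lbp_code_at", "lbp_map", "render_lbp_image"]

LBP_VARIANTS = ("default", "ror", "uniform", "nri_uniform", "var", "circular")

# east-first, counter-clockwise (row axis points down): (drow, dcol) per bit
GRID_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class LbpConfig:
    """Resolved LBP parameterization.

    The grid variants (everything except ``circular``) use the exact
    3x3 neighborhood and therefore require ``radius_R=1`` and
    ``neighbors_P=8``; ``circular`` samples ``neighbors_P`` points at
    ``radius_R`` with bilinear interpolation.
    ``border_mode="replicate"`` pads so the code map has the extent of
    the input; ``"valid"`` keeps only pixels whose neighborhood lies
    fully inside.
    """

    variant: str = "var"
    neighbors_P: int = 8
    radius_R: float = 1.0
    border_mode: str = "replicate"

    def __post_init__(self) -> None:
        if self.variant not in LBP_VARIANTS:
            raise ValueError(f"variant must be one of {LBP_VARIANTS}, got {self.variant!r}")
        if self.neighbors_P < 2:
            raise ValueError("neighbors_P must be >= 2")
        if self.radius_R <= 0:
            raise ValueError("radius_R must be positive")
        if self.border_mode not in ("replicate", "valid"):
            raise ValueError("border_mode must be 'replicate' or 'valid'")
        if self.variant != "circular" and (self.neighbors_P != 8 or self.radius_R != 1):
            raise ValueError(
                f"variant {self.variant!r} uses the fixed 3x3 grid and requires "
                f"neighbors_P=8, radius_R=1 (got P={self.neighbors_P}, R={self.radius_R})"
            )

    @property
    def max_code(self) -> float:
        """Largest possible code (used by the renderer; nan for var)."""
        p = self.neighbors_P
        if self.variant in ("default", "ror", "circular"):
            return float(2**p - 1)
        if self.variant == "uniform":
            return float(p + 1)
        if self.variant == "nri_uniform":
            return float(p * (p - 1) + 2)  # 58 for P=8
        return float("nan")


@dataclass(frozen=True)
class LbpCodeMap:
    """Per-pixel LBP codes (integer, or nonnegative real for var)."""

    codes: np.ndarray
    variant: str
    config: LbpConfig

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.size == 0:
            raise ValueError(f"codes must be a non-empty 2-D array, got shape {codes.shape}")
        object.__setattr__(self, "codes", codes)


@lru_cache(maxsize=None)
def _nri_uniform_table(p: int) -> np.ndarray:
    """Label table: raw code -> nri_uniform label (uniform codes in numeric
    order get 0..57; non-uniform codes get the shared last label)."""
    n = 2**p
    codes = np.arange(n, dtype=np.int64)
    rot1 = ((codes >> 1) | (codes << (p - 1))) & (n - 1)
    transitions = np.array([bin(int(c)).count("1") for c in (codes ^ rot1)])
    uniform = transitions <= 2
    table = np.full(n, uniform.sum(), dtype=np.int64)
    table[uniform] = np.arange(uniform.sum())
    return table


def _neighbor_stack_grid(padded: np.ndarray, h: int, w: int) -> np.ndarray:
    """(P, h, w) stack of the 8 grid neighbors of each pixel."""
    stack = np.empty((8, h, w), dtype=padded.dtype)
    for i, (dr, dc) in enumerate(GRID_OFFSETS):
        stack[i] = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    return stack


def _neighbor_stack_circular(img: np.ndarray, p: int, r: float) -> np.ndarray:
    """(P, h, w) stack of bilinearly interpolated circular samples.

    Sample i sits at angle 2*pi*i/p measured counter-clockwise from east
    (column +, row - conventions of an image grid)."""
    h, w = img.shape
    pad = int(np.ceil(r)) + 1  # +1 so the bilinear upper corner stays in range
    padded = np.pad(img, pad, mode="edge")
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    out = np.empty((p, h, w), dtype=np.float64)
    for i in range(p):
        theta = 2.0 * np.pi * i / p
        # snap to 1e-6 so cardinal samples land exactly on grid points
        # (cos(pi/2) is ~6e-17, which would otherwise break exact ties)
        rr = rows + pad - np.round(r * np.sin(theta), 6)
        cc = cols + pad + np.round(r * np.cos(theta), 6)
        r0 = np.floor(rr).astype(np.int64)
        c0 = np.floor(cc).astype(np.int64)
        fr = rr - r0
        fc = cc - c0
        # rounding the sample kills last-ulp interpolation noise, so an
        # exact tie with the center stays a tie (>= semantics)
        out[i] = np.round(
            padded[r0, c0] * (1 - fr) * (1 - fc)
            + padded[r0, c0 + 1] * (1 - fr) * fc
            + padded[r0 + 1, c0] * fr * (1 - fc)
            + padded[r0 + 1, c0 + 1] * fr * fc,
            10,
        )
    return out


def _codes_from_stack(neighbors: np.ndarray, center: np.ndarray, cfg: LbpConfig) -> np.ndarray:
    p = neighbors.shape[0]
    if cfg.variant == "var":
        return neighbors.var(axis=0)  # population variance over the P samples
    bits = neighbors >= center  # ties count as 1
    weights = (1 << np.arange(p, dtype=np.int64))[:, None, None]
    code = (bits * weights).sum(axis=0)
    if cfg.variant in ("default", "circular"):
        return code
    if cfg.variant == "ror":
        mask = 2**p - 1
        best = code.copy()
        for r in range(1, p):
            np.minimum(best, ((code >> r) | (code << (p - r))) & mask, out=best)
        return best
    ones = bits.sum(axis=0)
    transitions = (bits != np.roll(bits, -1, axis=0)).sum(axis=0)
    if cfg.variant == "uniform":
        return np.where(transitions <= 2, ones, p + 1).astype(np.int64)
    # nri_uniform
    return _nri_uniform_table(p)[code]


def lbp_code_at(patch: np.ndarray, cfg: LbpConfig) -> float:
    """Code of the center pixel of a single 3x3 patch (grid variants)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (3, 3):
        raise ValueError(f"patch must be 3x3, got {patch.shape}")
    if cfg.variant == "circular":
        raise ValueError("lbp_code_at is defined for the 3x3 grid variants only")
    neighbors = np.array([[[patch[1 + dr, 1 + dc]]] for dr, dc in GRID_OFFSETS])
    code = _codes_from_stack(neighbors, patch[1:2, 1:2], cfg)
    return float(code[0, 0])


def lbp_map(img: GrayImage, cfg: LbpConfig) -> LbpCodeMap:
    """Apply the LBP operator at every pixel.

    With ``border_mode="replicate"`` the image is edge-padded so the
    code map matches the input extent; ``"valid"`` shrinks the map to
    pixels whose full neighborhood is inside the image.
    """
    px = img.pixels
    need = int(2 * np.ceil(cfg.radius_R) + 1)
    if px.shape[0] < need or px.shape[1] < need:
        raise ValueError(f"image {px.shape} smaller than the {need}x{need} neighborhood")
    if cfg.variant == "circular":
        if cfg.border_mode == "valid":
            pad = int(np.ceil(cfg.radius_R))
            core = px[pad:-pad, pad:-pad] if pad else px
            neighbors = _neighbor_stack_circular(px, cfg.neighbors_P, cfg.radius_R)
            neighbors = neighbors[:, pad : pad + core.shape[0], pad : pad + core.shape[1]]
            center = np.round(core, 10)
        else:
            neighbors = _neighbor_stack_circular(px, cfg.neighbors_P, cfg.radius_R)
            center = np.round(px, 10)
    else:
        if cfg.border_mode == "valid":
            padded = px
            center = px[1:-1, 1:-1]
        else:
            padded = np.pad(px, 1, mode="edge")
            center = px
        neighbors = _neighbor_stack_grid(padded, center.shape[0], center.shape[1])
    codes = _codes_from_stack(neighbors, center, cfg)
    return LbpCodeMap(codes=codes, variant=cfg.variant, config=cfg)


def render_lbp_image(code_map: LbpCodeMap) -> GrayImage:
    """Render codes as a [0, 1] grayscale feature image.

    Integer variants divide by the largest possible code; the unbounded
    ``var`` map is min-max normalized per image (constant -> zeros).
    """
    codes = code_map.codes.astype(np.float64)
    if code_map.variant == "var":
        lo, hi = codes.min(), codes.max()
        out = np.zeros_like(codes) if hi == lo else (codes - lo) / (hi - lo)
    else:
        out = codes / code_map.config.max_code
    return GrayImage(out, source_id=f"lbp:{code_map.variant}")
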