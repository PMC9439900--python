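"""Synthetic two-class radiograph-like image generator.

Both classes share a smooth thorax-like background (Gaussian-filtered
white noise plus a vertical brightness gradient) and optional
low-amplitude horizontal sinusoidal bands that stand in for rib
shadows.  The "pneumonia" class additionally receives a few blurred
blob opacities — a localized intensity increase carrying fine-grained
texture noise — placed inside a central elliptical lung-field mask.
The class signal is therefore carried by local second-order texture
statistics (exactly what LBP and HOG respond to), not by any global
intensity cue alone, and setting both the blob intensity delta and the
texture noise to zero makes the two classes distributionally
identical (a null dataset for leakage checks).

The generator writes the same ``<root>/<class>/<name>.png`` layout the
preprocessing module reads, is bit-deterministic under a fixed seed,
and also offers an in-memory path (:func:`generate_arrays`) so tests
and experiments can skip the filesystem.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage as _ndi

from .preprocess import GrayImage
from .texture_hog import HogConfig, cell_histograms, gradients
from .texture_lbp import LbpConfig, lbp_map

__all__ = [
    "SyntheticSpec",
    "generate_arrays",
    "generate_dataset",
    "texture_separation_check",
]

CLASS_NAMES = ("normal", "pneumonia")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one two-class dataset.

    Defaults are the desk-scale operating point: 64x64 images whose
    pneumonia class carries 2-4 blob opacities of radius 4-9 px with an
    intensity delta of 0.25 and texture noise sigma 0.12 — strong
    enough that texture statistics separate the classes, weak enough
    that single-pixel intensity does not trivially do so.
    """

    n_per_class: int = 100
    image_size: Tuple[int, int] = (64, 64)
    background_amplitude: float = 0.15
    background_corr_length: float = 6.0
    gradient_strength: float = 0.25
    lesion_count_range: Tuple[int, int] = (2, 4)
    lesion_radius_range: Tuple[float, float] = (4.0, 9.0)
    lesion_intensity_delta: float = 0.25
    lesion_texture_sigma: float = 0.12
    rib_amplitude: float = 0.05
    rib_spacing: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size components must be >= 8")
        if self.lesion_count_range[0] > self.lesion_count_range[1]:
            raise ValueError("lesion_count_range must be (lo, hi) with lo <= hi")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (lo, hi) with lo <= hi")


def _background(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    h, w = spec.image_size
    noise = rng.standard_normal((h, w))
    smooth = _ndi.gaussian_filter(noise, spec.background_corr_length)
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    rows = np.linspace(0.0, 1.0, h)[:, None]
    img = 0.45 + spec.background_amplitude * smooth + spec.gradient_strength * (rows - 0.5)
    if spec.rib_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        img = img + spec.rib_amplitude * np.sin(
            2 * np.pi * np.arange(h)[:, None] / spec.rib_spacing + phase
        )
    return img


def _lung_mask(h: int, w: int) -> np.ndarray:
    rr = (np.arange(h)[:, None] - (h - 1) / 2) / (0.38 * h)
    cc = (np.arange(w)[None, :] - (w - 1) / 2) / (0.38 * w)
    return rr**2 + cc**2 <= 1.0


def _add_lesions(img: np.ndarray, rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    h, w = img.shape
    mask = _lung_mask(h, w)
    centers = np.argwhere(mask)
    n = rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    out = img.copy()
    for _ in range(int(n)):
        cy, cx = centers[rng.integers(len(centers))]
        radius = rng.uniform(*spec.lesion_radius_range)
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        blob = np.exp(-d2 / (2.0 * (radius / 2.0) ** 2))
        support = blob > 0.05
        out = out + spec.lesion_intensity_delta * blob
        if spec.lesion_texture_sigma > 0:
            speckle = rng.standard_normal((h, w)) * spec.lesion_texture_sigma
            out = out + np.where(support, speckle * blob, 0.0)
    return out


def generate_arrays(spec: SyntheticSpec) -> Tuple[List[np.ndarray], List[int], List[str]]:
    """Generate the dataset in memory.

    Returns (images, labels, names); label 0 = normal, 1 = pneumonia;
    intensities are clipped to [0, 1] and quantized to 8 bits so the
    in-memory path matches the PNG round trip exactly.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    images: List[np.ndarray] = []
    labels: List[int] = []
    names: List[str] = []
    for label, cls in enumerate(CLASS_NAMES):
        for i in range(spec.n_per_class):
            img = _background(rng, spec)
            if cls == "pneumonia":
                img = _add_lesions(img, rng, spec)
            img = np.clip(img, 0.0, 1.0)
            img8 = np.round(img * 255.0).astype(np.uint8)
            images.append(img8.astype(np.float64) / 255.0)
            labels.append(label)
            names.append(f"{cls}_{i:04d}.png")
    return images, labels, names


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write PNGs under ``out_dir/<class>/`` plus a ``manifest.csv``.

    Returns the manifest path.  Bit-deterministic for a fixed spec.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        for cls in CLASS_NAMES:
            (out_dir / cls).mkdir(exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    images, labels, names = generate_arrays(spec)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["filename", "class", "n_per_class", "image_h", "image_w",
             "lesion_intensity_delta", "lesion_texture_sigma", "seed"]
        )
        for img, label, name in zip(images, labels, names):
            cls = CLASS_NAMES[label]
            arr = np.round(np.asarray(img) * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out_dir / cls / name)
            writer.writerow(
                [f"{cls}/{name}", cls, spec.n_per_class, spec.image_size[0],
                 spec.image_size[1], spec.lesion_intensity_delta,
                 spec.lesion_texture_sigma, spec.seed]
            )
    return manifest


# ---------------------------------------------------------------------------
# texture separation diagnostic
# ---------------------------------------------------------------------------

def _texture_features(images: List[np.ndarray], lbp_cfg: LbpConfig, hog_cfg: HogConfig
                      ) -> np.ndarray:
    """Per-image feature vector: normalized LBP code histogram + mean HOG energy."""
    feats = []
    for px in images:
        img = GrayImage(np.asarray(px, dtype=np.float64))
        codes = lbp_map(img, lbp_cfg).codes
        if lbp_cfg.variant == "var":
            hist, _ = np.histogram(codes, bins=16, range=(0.0, max(codes.max(), 1e-12)))
        else:
            nmax = int(lbp_cfg.max_code)
            hist = np.bincount(codes.ravel().astype(np.int64), minlength=nmax + 1)
        hist = hist / max(hist.sum(), 1)
        hog_energy = cell_histograms(gradients(img, hog_cfg), hog_cfg).cell_histograms.mean()
        feats.append(np.concatenate([hist, [hog_energy]]))
    return np.asarray(feats)


def texture_separation_check(
    data: str | Path | Tuple[List[np.ndarray], List[int]],
    lbp_cfg: LbpConfig | None = None,
    hog_cfg: HogConfig | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> Dict[str, float]:
    """Quantify how far apart the two classes' texture statistics sit.

    ``data`` is either a dataset directory written by
    :func:`generate_dataset` or an in-memory ``(images, labels)`` pair.
    The separation score is the Euclidean distance between class-mean
    feature vectors (LBP code histogram + mean HOG cell energy); its
    significance is assessed by label permutation (p-value with the
    standard +1 correction).
    """
    lbp_cfg = lbp_cfg or LbpConfig()
    hog_cfg = hog_cfg or HogConfig()
    if isinstance(data, (str, Path)):
        root = Path(data)
        images, labels = [], []
        for label, cls in enumerate(CLASS_NAMES):
            for f in sorted((root / cls).glob("*.png")):
                with Image.open(f) as im:
                    images.append(np.asarray(im.convert("L"), dtype=np.float64) / 255.0)
                labels.append(label)
    else:
        images, labels = list(data[0]), list(data[1])
    labels_arr = np.asarray(labels)
    if len(np.unique(labels_arr)) < 2:
        raise ValueError("texture_separation_check needs samples from both classes")

    feats = _texture_features(images, lbp_cfg, hog_cfg)
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    feats = feats / scale

    def score(lab: np.ndarray) -> float:
        mu0 = feats[lab == 0].mean(axis=0)
        mu1 = feats[lab == 1].mean(axis=0)
        return float(np.linalg.norm(mu1 - mu0))

    observed = score(labels_arr)
    rng = np.random.Generator(np.random.PCG64(seed))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels_arr)
        if score(perm) >= observed:
            exceed += 1
    pvalue = (exceed + 1) / (n_permutations + 1)
    return {"score": observed, "pvalue": float(pvalue), "n_permutations": n_permutations}
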