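"""Independent reference implementations used only by the tests.

Everything here is written as plain per-pixel Python loops (or simple
symbolic bookkeeping), deliberately sharing no code with the vectorized
package implementations it checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

# east-first, counter-clockwise enumeration; bit i weighs 2**i
NEIGHBOR_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def _pad_replicate(px) -> List[List[float]]:
    h = len(px)
    w = len(px[0])
    out = []
    for r in range(-1, h + 1):
        rr = min(max(r, 0), h - 1)
        out.append([float(px[rr][min(max(c, 0), w - 1)]) for c in range(-1, w + 1)])
    return out


def _uniform_label_table(p: int = 8) -> Dict[int, int]:
    """code -> nri_uniform label, uniform codes in numeric order."""
    table = {}
    next_label = 0
    nonuniform = []
    for code in range(2**p):
        bits = [(code >> i) & 1 for i in range(p)]
        transitions = sum(bits[i] != bits[(i + 1) % p] for i in range(p))
        if transitions <= 2:
            table[code] = next_label
            next_label += 1
        else:
            nonuniform.append(code)
    for code in nonuniform:
        table[code] = next_label
    return table


_NRI_TABLE = _uniform_label_table(8)


def lbp_reference(pixels, variant: str) -> List[List[float]]:
    """Per-pixel double-loop LBP with replicate border, 3x3 grid, P=8."""
    h = len(pixels)
    w = len(pixels[0])
    padded = _pad_replicate(pixels)
    out = [[0.0] * w for _ in range(h)]
    for r in range(h):
        for c in range(w):
            center = float(pixels[r][c])
            neigh = [padded[r + 1 + dr][c + 1 + dc] for dr, dc in NEIGHBOR_OFFSETS]
            if variant == "var":
                mean = sum(neigh) / 8.0
                out[r][c] = sum((v - mean) ** 2 for v in neigh) / 8.0
                continue
            bits = [1 if v >= center else 0 for v in neigh]
            code = sum(b << i for i, b in enumerate(bits))
            if variant == "default":
                out[r][c] = code
            elif variant == "ror":
                best = code
                for rot in range(1, 8):
                    rotated = bits[rot:] + bits[:rot]
                    best = min(best, sum(b << i for i, b in enumerate(rotated)))
                out[r][c] = best
            elif variant == "uniform":
                transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
                out[r][c] = sum(bits) if transitions <= 2 else 9
            elif variant == "nri_uniform":
                out[r][c] = _NRI_TABLE[code]
            else:
                raise ValueError(variant)
    return out


def circular_lbp_reference(pixels, p: int, radius: float) -> List[List[float]]:
    """Loop version of the interpolated circular sampler (raw codes)."""
    h = len(pixels)
    w = len(pixels[0])

    def sample(rr: float, cc: float) -> float:
        r0 = math.floor(rr)
        c0 = math.floor(cc)
        fr = rr - r0
        fc = cc - c0

        def at(r, c):
            return float(pixels[min(max(r, 0), h - 1)][min(max(c, 0), w - 1)])

        # same 10-decimal sample rounding convention as the implementation
        return round(
            at(r0, c0) * (1 - fr) * (1 - fc)
            + at(r0, c0 + 1) * (1 - fr) * fc
            + at(r0 + 1, c0) * fr * (1 - fc)
            + at(r0 + 1, c0 + 1) * fr * fc,
            10,
        )

    out = [[0.0] * w for _ in range(h)]
    for r in range(h):
        for c in range(w):
            code = 0
            for i in range(p):
                theta = 2.0 * math.pi * i / p
                # same coordinate-snapping convention as the implementation
                dr = round(radius * math.sin(theta), 6)
                dc = round(radius * math.cos(theta), 6)
                v = sample(r - dr, c + dc)
                if v >= round(float(pixels[r][c]), 10):
                    code += 1 << i
            out[r][c] = code
    return out


def hog_reference(pixels, cell_size: int, n_bins: int, signed: bool = False,
                  as_printed: bool = False):
    """Per-pixel gradient + voting loop: returns (fx, fy, mag, hist).

    hist is a dict (cell_row, cell_col) -> list of n_bins votes."""
    h = len(pixels)
    w = len(pixels[0])
    padded = _pad_replicate(pixels)
    angle_range = 360.0 if signed else 180.0
    bin_width = angle_range / n_bins
    fx = [[0.0] * w for _ in range(h)]
    fy = [[0.0] * w for _ in range(h)]
    mag = [[0.0] * w for _ in range(h)]
    hist: Dict[Tuple[int, int], List[float]] = {}
    cy, cx = h // cell_size, w // cell_size
    for r in range(cy):
        for c in range(cx):
            hist[(r, c)] = [0.0] * n_bins
    for r in range(h):
        for c in range(w):
            gx = padded[r + 1][c + 2] - padded[r + 1][c]
            gy = padded[r + 2][c + 1] - padded[r][c + 1]
            fx[r][c] = gx
            fy[r][c] = gy
            m = math.hypot(gx, gy)
            mag[r][c] = m
            cr, cc = r // cell_size, c // cell_size
            if cr >= cy or cc >= cx or m == 0.0:
                continue
            if as_printed:
                ang = math.degrees(math.atan2(gx, gy)) % angle_range
            else:
                ang = math.degrees(math.atan2(gy, gx)) % angle_range
            f = ang / bin_width - 0.5
            b0 = math.floor(f)
            frac = f - b0
            hist[(cr, cc)][b0 % n_bins] += m * (1.0 - frac)
            hist[(cr, cc)][(b0 + 1) % n_bins] += m * frac
    return fx, fy, mag, hist


def metrics_reference(pred: Sequence, truth: Sequence, averaging: str = "weighted"):
    """Brute-force counting of accuracy / precision / recall / F1."""
    n = len(truth)
    classes = sorted(set(list(truth) + list(pred)), key=str)
    acc = sum(1 for p, t in zip(pred, truth) if p == t) / n
    rows = []
    for c in classes:
        tp = fp = fn = 0
        for p, t in zip(pred, truth):
            if p == c and t == c:
                tp += 1
            elif p == c:
                fp += 1
            elif t == c:
                fn += 1
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append((tp + fn, prec, rec, f1))
    if averaging == "weighted":
        total = sum(r[0] for r in rows)
        weights = [r[0] / total for r in rows]
    else:
        weights = [1.0 / len(rows)] * len(rows)
    prec = sum(w * r[1] for w, r in zip(weights, rows))
    rec = sum(w * r[2] for w, r in zip(weights, rows))
    f1 = sum(w * r[3] for w, r in zip(weights, rows))
    return acc, prec, rec, f1


def vgg_shape_propagation(input_hw: Tuple[int, int], widths: Sequence[int],
                          depths: Sequence[int]) -> Dict[str, Tuple[int, int, int]]:
    """Symbolic shape walk through the conv stages; records the tensor
    shape right after the last conv of each stage (pre-pool)."""
    h, w = input_hw
    shapes = {}
    for k, (width, depth) in enumerate(zip(widths, depths), start=1):
        # `depth` 3x3 same-convs leave spatial size unchanged, set channels
        shapes[f"block{k}"] = (width, h, w)
        h, w = h // 2, w // 2  # the stage's 2x2 max-pool
    return shapes
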