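"""Two-branch texture/depth fusion network (FC-VGG style), in pure numpy.

The backbone is a modified VGG-16: five conv stages of 2,2,3,3,3
3x3 convolutions with widths 64,128,256,512,512 (each stage closed by
a 2x2 max-pool), followed by a reduced head of two hidden fully
connected layers with dropout and a 2-unit output.  A texture branch
with the same stage layout (fed by the stacked LBP/HOG feature images)
joins the backbone by element-wise Add fusion at a configurable
position: at the input, or after the last convolution of one of the
five blocks, before that block's max-pool.  The fusion is

    Z_add[i] = (X[i] + Y[i]) * K[i]        per channel i,

with learnable per-channel 1x1 kernels K initialized to identity, so
training starts from a plain sum and the tensor shape is unchanged.

Forward and backward passes are hand-written (there is no autodiff
framework underneath); convolutions are evaluated as nine shifted
GEMMs, which keeps a CPU-only training loop fast at the scaled-down
widths used for experiments.  ``width_multiplier`` scales every conv
width and the FC width; 1.0 with 224x224 input reproduces the full
architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage as _ndi

__all__ = [
    "FusionNetSpec",
    "FusionInput",
    "FusionNet",
    "add_fuse",
    "build_network",
    "fusion_position_shapes",
    "summarize",
]

FUSION_POSITIONS = ("input", "block1", "block2", "block3", "block4", "block5")
STAGE_WIDTHS = (64, 128, 256, 512, 512)
STAGE_DEPTHS = (2, 2, 3, 3, 3)
FC_WIDTH = 4096
TEXTURE_MODES = ("stacked", "separate_branches")


@dataclass(frozen=True)
class FusionNetSpec:
    """Declarative description of the fused network."""

    fusion_position: str = "block3"
    width_multiplier: float = 1.0
    dropout_rate: float = 0.5
    texture_mode: str = "stacked"
    share_weights: bool = False
    input_size: Tuple[int, int] = (224, 224)
    depth_channels: int = 1
    texture_channels: int = 2
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.fusion_position not in FUSION_POSITIONS:
            raise ValueError(f"fusion_position must be one of {FUSION_POSITIONS}")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must lie in (0, 1]")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.texture_mode not in TEXTURE_MODES:
            raise ValueError(f"texture_mode must be one of {TEXTURE_MODES}")
        h, w = self.input_size
        if h % 32 or w % 32 or h < 32 or w < 32:
            raise ValueError(
                f"input_size must be a positive multiple of 32 (five 2x pools), got {self.input_size}"
            )
        if self.share_weights and self.texture_channels != self.depth_channels:
            raise ValueError(
                "share_weights requires texture_channels == depth_channels "
                "(the shared first conv fixes the input channel count)"
            )

    @property
    def stage_widths(self) -> Tuple[int, ...]:
        return tuple(max(1, round(w * self.width_multiplier)) for w in STAGE_WIDTHS)

    @property
    def fc_width(self) -> int:
        return max(4, round(FC_WIDTH * self.width_multiplier))

    @property
    def fusion_block(self) -> int:
        """0 for input fusion, else 1..5."""
        return 0 if self.fusion_position == "input" else int(self.fusion_position[-1])


@dataclass(frozen=True)
class FusionInput:
    """A preprocessed radiograph plus its stacked texture feature images."""

    depth_image: np.ndarray    # (H, W) or (C_d, H, W)
    texture_image: np.ndarray  # (C_t, H, W)

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_image, dtype=np.float32)
        if d.ndim == 2:
            d = d[None]
        t = np.asarray(self.texture_image, dtype=np.float32)
        if t.ndim == 2:
            t = t[None]
        if d.shape[1:] != t.shape[1:]:
            raise ValueError(
                f"depth {d.shape[1:]} and texture {t.shape[1:]} spatial extents differ"
            )
        object.__setattr__(self, "depth_image", d)
        object.__setattr__(self, "texture_image", t)


# ---------------------------------------------------------------------------
# standalone Add fusion (the fusion primitive, independent of the network)
# ---------------------------------------------------------------------------

def add_fuse(x: np.ndarray, y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Per-channel Add fusion: output_i = (X_i + Y_i) filtered by K_i.

    ``x`` and ``y`` are (C, H, W) or (N, C, H, W) activation tensors of
    identical shape; ``k`` is (C,) (per-channel 1x1 scale) or
    (C, kh, kw) odd-sized kernels applied with zero padding
    (cross-correlation convention).  Identity kernels make the result
    the exact element-wise sum.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"add_fuse shape mismatch: x {x.shape} vs y {y.shape}")
    if x.ndim == 3:
        return add_fuse(x[None], y[None], k)[0]
    if x.ndim != 4:
        raise ValueError(f"expected (N, C, H, W) or (C, H, W), got {x.shape}")
    k = np.asarray(k, dtype=np.float64)
    c = x.shape[1]
    s = x + y
    if k.ndim == 1:
        if k.shape[0] != c:
            raise ValueError(f"need one kernel per channel: {k.shape[0]} kernels, {c} channels")
        return s * k[None, :, None, None]
    if k.ndim != 3 or k.shape[0] != c:
        raise ValueError(f"k must be (C,) or (C, kh, kw) with C={c}, got {k.shape}")
    out = np.empty_like(s)
    for i in range(c):
        for n in range(s.shape[0]):
            out[n, i] = _ndi.correlate(s[n, i], k[i], mode="constant", cval=0.0)
    return out


# ---------------------------------------------------------------------------
# layer primitives: forward returns (out, backward-closure)
# ---------------------------------------------------------------------------

Backward = Callable[[np.ndarray, Dict[str, np.ndarray]], np.ndarray]


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray, name: str):
    """3x3 'same' convolution (zero pad 1) as nine shifted GEMMs."""
    n, cin, h, wd = x.shape
    cout = w.shape[0]
    xp = np.zeros((n, cin, h + 2, wd + 2), dtype=np.float32)
    xp[:, :, 1:-1, 1:-1] = x
    out = np.zeros((n, cout, h * wd), dtype=np.float32)
    views = []
    for i in range(3):
        for j in range(3):
            xs = xp[:, :, i : i + h, j : j + wd].reshape(n, cin, h * wd)
            views.append(xs)
            out += np.matmul(w[:, :, i, j], xs)
    out = out.reshape(n, cout, h, wd) + b[None, :, None, None]

    def backward(dout: np.ndarray, grads: Dict[str, np.ndarray]) -> np.ndarray:
        df = dout.reshape(n, cout, h * wd)
        grads[name + "_b"] += dout.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        dw = grads[name + "_W"]
        for idx in range(9):
            i, j = divmod(idx, 3)
            xs = views[idx]
            dw[:, :, i, j] += np.einsum("ncp,nkp->ck", df, xs, optimize=True)
            dxp[:, :, i : i + h, j : j + wd] += np.matmul(
                w[:, :, i, j].T, df
            ).reshape(n, cin, h, wd)
        return dxp[:, :, 1:-1, 1:-1]

    return out, backward


def _relu(x: np.ndarray):
    out = np.maximum(x, 0.0)
    mask = x > 0

    def backward(dout, grads):
        return dout * mask

    return out, backward


def _maxpool2(x: np.ndarray):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : 2 * h2, : 2 * w2]
    r = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    arg = r.argmax(axis=4)
    out = np.take_along_axis(r, arg[..., None], axis=4)[..., 0]

    def backward(dout, grads):
        dr = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(dr, arg[..., None], dout[..., None].astype(np.float32), axis=4)
        dxc = dr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        if dxc.shape == x.shape:
            return dxc
        dx = np.zeros_like(x)
        dx[:, :, : 2 * h2, : 2 * w2] = dxc
        return dx

    return out, backward


def _dense(x: np.ndarray, w: np.ndarray, b: np.ndarray, name: str):
    out = x @ w.T + b

    def backward(dout, grads):
        grads[name + "_W"] += dout.T @ x
        grads[name + "_b"] += dout.sum(axis=0)
        return dout @ w

    return out, backward


def _dropout(x: np.ndarray, rate: float, rng: np.random.Generator | None, train: bool):
    if not train or rate == 0.0 or rng is None:
        return x, (lambda dout, grads: dout)
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(np.float32) / keep

    def backward(dout, grads):
        return dout * mask

    return x * mask, backward


def _fuse_scale(x: np.ndarray, terms: List[np.ndarray], k: np.ndarray, name: str,
                term_backwards: List[List[Backward]]):
    """z = (x + sum(terms)) * k, k per-channel, backprop into every term's tape."""
    s = x + sum(terms)
    out = s * k[None, :, None, None]

    def backward(dout, grads):
        grads[name] += (s * dout).sum(axis=(0, 2, 3))
        ds = dout * k[None, :, None, None]
        for tape in term_backwards:
            d = ds
            for bw in reversed(tape):
                d = bw(d, grads)
        return ds

    return out, backward


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class FusionNet:
    """Trainable fused classifier built from a :class:`FusionNetSpec`.

    Parameters live in ``self.params`` (name -> float32 array);
    :meth:`loss_and_grads` returns the mean cross-entropy and a grads
    dict of the same keys.  All randomness (init, dropout) flows
    through explicit numpy generators, so runs are reproducible.
    """

    def __init__(self, spec: FusionNetSpec, seed: int = 0):
        self.spec = spec
        self.params: Dict[str, np.ndarray] = {}
        rng = np.random.Generator(np.random.PCG64(seed))
        widths = spec.stage_widths

        def he_conv(name, cin, cout):
            bound = np.sqrt(6.0 / (cin * 9))
            self.params[name + "_W"] = rng.uniform(-bound, bound, (cout, cin, 3, 3)).astype(np.float32)
            self.params[name + "_b"] = np.zeros(cout, dtype=np.float32)

        def he_dense(name, din, dout):
            bound = np.sqrt(6.0 / din)
            self.params[name + "_W"] = rng.uniform(-bound, bound, (dout, din)).astype(np.float32)
            self.params[name + "_b"] = np.zeros(dout, dtype=np.float32)

        fb = spec.fusion_block
        in_ch = spec.texture_channels if fb == 0 else spec.depth_channels
        cin = in_ch
        for s, (wd, depth) in enumerate(zip(widths, STAGE_DEPTHS), start=1):
            for l in range(depth):
                he_conv(f"bb{s}_c{l}", cin, wd)
                cin = wd
        # texture branch mirrors stages 1..fb (absent for input fusion)
        if fb > 0 and not spec.share_weights:
            n_branches = spec.texture_channels if spec.texture_mode == "separate_branches" else 1
            br_in = 1 if spec.texture_mode == "separate_branches" else spec.texture_channels
            for br in range(n_branches):
                cin_t = br_in
                for s in range(1, fb + 1):
                    for l in range(STAGE_DEPTHS[s - 1]):
                        he_conv(f"tx{br}_{s}_c{l}", cin_t, widths[s - 1])
                        cin_t = widths[s - 1]
        fuse_ch = spec.texture_channels if fb == 0 else widths[fb - 1]
        self.params["fuse_k"] = np.ones(fuse_ch, dtype=np.float32)  # identity: start from plain add

        h, w = spec.input_size
        self.flat_dim = widths[-1] * (h // 32) * (w // 32)
        he_dense("fc1", self.flat_dim, spec.fc_width)
        he_dense("fc2", spec.fc_width, spec.fc_width)
        he_dense("out", spec.fc_width, spec.n_classes)

    # -- forward ------------------------------------------------------------

    def _texture_tapes(self, texture: np.ndarray, use_fusion_kernel_only: bool):
        """Run the texture branch(es) up to the fusion point.

        Returns (list of branch outputs, list of per-branch backward tapes)."""
        spec = self.spec
        fb = spec.fusion_block
        outs, tapes = [], []
        if spec.texture_mode == "separate_branches" and not spec.share_weights:
            branch_inputs = [texture[:, i : i + 1] for i in range(texture.shape[1])]
        else:
            branch_inputs = [texture]
        for br, t in enumerate(branch_inputs):
            tape: List[Backward] = []
            x = t
            prefix = "bb" if spec.share_weights else f"tx{br}_"
            for s in range(1, fb + 1):
                for l in range(STAGE_DEPTHS[s - 1]):
                    name = f"bb{s}_c{l}" if spec.share_weights else f"tx{br}_{s}_c{l}"
                    x, bw = _conv3x3(x, self.params[name + "_W"], self.params[name + "_b"], name)
                    tape.append(bw)
                    x, bw = _relu(x)
                    tape.append(bw)
                if s < fb:
                    x, bw = _maxpool2(x)
                    tape.append(bw)
            outs.append(x)
            tapes.append(tape)
        return outs, tapes

    def forward(self, depth: np.ndarray, texture: np.ndarray | None,
                train: bool = False, rng: np.random.Generator | None = None):
        """Logits for a batch; ``texture=None`` runs the depth-only ablation.

        ``depth``: (N, C_d, H, W); ``texture``: (N, C_t, H, W).
        Returns (logits, backward-tape)."""
        spec = self.spec
        fb = spec.fusion_block
        depth = np.ascontiguousarray(depth, dtype=np.float32)
        if texture is not None:
            texture = np.ascontiguousarray(texture, dtype=np.float32)
        tape: List[Backward] = []
        k = self.params["fuse_k"]

        if fb == 0:
            base = np.broadcast_to(depth, (depth.shape[0], spec.texture_channels) + depth.shape[2:])
            base = np.ascontiguousarray(base)
            terms = [texture] if texture is not None else [np.zeros_like(base)]
            x, bw = _fuse_scale(base, terms, k, "fuse_k", term_backwards=[])
            tape.append(bw)
        else:
            x = depth

        for s in range(1, 6):
            for l in range(STAGE_DEPTHS[s - 1]):
                name = f"bb{s}_c{l}"
                x, bw = _conv3x3(x, self.params[name + "_W"], self.params[name + "_b"], name)
                tape.append(bw)
                x, bw = _relu(x)
                tape.append(bw)
            if s == fb:
                if texture is not None:
                    touts, ttapes = self._texture_tapes(texture, False)
                else:
                    touts, ttapes = [np.zeros_like(x)], [[]]
                x, bw = _fuse_scale(x, touts, k, "fuse_k", term_backwards=ttapes)
                tape.append(bw)
            x, bw = _maxpool2(x)
            tape.append(bw)

        n = x.shape[0]
        flat_shape = x.shape
        x = x.reshape(n, -1)
        tape.append(lambda dout, grads, shp=flat_shape: dout)  # placeholder; reshape handled below

        def unflatten(dout, grads, shp=flat_shape):
            return dout.reshape(shp)

        tape[-1] = unflatten

        x, bw = _dense(x, self.params["fc1_W"], self.params["fc1_b"], "fc1")
        tape.append(bw)
        x, bw = _relu(x)
        tape.append(bw)
        x, bw = _dropout(x, spec.dropout_rate, rng, train)
        tape.append(bw)
        x, bw = _dense(x, self.params["fc2_W"], self.params["fc2_b"], "fc2")
        tape.append(bw)
        x, bw = _relu(x)
        tape.append(bw)
        x, bw = _dropout(x, spec.dropout_rate, rng, train)
        tape.append(bw)
        x, bw = _dense(x, self.params["out_W"], self.params["out_b"], "out")
        tape.append(bw)
        return x, tape

    def predict_logits(self, depth: np.ndarray, texture: np.ndarray | None) -> np.ndarray:
        logits, _ = self.forward(depth, texture, train=False)
        return logits

    def loss_and_grads(self, depth: np.ndarray, texture: np.ndarray | None,
                       labels: np.ndarray, rng: np.random.Generator | None = None):
        """Mean softmax cross-entropy and parameter gradients."""
        logits, tape = self.forward(depth, texture, train=True, rng=rng)
        n = logits.shape[0]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d = dlogits.astype(np.float32)
        for bw in reversed(tape):
            d = bw(d, grads)
        return float(loss), grads

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def build_network(spec: FusionNetSpec, seed: int = 0) -> FusionNet:
    """Instantiate a trainable :class:`FusionNet` from its spec."""
    return FusionNet(spec, seed=seed)


def fusion_position_shapes(spec: FusionNetSpec, input_size: Tuple[int, int] | None = None
                           ) -> Dict[str, Tuple[int, int, int]]:
    """(channels, height, width) at which Add would occur, per position.

    Fusion happens after the last convolution of the named block and
    before its max-pool, so block k sees the input downsampled by the
    k-1 preceding pools.
    """
    h, w = input_size if input_size is not None else spec.input_size
    shapes: Dict[str, Tuple[int, int, int]] = {"input": (spec.texture_channels, h, w)}
    widths = spec.stage_widths
    for k in range(1, 6):
        div = 2 ** (k - 1)
        if h % div or w % div:
            raise ValueError(f"input {h}x{w} not divisible by {div} for block{k}")
        shapes[f"block{k}"] = (widths[k - 1], h // div, w // div)
    return shapes


def summarize(spec: FusionNetSpec, seed: int = 0) -> str:
    """Human-readable layer/shape/parameter table."""
    net = build_network(spec, seed=seed)
    shapes = fusion_position_shapes(spec)
    lines = [
        f"FusionNet  position={spec.fusion_position}  width_multiplier={spec.width_multiplier}",
        f"input {spec.input_size[0]}x{spec.input_size[1]}  "
        f"depth_channels={spec.depth_channels} texture_channels={spec.texture_channels}",
        "",
        f"{'position':<10}{'fuse shape (C,H,W)':<24}",
    ]
    for pos, shp in shapes.items():
        marker = "  <- fusion here" if pos == spec.fusion_position else ""
        lines.append(f"{pos:<10}{str(shp):<24}{marker}")
    lines.append("")
    lines.append(f"{'parameter':<16}{'shape':<20}{'count':>12}")
    for name, arr in net.params.items():
        lines.append(f"{name:<16}{str(arr.shape):<20}{arr.size:>12,}")
    lines.append(f"{'total':<36}{net.n_parameters:>12,}")
    return "\n".join(lines)
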