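"""K-fold experiment harness: data assignment, training, metrics.

The evaluation vocabulary is the standard confusion-matrix suite —
accuracy, precision, recall and F1 per class, combined by
support-weighted (default) or macro averaging.  In a binary task the
support-weighted recall is algebraically identical to the overall
accuracy; that identity is asserted in the tests and is the signature
by which weighted averaging was chosen as the default.

``run_experiment`` wires every stage together: preprocess → texture
feature images → stratified k-fold → train the fused network per fold
→ evaluate the held-out fold, writing a results directory (JSON
metrics, per-sample prediction CSV, resolved config, log).  ``sweep``
repeats an experiment along one axis (LBP variant, HOG cell size or
fusion position) and emits a comparison table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .preprocess import GrayImage, PreprocessConfig, normalize_minmax, resize
from .texture_hog import HogConfig, hog_feature_image
from .texture_lbp import LbpConfig, lbp_map, render_lbp_image
from .fusion_net import FusionNet, FusionNetSpec, build_network
from .synthetic_data import SyntheticSpec, generate_arrays

logger = logging.getLogger("texfuse")

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "ConfusionCounts",
    "MetricsReport",
    "ExperimentConfig",
    "make_folds",
    "compute_metrics",
    "extract_features",
    "train_network",
    "run_experiment",
    "sweep",
]

SWEEP_AXES = {
    "lbp_variant": ("default", "ror", "uniform", "nri_uniform", "var", "circular"),
    "hog_cell_size": (2, 4, 8, 16, 32),
    "fusion_position": ("input", "block1", "block2", "block3", "block4", "block5"),
}


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: Dict[str, int]  # sample id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> List[str]:
        return [sid for sid, f in self.assignments.items() if f == fold]


def make_folds(labels: Sequence[Tuple[str, str]], k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified, seed-deterministic k-fold assignment.

    ``labels`` is a list of (sample id, class name) pairs.  Per class,
    fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = [sid for sid, _ in labels]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    classes = [c for _, c in labels]
    counts: Dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    for c, n in counts.items():
        if n < k:
            raise ValueError(f"class {c!r} has {n} samples, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: Dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), classes)):
        for i in test_idx:
            assignments[ids[i]] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    per_class: Dict[str, Dict[str, float]]
    n_samples: int

    def as_dict(self) -> Dict:
        return dataclasses.asdict(self)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); defining as 0", what)
        return 0.0
    return num / den


def compute_metrics(pred: Sequence, truth: Sequence, averaging: str = "weighted") -> MetricsReport:
    """Confusion-count metrics with weighted or macro averaging.

    Per class c (one-vs-rest): precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2PR/(P+R); accuracy is the global
    fraction correct.  A class never predicted gets precision 0 (with
    a logged warning) rather than NaN.
    """
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    if averaging not in ("weighted", "macro"):
        raise ValueError("averaging must be 'weighted' or 'macro'")
    pred = list(pred)
    truth = list(truth)
    n = len(truth)
    class_set = sorted(set(truth) | set(pred), key=str)
    per_class: Dict[str, Dict[str, float]] = {}
    correct = sum(p == t for p, t in zip(pred, truth))
    accuracy = correct / n
    precs, recs, f1s, weights = [], [], [], []
    for c in class_set:
        tp = sum(1 for p, t in zip(pred, truth) if p == c and t == c)
        fp = sum(1 for p, t in zip(pred, truth) if p == c and t != c)
        fn = sum(1 for p, t in zip(pred, truth) if p != c and t == c)
        tn = n - tp - fp - fn
        support = tp + fn
        prec = _safe_div(tp, tp + fp, f"precision[{c}]")
        rec = _safe_div(tp, tp + fn, f"recall[{c}]")
        f1 = _safe_div(2 * prec * rec, prec + rec, f"f1[{c}]")
        per_class[str(c)] = {
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "support": support, "precision": prec, "recall": rec, "f1": f1,
        }
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
        weights.append(support)
    if averaging == "weighted":
        wsum = sum(weights)
        w = [x / wsum for x in weights] if wsum else [0.0] * len(weights)
    else:
        w = [1.0 / len(class_set)] * len(class_set)
    agg = lambda vals: float(sum(v * wi for v, wi in zip(vals, w)))
    return MetricsReport(
        accuracy=float(accuracy),
        precision=agg(precs),
        recall=agg(recs),
        f1=agg(f1s),
        averaging=averaging,
        per_class=per_class,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization parameters.  The full-scale operating point is
    lr 1e-4, 50 epochs, batch 64; scaled-down experiments typically
    use fewer epochs with a proportionally larger learning rate."""

    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    optimizer_name: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError("optimizer_name must be 'adam' or 'sgd'")


@dataclass
class ExperimentConfig:
    """Fully resolved experiment: data source, feature configs, model, training."""

    data_dir: Optional[str] = None
    synthetic: Optional[SyntheticSpec] = None
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(crop_mode="none", target_size=(64, 64)))
    lbp: LbpConfig = field(default_factory=LbpConfig)
    hog: HogConfig = field(default_factory=HogConfig)
    model: FusionNetSpec = field(default_factory=lambda: FusionNetSpec(width_multiplier=0.125, input_size=(64, 64)))
    train: TrainConfig = field(default_factory=TrainConfig)
    k_folds: int = 5
    averaging: str = "weighted"
    use_texture: bool = True

    @classmethod
    def from_dict(cls, d: Dict) -> "ExperimentConfig":
        def sub(klass, key):
            block = d.get(key)
            return klass(**block) if block is not None else None

        kwargs: Dict = {}
        for key, klass in [
            ("preprocess", PreprocessConfig), ("lbp", LbpConfig), ("hog", HogConfig),
            ("model", FusionNetSpec), ("train", TrainConfig),
        ]:
            block = d.get(key)
            if block is not None:
                if "target_size" in block:
                    block = dict(block, target_size=tuple(block["target_size"]))
                if "input_size" in block:
                    block = dict(block, input_size=tuple(block["input_size"]))
                kwargs[key] = klass(**block)
        syn = d.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            for tk in ("image_size", "lesion_count_range", "lesion_radius_range"):
                if tk in syn:
                    syn[tk] = tuple(syn[tk])
            kwargs["synthetic"] = SyntheticSpec(**syn)
        for key in ("data_dir", "k_folds", "averaging", "use_texture"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# feature extraction + training
# ---------------------------------------------------------------------------

def extract_features(images: Sequence[np.ndarray], cfg: ExperimentConfig
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Preprocess images and compute their texture-feature stacks.

    Returns (depth, texture): float32 arrays of shape (N, 1, H, W) and
    (N, 2, H, W) where (H, W) is the model input size.
    """
    target = cfg.model.input_size
    pcfg = dataclasses.replace(cfg.preprocess, target_size=target)
    depth_list, tex_list = [], []
    for px in images:
        img = GrayImage(np.asarray(px, dtype=np.float64))
        img = resize(normalize_minmax(img), pcfg)
        lbp_img = render_lbp_image(lbp_map(img, cfg.lbp))
        hog_img = hog_feature_image(img, cfg.hog)
        depth_list.append(img.pixels[None])
        tex_list.append(np.stack([lbp_img.pixels, hog_img.pixels]))
    return (
        np.asarray(depth_list, dtype=np.float32),
        np.asarray(tex_list, dtype=np.float32),
    )


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class _SGD:
    def __init__(self, params, lr):
        self.lr = lr

    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * g


def train_network(net: FusionNet, depth: np.ndarray, texture: Optional[np.ndarray],
                  labels: np.ndarray, cfg: TrainConfig) -> List[float]:
    """Minibatch training; returns the per-epoch mean loss trace."""
    opt = (_Adam if cfg.optimizer_name == "adam" else _SGD)(net.params, cfg.learning_rate)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    n = depth.shape[0]
    labels = np.asarray(labels, dtype=np.int64)
    trace: List[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            tex = texture[idx] if texture is not None else None
            loss, grads = net.loss_and_grads(depth[idx], tex, labels[idx], rng=rng)
            opt.step(net.params, grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


def _predict_labels(net: FusionNet, depth: np.ndarray, texture: Optional[np.ndarray],
                    batch: int = 64) -> Tuple[np.ndarray, np.ndarray]:
    preds, scores = [], []
    for start in range(0, depth.shape[0], batch):
        tex = texture[start : start + batch] if texture is not None else None
        logits = net.predict_logits(depth[start : start + batch], tex)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        preds.append(logits.argmax(axis=1))
        scores.append(p[:, 1])
    return np.concatenate(preds), np.concatenate(scores)


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

def _load_directory(data_dir: str | Path) -> Tuple[List[np.ndarray], List[int], List[str]]:
    from PIL import Image

    root = Path(data_dir)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"{root} must contain at least two class directories")
    images, labels, ids = [], [], []
    for label, cdir in enumerate(class_dirs):
        files = sorted(list(cdir.glob("*.png")) + list(cdir.glob("*.jpg")) + list(cdir.glob("*.jpeg")))
        for f in files:
            with Image.open(f) as im:
                images.append(np.asarray(im.convert("L"), dtype=np.float64) / 255.0)
            labels.append(label)
            ids.append(f"{cdir.name}/{f.name}")
    return images, labels, ids


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> Dict:
    """Full k-fold cross-validated experiment.

    Returns a results bundle: per-fold and mean metric reports, the
    resolved config and all seeds; optionally written to ``out_dir``
    as metrics.json + predictions.csv + resolved_config.yaml + log.
    """
    t0 = time.time()
    if cfg.data_dir is not None:
        images, labels, ids = _load_directory(cfg.data_dir)
    elif cfg.synthetic is not None:
        images, labels, ids = generate_arrays(cfg.synthetic)
    else:
        raise ValueError("config must provide data_dir or a synthetic spec")
    labels = np.asarray(labels)
    class_names = ["normal", "pneumonia"] if cfg.synthetic is not None else None

    depth, texture = extract_features(images, cfg)
    plan = make_folds(
        [(sid, str(lab)) for sid, lab in zip(ids, labels)], k=cfg.k_folds, seed=cfg.train.seed
    )
    id_to_idx = {sid: i for i, sid in enumerate(ids)}

    fold_reports: List[MetricsReport] = []
    rows = []
    for fold in range(cfg.k_folds):
        try:
            test_ids = plan.fold_ids(fold)
            test_idx = np.asarray([id_to_idx[s] for s in test_ids])
            train_idx = np.asarray([i for i in range(len(ids)) if i not in set(test_idx)])
            net_seed = (cfg.train.seed * 1009 + fold * 101) % (2**31 - 1)
            net = build_network(cfg.model, seed=net_seed)
            tcfg = dataclasses.replace(cfg.train, seed=(cfg.train.seed * 31 + fold) % (2**31 - 1))
            tex_train = texture[train_idx] if cfg.use_texture else None
            train_network(net, depth[train_idx], tex_train, labels[train_idx], tcfg)
            tex_test = texture[test_idx] if cfg.use_texture else None
            preds, scores = _predict_labels(net, depth[test_idx], tex_test)
            report = compute_metrics(preds.tolist(), labels[test_idx].tolist(), cfg.averaging)
            fold_reports.append(report)
            for sid, t, p, sc in zip(test_ids, labels[test_idx], preds, scores):
                rows.append({"sample_id": sid, "fold": fold, "truth": int(t),
                             "prediction": int(p), "score_pneumonia": float(sc)})
            logger.info("fold %d: accuracy %.4f", fold, report.accuracy)
        except Exception:
            logger.exception("fold %d failed; continuing with remaining folds", fold)
    if not fold_reports:
        raise RuntimeError("all folds failed")

    mean = {
        m: float(np.mean([getattr(r, m) for r in fold_reports]))
        for m in ("accuracy", "precision", "recall", "f1")
    }
    bundle = {
        "per_fold": [r.as_dict() for r in fold_reports],
        "mean": mean,
        "n_folds_completed": len(fold_reports),
        "seed": cfg.train.seed,
        "use_texture": cfg.use_texture,
        "class_names": class_names,
        "wall_time_s": time.time() - t0,
        "config": cfg.to_dict(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
        pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
        with open(out / "log.txt", "a") as fh:
            fh.write(
                f"{time.strftime('%Y-%m-%d %H:%M:%S')} seed={cfg.train.seed} "
                f"mean_accuracy={mean['accuracy']:.4f} wall={bundle['wall_time_s']:.1f}s\n"
            )
    return bundle


def sweep(cfg: ExperimentConfig, axis: str, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Re-run the experiment along one axis; returns the comparison table."""
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {sorted(SWEEP_AXES)}")
    rows = []
    for value in SWEEP_AXES[axis]:
        c = dataclasses.replace(cfg)
        if axis == "lbp_variant":
            c.lbp = dataclasses.replace(cfg.lbp, variant=value)
        elif axis == "hog_cell_size":
            c.hog = dataclasses.replace(cfg.hog, cell_size=value)
        else:
            c.model = dataclasses.replace(cfg.model, fusion_position=value)
        bundle = run_experiment(c)
        rows.append({axis: value, **bundle["mean"]})
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
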