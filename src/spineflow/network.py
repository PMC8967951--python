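"""Patch pipeline, training, tiled prediction and masked evaluation.

The public surface is :class:`SpineSegmenter`, a fit/predict estimator in
the scikit-learn style: construct with config objects, ``fit`` on paired
intensity/label volumes, ``predict`` full volumes by tiled inference.
Module-level functions (:func:`extract_patches`, :func:`predict_volume`,
:func:`evaluate`, ...) expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from ._layers import softmax
from ._unet import UNet3D
from .config import TrainConfig, UNetConfig, WeightingConfig
from .core import IntensityVolume, LabelVolume, SHAFT, SPINE, ValidationError, VoxelGeometry
from .weighting import LOG_CLAMP, build_weight_volume, class_weights_smoothed, wcel

#: Evaluation mask radius: the largest observed spine-to-shaft distance (μm).
DEFAULT_MASK_RADIUS_UM = 7.58


def build_model(cfg: UNetConfig, seed: int = 0) -> UNet3D:
    """Instantiate the volumetric U-Net; validates the patch-size contract."""
    return UNet3D(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# patches

@dataclass
class Patch:
    image: np.ndarray  # (D, H, W) input window, normalized
    labels: np.ndarray  # (d, h, w) output-window labels
    weight: np.ndarray  # (d, h, w)
    position: Tuple[int, int, int]  # zyx of output window origin


def _tile_positions(vol_shape_zyx, out_zyx) -> List[Tuple[int, int, int]]:
    """Output-window origins tiling the volume with stride = output size.

    The trailing window on each axis is clipped to the volume, so output
    regions are disjoint and cover everything."""
    axes = []
    for size, step in zip(vol_shape_zyx, out_zyx):
        pos = list(range(0, size, step))
        axes.append(pos)
    return [(z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]]


def _padded_window(arr: np.ndarray, lo_zyx, hi_zyx, mode: str) -> np.ndarray:
    """Window [lo, hi) with out-of-volume context filled by padding."""
    pads, sls = [], []
    for ax, (lo, hi) in enumerate(zip(lo_zyx, hi_zyx)):
        n = arr.shape[ax]
        pads.append((max(0, -lo), max(0, hi - n)))
        sls.append(slice(max(0, lo), min(n, hi)))
    win = arr[tuple(sls)]
    if any(p != (0, 0) for p in pads):
        np_mode = "reflect" if mode == "reflective" else "constant"
        win = np.pad(win, pads, mode=np_mode)
    return win


def _patch_keep(labels: np.ndarray, cfg: TrainConfig) -> bool:
    frac = float((labels > 0).mean())
    if cfg.patch_filter == "any_labeled":
        return frac > 0
    return frac > cfg.min_label_fraction


def extract_patches(
    image: IntensityVolume,
    labels: LabelVolume,
    net_cfg: UNetConfig,
    train_cfg: TrainConfig,
    weighting_cfg: Optional[WeightingConfig] = None,
    dataset_class_weights: Optional[np.ndarray] = None,
) -> Iterator[Patch]:
    """Yield filtered training patches covering the volume.

    Output windows tile the volume with stride equal to the output patch;
    the wider input window adds the architecture's context margin, filled
    with reflective (or zero) padding at the borders.  Patches failing the
    labeled-content filter are dropped.
    """
    weighting_cfg = weighting_cfg or WeightingConfig()
    img = np.asarray(image.values, dtype=np.float32)
    lab = labels.labels
    if img.shape != lab.shape:
        raise ValidationError("image and label volumes must be aligned")
    out_zyx = (net_cfg.output_patch[2], net_cfg.output_patch[1], net_cfg.output_patch[0])
    margins = net_cfg.margins
    m_zyx = (margins[2], margins[1], margins[0])
    scale = max(float(img.max()), 1.0)
    for pos in _tile_positions(img.shape, out_zyx):
        hi = tuple(p + s for p, s in zip(pos, out_zyx))
        lab_win = _padded_window(lab, pos, hi, net_cfg.padding_mode)
        if not _patch_keep(lab_win, train_cfg):
            continue
        in_lo = tuple(p - m for p, m in zip(pos, m_zyx))
        in_hi = tuple(h + m for h, m in zip(hi, m_zyx))
        img_win = _padded_window(img, in_lo, in_hi, net_cfg.padding_mode) / scale
        w = build_weight_volume(lab_win, weighting_cfg, image.geometry, dataset_class_weights)
        yield Patch(img_win, lab_win, w, pos)


def augment_isometric(
    image: np.ndarray,
    labels: np.ndarray,
    weight: Optional[np.ndarray] = None,
    seed: int | np.random.Generator = 0,
) -> Tuple[np.ndarray, ...]:
    """Apply one random isometry (identity, in-plane 90° rotation, axis flip,
    integer-voxel translation) identically to image, labels and weights.

    Translations are periodic shifts, preserving voxel-to-voxel
    correspondence and the label histogram."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(rng.integers(0, 4))  # in-plane rotation (y-x plane)
    flips = [bool(rng.integers(0, 2)) for _ in range(3)]
    same_shape = image.shape == labels.shape
    # rotation only when the in-plane extent is square, so shapes survive
    rotatable = image.shape[1] == image.shape[2] and labels.shape[1] == labels.shape[2]
    shift = tuple(int(s) for s in rng.integers(-2, 3, size=3)) if same_shape else (0, 0, 0)

    def tf(a):
        if a is None:
            return None
        if rotatable and k:
            a = np.rot90(a, k=k, axes=(1, 2))
        for ax, f in enumerate(flips):
            if f:
                a = np.flip(a, axis=ax)
        if any(shift):
            a = np.roll(a, shift, axis=(0, 1, 2))
        return a.copy()

    out = (tf(image), tf(labels))
    return out + ((tf(weight),) if weight is not None else ())


# ---------------------------------------------------------------------------
# losses on batches (mean over voxels, for stable learning-rate scales)

def _loss_and_grad(logits: np.ndarray, lab: np.ndarray, w: np.ndarray, loss: str):
    """Loss value (mean per voxel) and d(loss)/d(logits); channels-last."""
    p = softmax(logits, axis=-1)
    n, d, h, wd, _ = logits.shape
    r = np.stack([(lab == k) for k in range(3)], axis=-1).astype(np.float32)
    nvox = n * d * h * wd
    if loss in ("wcel", "cel"):
        wmap = np.ones_like(lab, dtype=np.float32) if loss == "cel" else w.astype(np.float32)
        logp = np.log(np.clip(p, LOG_CLAMP, None))
        value = float(-(wmap[..., None] * r * logp).sum() / nvox)
        grad = wmap[..., None] * (p - r) / nvox
        return value, grad.astype(np.float32)
    # generalized Dice
    wk = np.zeros(3)
    counts = r.reshape(-1, 3).sum(axis=0)
    present = counts > 0
    wk[present] = 1.0 / counts[present] ** 2
    inter = (r * p).reshape(-1, 3).sum(axis=0)
    total = (r + p).reshape(-1, 3).sum(axis=0)
    A = float((wk * inter).sum())
    B = float((wk * total).sum())
    if B == 0:
        return 0.0, np.zeros_like(p, dtype=np.float32)
    value = 1.0 - 2.0 * A / B
    dldp = -2.0 * (wk * r * B - A * wk) / B**2
    grad = p * (dldp - (dldp * p).sum(axis=-1, keepdims=True))
    return float(value), grad.astype(np.float32)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_f1: List[float] = field(default_factory=list)
    best_epoch: int = -1


def train(
    model: UNet3D,
    data: Sequence[Tuple[IntensityVolume, LabelVolume]],
    train_cfg: TrainConfig,
    weighting_cfg: Optional[WeightingConfig] = None,
    val_data: Optional[Sequence[Tuple[IntensityVolume, LabelVolume]]] = None,
) -> TrainingHistory:
    """Train in place, minimizing the configured loss with Adam.

    Whole volumes are split into train/validation when ``val_data`` is not
    given.  After each epoch the masked mean F1 on the validation volumes is
    logged and the parameters of the best epoch are retained.
    """
    weighting_cfg = weighting_cfg or WeightingConfig()
    if len(data) == 0:
        raise ValidationError("training requires at least one volume")
    rng = np.random.default_rng(train_cfg.seed)

    if val_data is None:
        n_val = max(1, round(train_cfg.validation_fraction * len(data))) if len(data) > 1 else 0
        order = rng.permutation(len(data))
        val_idx = set(order[:n_val].tolist())
        val_data = [data[i] for i in sorted(val_idx)]
        data = [data[i] for i in range(len(data)) if i not in val_idx]

    ds_weights = None
    if weighting_cfg.class_scope == "dataset":
        all_labs = np.concatenate([lab.labels.ravel() for _, lab in data])
        ds_weights = class_weights_smoothed(all_labs)

    patches: List[Patch] = []
    for img, lab in data:
        patches.extend(
            extract_patches(img, lab, model.cfg, train_cfg, weighting_cfg, ds_weights)
        )
    if not patches:
        raise ValidationError("no patches passed the label-content filter")

    opt = model.make_optimizer(
        train_cfg.learning_rate, train_cfg.beta1, train_cfg.beta2, train_cfg.eps
    )
    history = TrainingHistory()
    best_f1, best_params = -1.0, None

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(patches))
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [patches[i] for i in order[start:start + train_cfg.batch_size]]
            imgs, labs, ws = [], [], []
            for p in batch:
                im, lb, w = p.image, p.labels, p.weight
                if train_cfg.augment:
                    im, lb, w = augment_isometric(im, lb, w, rng)
                imgs.append(im)
                labs.append(lb)
                ws.append(w)
            x = np.stack(imgs)[..., None]
            logits = model.forward(x)
            value, grad = _loss_and_grad(logits, np.stack(labs), np.stack(ws), weighting_cfg.loss)
            model.backward(grad)
            opt.step(model.grads)
            losses.append(value)
        history.train_loss.append(float(np.mean(losses)))

        if val_data:
            vloss, vf1 = _validate(model, val_data, weighting_cfg)
            history.val_loss.append(vloss)
            history.val_f1.append(vf1)
            if vf1 > best_f1:
                best_f1 = vf1
                best_params = [p.copy() for p in model.params]
                history.best_epoch = epoch
        else:
            history.best_epoch = epoch

    if best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
    return history


def _validate(model, val_data, weighting_cfg) -> Tuple[float, float]:
    losses, f1s = [], []
    for img, lab in val_data:
        prob, pred = predict_volume(model, img)
        r = lab.one_hot()
        losses.append(wcel(prob, r) / lab.labels.size)
        rep = evaluate(pred, lab)
        f1s.append(rep.f1_mean)
    return float(np.mean(losses)), float(np.mean(f1s))


# ---------------------------------------------------------------------------
# prediction

def predict_volume(
    model: UNet3D, image: IntensityVolume
) -> Tuple[np.ndarray, LabelVolume]:
    """Tiled full-volume inference.

    Tiles with stride equal to the output patch (reflective context at the
    borders), writes each output voxel exactly once, and returns the class
    probabilities ``(3, z, y, x)`` plus the argmax label map (ties broken
    toward the lower class code)."""
    cfg = model.cfg
    img = np.asarray(image.values, dtype=np.float32)
    scale = max(float(img.max()), 1.0)
    out_zyx = (cfg.output_patch[2], cfg.output_patch[1], cfg.output_patch[0])
    m_zyx = (cfg.margins[2], cfg.margins[1], cfg.margins[0])
    prob = np.zeros((3,) + img.shape, dtype=np.float32)
    for pos in _tile_positions(img.shape, out_zyx):
        hi = tuple(min(p + s, n) for p, s, n in zip(pos, out_zyx, img.shape))
        in_lo = tuple(p - m for p, m in zip(pos, m_zyx))
        in_hi = tuple(p + s + m for p, s, m in zip(pos, out_zyx, m_zyx))
        win = _padded_window(img, in_lo, in_hi, cfg.padding_mode) / scale
        p_out = model.predict_proba_patch(win[None, ..., None])[0]  # (d, h, w, 3)
        sl = tuple(slice(p, h) for p, h in zip(pos, hi))
        crop = tuple(slice(0, h - p) for p, h in zip(pos, hi))
        prob[(slice(None),) + sl] = np.moveaxis(p_out[crop], -1, 0)
    labels = prob.argmax(axis=0).astype(np.uint8)
    return prob, LabelVolume(labels, image.geometry)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


@dataclass
class MetricsReport:
    per_class: Dict[str, ClassMetrics]
    f1_mean: float
    mask_radius_um: float

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: per-class precision/recall/F1 plus the F1 mean."""
        rows = []
        for name, m in self.per_class.items():
            rows.append(
                {"class": name, "precision": m.precision, "recall": m.recall, "f1": m.f1,
                 "tp": m.tp, "fp": m.fp, "fn": m.fn}
            )
        df = pd.DataFrame(rows)
        df.attrs["f1_mean"] = self.f1_mean
        df.attrs["mask_radius_um"] = self.mask_radius_um
        return df


def evaluate(
    pred: LabelVolume,
    gt: LabelVolume,
    mask_radius_um: float = DEFAULT_MASK_RADIUS_UM,
) -> MetricsReport:
    """Per-class precision/recall/F1 restricted to the shaft neighborhood.

    Voxels farther than ``mask_radius_um`` (physical distance) from the
    ground-truth dendritic shaft are excluded, matching how incompletely
    annotated stacks are scored.  Zero-denominator metrics are reported as 0
    and flagged."""
    if pred.labels.shape != gt.labels.shape:
        raise ValidationError("prediction and ground truth shapes differ")
    shaft = gt.labels == SHAFT
    if np.isinf(mask_radius_um) or not shaft.any():
        mask = np.ones_like(gt.labels, dtype=bool)
    else:
        d = ndimage.distance_transform_edt(~shaft, sampling=gt.geometry.spacing_zyx)
        mask = d <= mask_radius_um
    p = pred.labels[mask]
    g = gt.labels[mask]
    per = {}
    f1s = []
    for cls, name in ((SHAFT, "shaft"), (SPINE, "spine")):
        tp = int(((p == cls) & (g == cls)).sum())
        fp = int(((p == cls) & (g != cls)).sum())
        fn = int(((p != cls) & (g == cls)).sum())
        degenerate = False
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        if (tp + fp == 0) or (tp + fn == 0):
            degenerate = True
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[name] = ClassMetrics(tp, fp, fn, prec, rec, f1, degenerate)
        f1s.append(f1)
    return MetricsReport(per, float(np.mean(f1s)), mask_radius_um)


# ---------------------------------------------------------------------------
# estimator

class SpineSegmenter:
    """Volumetric 3-class segmentation estimator (scikit-learn style).

    Parameters mirror the network/training/weighting config dataclasses.
    After :meth:`fit`, the trained network is available as ``model_`` and
    the loss/F1 trajectory as ``history_``.
    """

    def __init__(
        self,
        network: Optional[UNetConfig] = None,
        train: Optional[TrainConfig] = None,
        weighting: Optional[WeightingConfig] = None,
    ):
        self.network = network or UNetConfig()
        self.train = train or TrainConfig()
        self.weighting = weighting or WeightingConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"network": self.network, "train": self.train, "weighting": self.weighting}

    def set_params(self, **params) -> "SpineSegmenter":
        for k, v in params.items():
            if k not in ("network", "train", "weighting"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        X: Sequence[IntensityVolume],
        y: Sequence[LabelVolume],
        val: Optional[Sequence[Tuple[IntensityVolume, LabelVolume]]] = None,
    ) -> "SpineSegmenter":
        if len(X) != len(y):
            raise ValidationError("X and y must pair up")
        self.model_ = build_model(self.network, self.train.seed)
        self.history_ = train(self.model_, list(zip(X, y)), self.train, self.weighting, val)
        return self

    def predict(self, X: IntensityVolume) -> LabelVolume:
        self._check_fitted()
        return predict_volume(self.model_, X)[1]

    def predict_proba(self, X: IntensityVolume) -> np.ndarray:
        self._check_fitted()
        return predict_volume(self.model_, X)[0]

    def score(self, X: IntensityVolume, y: LabelVolume) -> float:
        """Masked mean F1 on one volume."""
        return evaluate(self.predict(X), y).f1_mean

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise ValidationError("SpineSegmenter is not fitted; call fit first")
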