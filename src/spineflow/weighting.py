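"""Class weights, distance-based pixel weights, and the two training losses.

The weight map factorizes as ``w(x) = w_class(x) * w_pixel(x)``: the class
term counteracts the extreme background/shaft/spine imbalance with a
smoothed log-frequency weight, and the pixel term down-weights voxels far
from any annotated structure so that unreconstructed branches do not
penalize the model.  The losses are the weighted cross-entropy (WCEL) and
the generalized Dice loss (GDL).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .config import WeightingConfig
from .core import LabelVolume, ValidationError, VoxelGeometry

LOG_CLAMP = 1e-12  # floors log(p) to keep confident wrong predictions finite


def class_weights_smoothed(labels: np.ndarray) -> np.ndarray:
    """Smoothed per-class weights w_k from voxel counts.

    ``w'_k = max(log(2 * n_total / n_k), 1)`` (natural log), normalized to
    sum to one.  An absent class takes the single-voxel limit
    ``w'_k = log(2 * n_total)`` so patches without spines stay trainable.
    """
    lab = np.asarray(labels)
    n_total = lab.size
    if n_total < 1:
        raise ValidationError("empty label array")
    counts = np.array([(lab == k).sum() for k in range(3)], dtype=np.float64)
    safe = np.where(counts > 0, counts, 1.0)
    w_prime = np.maximum(np.log(2.0 * n_total / safe), 1.0)
    return w_prime / w_prime.sum()


def class_weights_gdl(one_hot: np.ndarray) -> np.ndarray:
    """Generalized-Dice class weights 1 / (sum_x r_k)^2; absent classes get 0
    so they drop out of both GDL sums."""
    r = np.asarray(one_hot, dtype=np.float64)
    counts = r.reshape(r.shape[0], -1).sum(axis=1)
    w = np.zeros_like(counts)
    present = counts > 0
    w[present] = 1.0 / counts[present] ** 2
    return w


def distance_field(
    labels: np.ndarray | LabelVolume, geometry: Optional[VoxelGeometry] = None
) -> np.ndarray:
    """Exact Euclidean distance (μm) to the nearest labeled structure voxel."""
    if isinstance(labels, LabelVolume):
        geometry = geometry or labels.geometry
        mask = labels.labels > 0
    else:
        mask = np.asarray(labels) > 0
    geometry = geometry or VoxelGeometry()
    if not mask.any():
        raise ValidationError("distance field needs at least one labeled voxel")
    return ndimage.distance_transform_edt(~mask, sampling=geometry.spacing_zyx)


def pixel_weight_exp(d: np.ndarray, r_decay: float = 0.5) -> np.ndarray:
    """Exponential decay weight (1 - r_decay)^d with d in μm."""
    if not 0 <= r_decay <= 1:
        raise ValidationError("r_decay must be in [0, 1]")
    return np.power(1.0 - r_decay, np.asarray(d, dtype=np.float64))


def pixel_weight_window(d: np.ndarray, d_max: float = 5.0) -> np.ndarray:
    """Quartic window weight (1 - (d/d_max)^2)^2 for d < d_max, else 0."""
    if d_max <= 0:
        raise ValidationError("d_max must be positive")
    d = np.asarray(d, dtype=np.float64)
    w = (1.0 - (d / d_max) ** 2) ** 2
    return np.where(d < d_max, w, 0.0)


def build_weight_volume(
    labels: np.ndarray,
    cfg: WeightingConfig,
    geometry: Optional[VoxelGeometry] = None,
    dataset_class_weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-voxel weight map w(x) = w_class(x) * w_pixel(x).

    ``class_scope='dataset'`` uses precomputed whole-data-set class weights;
    otherwise weights are computed from this patch.  ``mode='none'`` leaves
    the pixel term at 1.
    """
    lab = np.asarray(labels)
    if cfg.class_scope == "dataset":
        if dataset_class_weights is None:
            raise ValidationError("dataset class scope requires dataset_class_weights")
        wk = np.asarray(dataset_class_weights, dtype=np.float64)
    else:
        wk = class_weights_smoothed(lab)
    w = wk[lab]
    if cfg.mode != "none":
        if not (lab > 0).any():
            # no structure anywhere: distance is unbounded, both weights -> 0
            pix = np.zeros(lab.shape)
        else:
            d = distance_field(lab, geometry)
            pix = pixel_weight_exp(d, cfg.r_decay) if cfg.mode == "exp" else pixel_weight_window(d, cfg.d_max)
        w = w * pix
    return w


def _as_prob(pred: np.ndarray) -> np.ndarray:
    p = np.asarray(pred, dtype=np.float64)
    if p.ndim != 4 or p.shape[0] != 3:
        raise ValidationError(f"prediction must be (3, z, y, x), got {p.shape}")
    return p


def wcel(pred: np.ndarray, gt_one_hot: np.ndarray, weight: Optional[np.ndarray] = None) -> float:
    """Weighted cross-entropy −Σ_x w(x) Σ_k r_k(x) log p_k(x)."""
    p = _as_prob(pred)
    r = np.asarray(gt_one_hot, dtype=np.float64)
    if r.shape != p.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs gt {r.shape}")
    logp = np.log(np.clip(p, LOG_CLAMP, None))
    ce = -(r * logp).sum(axis=0)
    if weight is not None:
        w = np.asarray(weight, dtype=np.float64)
        if w.shape != ce.shape:
            raise ValidationError(f"weight shape {w.shape} != volume shape {ce.shape}")
        ce = w * ce
    return float(ce.sum())


def gdl(pred: np.ndarray, gt_one_hot: np.ndarray) -> float:
    """Generalized Dice loss: 1 − 2 Σ_k w_k Σ_x r_k p_k / Σ_k w_k Σ_x (r_k + p_k)."""
    p = _as_prob(pred)
    r = np.asarray(gt_one_hot, dtype=np.float64)
    if r.shape != p.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs gt {r.shape}")
    wk = class_weights_gdl(r)
    inter = (r * p).reshape(3, -1).sum(axis=1)
    total = (r + p).reshape(3, -1).sum(axis=1)
    denom = float((wk * total).sum())
    if denom == 0:
        return 0.0
    return float(1.0 - 2.0 * (wk * inter).sum() / denom)
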