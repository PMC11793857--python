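"""Training objectives for the dual-decoder network and classification heads.

The segmentation stage minimizes a region loss and a contour loss

    L_r = 1 - (alpha * D + (1 - alpha) * C)
    L_c = 1 - (beta * C + (1 - beta) * C_rev)

where ``D`` is the soft Dice score over foreground classes, ``C`` and
``C_rev`` are score-like terms derived from distance-weighted cross-entropy
(``exp(-WCE)``, so each lies in (0, 1] and equals 1 at a perfect one-hot
prediction), ``alpha`` follows a linear warm-down schedule from 1.0 to 0.5,
and ``beta`` is the fraction of shape-boundary voxels in the batch.

The classification stage uses class-balanced cross-entropy: each task's
per-sample loss is scaled by ``K_c = (1/N_c) / sum_i(1/N_i)`` for the true
class ``c``, which normalizes to one across classes and equalizes the
contribution of unevenly represented grades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor

__all__ = [
    "EPS_DICE",
    "dice_score",
    "alpha_schedule",
    "beta_fraction",
    "distance_weight_maps",
    "edge_targets",
    "weighted_ce_score",
    "region_loss",
    "contour_loss",
    "ClassWeightTable",
    "class_weights",
    "classification_loss",
    "one_hot",
]

EPS_DICE = 1e-6


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, D, H, W) integer labels -> (N, C, D, H, W) float32 one-hot."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:],
                   dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def _check_probs(pred: np.ndarray) -> None:
    if pred.min() < -1e-5 or pred.max() > 1.0 + 1e-5:
        raise ValueError("predictions must be probabilities in [0, 1]")


def dice_score(pred_probs, target_onehot: np.ndarray):
    """Soft Dice over foreground classes: mean_c 2*sum(pq)/(sum p + sum q + eps).

    Accepts an autodiff ``Tensor`` (returns a scalar ``Tensor``) or a plain
    array (returns a float).
    """
    is_tensor = isinstance(pred_probs, Tensor)
    pred = pred_probs if is_tensor else Tensor(pred_probs)
    target_onehot = np.asarray(target_onehot, dtype=np.float32)
    if pred.data.shape != target_onehot.shape:
        raise ValueError(
            f"shape mismatch {pred.data.shape} vs {target_onehot.shape}"
        )
    _check_probs(pred.data)
    n_classes = pred.data.shape[1]
    axes = (0,) + tuple(range(2, pred.data.ndim))
    t = Tensor(target_onehot)
    inter = (pred * t).sum(axis=axes)
    psum = pred.sum(axis=axes)
    qsum = t.sum(axis=axes)
    # smoothing in numerator and denominator: a class absent from both
    # volumes scores 1, not 0
    per_class = (2.0 * inter + EPS_DICE) / (psum + qsum + EPS_DICE)
    fg = np.zeros(n_classes, dtype=np.float32)
    fg[1:] = 1.0
    d = (per_class * Tensor(fg)).sum() * (1.0 / float(n_classes - 1))
    return d if is_tensor else float(d.data)


def alpha_schedule(t: int) -> float:
    """Dice weight at iteration ``t``: 1 - 0.005 t, clamped below at 0.5."""
    if t < 0:
        raise ValueError("iteration index must be >= 0")
    return max(0.5, 1.0 - 0.005 * t)


def beta_fraction(edge_labels: np.ndarray) -> float:
    """Fraction of shape-boundary voxels over all voxels in the batch."""
    edge_labels = np.asarray(edge_labels)
    return float((edge_labels != 0).mean())


def distance_weight_maps(
    target_labels: np.ndarray,
    spacing_mm: tuple[float, float, float] | float,
    gamma: float = 5.0,
    tau_mm: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary-distance weight maps for the distance cross-entropy terms.

    ``d(x)`` is the Euclidean distance (mm) to the nearest inter-class
    boundary voxel; ``w_near = 1 + gamma * exp(-d/tau)`` emphasizes a band of
    width ~``tau_mm`` around boundaries, ``w_far = 1 + gamma * (1 - exp(-d/tau))``
    emphasizes interior and background.
    """
    labels = np.asarray(target_labels)
    spacing = ((spacing_mm,) * 3 if np.isscalar(spacing_mm)
               else tuple(spacing_mm))
    hi = ndimage.maximum_filter(labels, size=3)
    lo = ndimage.minimum_filter(labels, size=3)
    boundary = hi != lo
    if not boundary.any():
        warnings.warn("single-class label volume: uniform weight maps")
        ones = np.ones_like(labels, dtype=np.float32)
        return ones, ones.copy()
    d = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    near = np.exp(-d / tau_mm)
    w_near = (1.0 + gamma * near).astype(np.float32)
    w_far = (1.0 + gamma * (1.0 - near)).astype(np.float32)
    return w_near, w_far


def edge_targets(labels: np.ndarray) -> np.ndarray:
    """Three-class edge labels from region labels.

    The boundary of each foreground class is its morphological gradient
    (3x3x3 dilation minus erosion of the class mask); overlapping boundaries
    resolve to the lower class index; everything else is non-edge (0).
    """
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int16)
    struct = np.ones((3,) * labels.ndim, dtype=bool)
    for c in (2, 1):  # lower class index wins overlaps
        mask = labels == c
        if not mask.any():
            continue
        # border_value=1 on erosion: the grid boundary is not a shape edge
        grad = ndimage.binary_dilation(mask, struct) & ~ndimage.binary_erosion(
            mask, struct, border_value=1
        )
        out[grad] = c
    return out


def weighted_ce_score(pred_probs: Tensor, target_onehot: np.ndarray,
                      weights: np.ndarray | None = None) -> Tensor:
    """``exp(-WCE)`` with WCE the weight-averaged per-voxel cross-entropy."""
    _check_probs(pred_probs.data)
    t = Tensor(np.asarray(target_onehot, dtype=np.float32))
    ce = -(t * pred_probs.log()).sum(axis=1)  # (N, D, H, W)
    if weights is None:
        wce = ce.mean()
    else:
        w = np.asarray(weights, dtype=np.float32)
        w = np.broadcast_to(w, ce.data.shape)
        wce = (ce * Tensor(w)).sum() * (1.0 / float(w.sum()))
    return (-wce).exp()


def region_loss(pred_probs: Tensor, target_onehot: np.ndarray, alpha: float,
                w_near: np.ndarray | None = None) -> Tensor:
    """L_r = 1 - (alpha * Dice + (1 - alpha) * C) on mask-decoder outputs."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    d = dice_score(pred_probs, target_onehot)
    c_term = weighted_ce_score(pred_probs, target_onehot, w_near)
    return 1.0 - (alpha * d + (1.0 - alpha) * c_term)


def contour_loss(pred_edge_probs: Tensor, edge_onehot: np.ndarray, beta: float,
                 w_near: np.ndarray | None = None,
                 w_far: np.ndarray | None = None) -> Tensor:
    """L_c = 1 - (beta * C + (1 - beta) * C_rev) on contour-decoder outputs."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    c_term = weighted_ce_score(pred_edge_probs, edge_onehot, w_near)
    c_rev = weighted_ce_score(pred_edge_probs, edge_onehot, w_far)
    return 1.0 - (beta * c_term + (1.0 - beta) * c_rev)


@dataclass(frozen=True)
class ClassWeightTable:
    """Inverse-frequency class weights K_c (they sum to one)."""

    weights: tuple[float, ...]
    counts: tuple[float, ...]

    @property
    def n_classes(self) -> int:
        return len(self.weights)


def class_weights(counts) -> ClassWeightTable:
    """K_c = (1/N_c) / sum_i (1/N_i); undefined if any class count is zero."""
    counts = np.asarray(counts, dtype=np.float64)
    if (counts <= 0).any():
        raise ValueError("class balancing undefined for zero class counts")
    inv = 1.0 / counts
    k = inv / inv.sum()
    return ClassWeightTable(weights=tuple(float(v) for v in k),
                            counts=tuple(float(v) for v in counts))


def classification_loss(
    head_outputs: dict[str, Tensor],
    truth: dict[str, np.ndarray],
    weights: dict[str, ClassWeightTable],
) -> Tensor:
    """Class-balanced cross-entropy summed over the OS, JS and HSA tasks.

    ``head_outputs['os'|'js']`` are (N, 3) softmax probabilities,
    ``head_outputs['hsa']`` is (N, 1) sigmoid probability of the eccentric
    class; ``truth`` holds integer grades per task.
    """
    total = None
    for task in ("os", "js"):
        p = head_outputs[task]
        y = np.asarray(truth[task], dtype=int)
        k = np.asarray(weights[task].weights, dtype=np.float32)[y]
        onehot = np.zeros_like(p.data)
        onehot[np.arange(len(y)), y] = 1.0
        if (p.data[np.arange(len(y)), y] <= 0).any():
            warnings.warn(f"{task}: zero probability at true class, clamping")
        ce = -(Tensor(onehot) * p.log()).sum(axis=1)
        term = (ce * Tensor(k)).mean()
        total = term if total is None else total + term
    p = head_outputs["hsa"]
    y = np.asarray(truth["hsa"], dtype=np.float32).reshape(-1, 1)
    k = np.asarray(weights["hsa"].weights, dtype=np.float32)[
        y.astype(int).ravel()
    ].reshape(-1, 1)
    if ((p.data <= 0) & (y > 0)).any() or ((p.data >= 1) & (y < 1)).any():
        warnings.warn("hsa: zero probability at true class, clamping")
    ce = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    total = total + (ce * Tensor(k)).mean()
    return total


def classification_loss_from_logits(
    head_logits: dict[str, Tensor],
    truth: dict[str, np.ndarray],
    weights: dict[str, ClassWeightTable],
) -> Tensor:
    """Numerically stable variant of :func:`classification_loss` on logits.

    Identical loss values, but cross-entropy is computed via log-softmax
    (and softplus for the binary head), so gradients stay bounded
    (softmax minus one-hot) even when float32 probabilities saturate —
    which is what the training loops need to recover from confident
    mistakes.
    """
    total = None
    for task in ("os", "js"):
        z = head_logits[task]
        y = np.asarray(truth[task], dtype=int)
        k = np.asarray(weights[task].weights, dtype=np.float32)[y]
        zmax = z.data.max(axis=1, keepdims=True)  # detached shift
        lse = ((z - zmax).exp().sum(axis=1, keepdims=True)).log() + Tensor(zmax)
        logp = z - lse
        onehot = np.zeros_like(z.data)
        onehot[np.arange(len(y)), y] = 1.0
        ce = -(Tensor(onehot) * logp).sum(axis=1)
        term = (ce * Tensor(k)).mean()
        total = term if total is None else total + term
    z = head_logits["hsa"]
    y = np.asarray(truth["hsa"], dtype=np.float32).reshape(-1, 1)
    k = np.asarray(weights["hsa"].weights, dtype=np.float32)[
        y.astype(int).ravel()
    ].reshape(-1, 1)
    # bce(z, y) = softplus(z) - y*z, softplus via the overflow-safe form
    absz = z.relu() + (-z).relu()
    softplus = ((-absz).exp() + 1.0).log() + z.relu()
    ce = softplus - Tensor(y) * z
    return total + (ce * Tensor(k)).mean()
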