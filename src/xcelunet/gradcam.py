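"""3D multi-class GradCAM on the classification bottleneck.

For a chosen task (class set ``s`` in {OS, JS, HSA}) and class ``c``, the
class activation map is

    L = ReLU( sum_f alpha_f * A_f ),   alpha_f = (1/Z) * sum_{ijk} dy/dA_f,ijk

where ``A_f`` are the 64 pre-pooling bottleneck feature maps, ``Z`` their
voxel count (1000 for the 10x10x10 bottleneck of an 80^3 crop), and ``y``
the head's pre-activation score for class ``c`` (the pre-softmax logit for
OS/JS, the pre-sigmoid logit for HSA).  The map is ReLU-rectified and
trilinearly upsampled onto the input crop grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .core import GHCrop
from .network import XCELUNet

__all__ = [
    "ActivationMap",
    "LocalizationScore",
    "compute_gradcam",
    "overlay",
    "localization_score",
]

_TASK_HEADS = {"OS": "os", "JS": "js", "HSA": "hsa"}
_TASK_SIZES = {"OS": 3, "JS": 3, "HSA": 1}


@dataclass
class ActivationMap:
    heatmap: np.ndarray                # upsampled to crop shape, >= 0
    raw: np.ndarray                    # bottleneck-resolution map, >= 0
    class_set: str
    class_index: int
    alpha: np.ndarray                  # per-feature-map weights (64,)
    z: int                             # feature-map voxel count in Eq. averaging


@dataclass
class LocalizationScore:
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("localization fraction must lie in [0, 1]")


def _classification_logits(model: XCELUNet, bottleneck: Tensor) -> dict[str, Tensor]:
    from .layers import global_avg_pool

    h = model.cls_dense2(
        model.cls_dense1(global_avg_pool(bottleneck)).relu()
    ).relu()
    return {
        "os": model.os_head(h),
        "js": model.js_head(h),
        "hsa": model.hsa_head(h),
    }


def compute_gradcam(model: XCELUNet, crop: GHCrop | np.ndarray,
                    class_set: str, class_index: int) -> ActivationMap:
    """Class activation map of one task/class for a normalized GH crop."""
    class_set = class_set.upper()
    if class_set not in _TASK_HEADS:
        raise ValueError(f"class_set must be one of {list(_TASK_HEADS)}")
    if not 0 <= class_index < _TASK_SIZES[class_set]:
        raise ValueError(
            f"class_index {class_index} out of range for {class_set}"
        )
    data = crop.data if isinstance(crop, GHCrop) else np.asarray(crop)
    x = data.astype(np.float32)[None, None]

    # bottleneck activations as an autodiff leaf so gradients reach them
    # regardless of which parameter groups are frozen
    feats, _ = model._encode(Tensor(x))
    leaf = Tensor(feats.data, requires_grad=True)
    logits = _classification_logits(model, leaf)[_TASK_HEADS[class_set]]
    selector = np.zeros_like(logits.data)
    selector[0, class_index] = 1.0
    y = (logits * Tensor(selector)).sum()
    y.backward()

    delta = leaf.grad[0]                      # (64, z, z, z)
    z_count = int(np.prod(delta.shape[1:]))
    alpha = delta.sum(axis=(1, 2, 3)) / z_count
    raw = np.maximum(
        np.tensordot(alpha, leaf.data[0], axes=([0], [0])), 0.0
    )
    zoom = [t / s for t, s in zip(data.shape, raw.shape)]
    heat = ndimage.zoom(raw, zoom, order=1, mode="nearest")
    heat = np.maximum(heat, 0.0)
    return ActivationMap(
        heatmap=heat.astype(np.float32),
        raw=raw.astype(np.float32),
        class_set=class_set,
        class_index=class_index,
        alpha=alpha.astype(np.float32),
        z=z_count,
    )


def overlay(act: ActivationMap, crop: GHCrop | np.ndarray,
            alpha_blend: float = 0.5, cmap: str = "jet") -> np.ndarray:
    """Coronal/axial/sagittal mid-slice montage of the heatmap over the CT.

    Returns an (H, 3W, 3) float RGB array in [0, 1]; an all-zero map yields
    pure grayscale.
    """
    import matplotlib.cm as mcm

    data = crop.data if isinstance(crop, GHCrop) else np.asarray(crop)
    if data.shape != act.heatmap.shape:
        raise ValueError("crop and heatmap shapes differ")
    span = act.heatmap.max() - act.heatmap.min()
    heat = (act.heatmap - act.heatmap.min()) / span if span > 0 else (
        np.zeros_like(act.heatmap) if act.heatmap.max() == 0
        else np.ones_like(act.heatmap)
    )
    g_span = np.ptp(data)
    gray = (data - data.min()) / g_span if g_span > 0 else np.zeros_like(data)
    colormap = mcm.get_cmap(cmap) if hasattr(mcm, "get_cmap") else (
        __import__("matplotlib").colormaps[cmap]
    )
    mids = [s // 2 for s in data.shape]
    panes = []
    for axis in (0, 1, 2):  # axial, coronal, sagittal mid-slices
        sl = [slice(None)] * 3
        sl[axis] = mids[axis]
        g = gray[tuple(sl)]
        h = heat[tuple(sl)]
        rgb_heat = colormap(h)[..., :3]
        blend = alpha_blend * h[..., None]
        panes.append((1.0 - blend) * g[..., None] + blend * rgb_heat)
    height = max(p.shape[0] for p in panes)
    panes = [np.pad(p, ((0, height - p.shape[0]), (0, 0), (0, 0)))
             for p in panes]
    return np.clip(np.concatenate(panes, axis=1), 0.0, 1.0)


def localization_score(act: ActivationMap, region_mask: np.ndarray,
                       top_fraction: float = 0.1,
                       dilate_iters: int = 0) -> LocalizationScore:
    """Fraction of top-decile activation mass inside a stated region."""
    region = np.asarray(region_mask, dtype=bool)
    if region.shape != act.heatmap.shape:
        raise ValueError("region and heatmap shapes differ")
    if not region.any():
        raise ValueError("region mask is empty")
    if dilate_iters > 0:
        region = ndimage.binary_dilation(region, iterations=dilate_iters)
    heat = act.heatmap
    thresh = np.quantile(heat, 1.0 - top_fraction)
    sel = heat >= thresh
    total = heat[sel].sum()
    if total == 0:
        warnings.warn("activation map carries no mass; score set to 0")
        return LocalizationScore(0.0)
    inside = heat[sel & region].sum()
    return LocalizationScore(float(inside / total))
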