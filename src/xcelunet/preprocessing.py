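"""Volume standardization and construction of the two training corpora.

``DSeg`` holds label-cropped, patched full-shoulder volumes for the
segmentation stage; ``DCls`` holds fixed-size crops centred on the
glenohumeral joint (plus their sagittal mirrors) for the clinical-staging
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ConditionLabels, CTVolume, GHCrop, LabelVolume

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "PatchSet",
    "hu_normalize",
    "crop_to_labels",
    "extract_patches",
    "stitch_patches",
    "extract_gh_crop",
    "sagittal_flip",
    "load_nifti",
    "save_nifti",
]

HU_MIN = -1024.0  # air
HU_MAX = 2500.0   # dense cortical bone
_HU_RANGE = HU_MAX - HU_MIN  # 3524


@dataclass
class PatchSet:
    """Equally spaced overlapping sub-volumes covering a (padded) volume."""

    patches: list[tuple[np.ndarray, tuple[int, int, int]]]
    patch_edge: int
    source_shape: tuple[int, int, int]
    pad: tuple[int, int, int] = (0, 0, 0)  # leading pad applied per axis


def hu_normalize(vol: CTVolume) -> CTVolume:
    """Clip to [-1024, 2500] HU, shift positive and scale into [0, 1]."""
    if vol.units == "normalized":
        return CTVolume(vol.data.copy(), vol.spacing_mm, units="normalized")
    if not np.isfinite(vol.data).all():
        raise ValueError("volume contains non-finite voxels")
    data = (np.clip(vol.data, HU_MIN, HU_MAX) - HU_MIN) / _HU_RANGE
    return CTVolume(data.astype(np.float32), vol.spacing_mm, units="normalized")


def crop_to_labels(
    vol: CTVolume, labels: LabelVolume, margin: int = 0
) -> tuple[CTVolume, LabelVolume, tuple[int, int, int]]:
    """Tight bounding-box crop around nonzero labels (optional margin).

    Returns the cropped CT, cropped labels, and the crop offset (the index of
    the cropped origin in the source volume) for inverse mapping.
    """
    if vol.data.shape != labels.data.shape:
        raise ValueError("CT and label shapes differ")
    nz = np.nonzero(labels.data)
    if nz[0].size == 0:
        raise ValueError("label volume is empty: nothing to crop to")
    lo = [max(0, int(idx.min()) - margin) for idx in nz]
    hi = [min(s, int(idx.max()) + 1 + margin)
          for idx, s in zip(nz, labels.data.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return (
        CTVolume(vol.data[sl], vol.spacing_mm, units=vol.units),
        LabelVolume(labels.data[sl], labels.spacing_mm),
        tuple(lo),
    )


def _axis_offsets(length: int, edge: int, min_overlap_frac: float) -> list[int]:
    if length == edge:
        return [0]
    max_stride = edge * (1.0 - min_overlap_frac)
    n_windows = int(np.ceil((length - edge) / max_stride)) + 1
    return [int(round(v)) for v in np.linspace(0, length - edge, n_windows)]


def extract_patches(
    vol: CTVolume | LabelVolume | np.ndarray,
    patch_edge: int = 160,
    min_overlap_frac: float = 0.25,
) -> PatchSet:
    """Cover the volume with the minimal equally spaced overlapping windows.

    Per axis the number of windows is the smallest achieving neighbour
    overlap of at least ``min_overlap_frac * patch_edge``; axes shorter than
    the patch edge are first zero-padded symmetrically.
    """
    if patch_edge <= 0:
        raise ValueError("patch_edge must be positive")
    data = vol.data if isinstance(vol, (CTVolume, LabelVolume)) else np.asarray(vol)
    pad = []
    for s in data.shape:
        deficit = max(0, patch_edge - s)
        pad.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pad):
        data = np.pad(data, pad)
    offsets = [
        _axis_offsets(s, patch_edge, min_overlap_frac) for s in data.shape
    ]
    patches = []
    for o0 in offsets[0]:
        for o1 in offsets[1]:
            for o2 in offsets[2]:
                sub = data[o0:o0 + patch_edge, o1:o1 + patch_edge,
                           o2:o2 + patch_edge]
                patches.append((sub, (o0, o1, o2)))
    return PatchSet(
        patches=patches,
        patch_edge=patch_edge,
        source_shape=data.shape,
        pad=tuple(p[0] for p in pad),
    )


def stitch_patches(pred_patches: PatchSet, n_classes: int | None = None,
                   renormalize: bool = True) -> np.ndarray:
    """Average per-class probability patches back into one volume.

    Every patch holds ``(C, e, e, e)`` probabilities at its recorded offset;
    overlaps are arithmetic means, optionally renormalized so the per-voxel
    class probabilities sum to one.
    """
    e = pred_patches.patch_edge
    first = pred_patches.patches[0][0]
    c = first.shape[0] if n_classes is None else n_classes
    shape = pred_patches.source_shape
    acc = np.zeros((c,) + tuple(shape), dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int32)
    for patch, (o0, o1, o2) in pred_patches.patches:
        if (o0 < 0 or o1 < 0 or o2 < 0 or o0 + e > shape[0]
                or o1 + e > shape[1] or o2 + e > shape[2]):
            raise ValueError(f"patch offset {(o0, o1, o2)} outside source")
        acc[:, o0:o0 + e, o1:o1 + e, o2:o2 + e] += patch
        cnt[o0:o0 + e, o1:o1 + e, o2:o2 + e] += 1
    if (cnt == 0).any():
        raise ValueError("patch set does not cover the volume")
    out = acc / cnt
    if renormalize:
        out = out / out.sum(axis=0, keepdims=True)
    p0, p1, p2 = pred_patches.pad
    return out[:, p0:, p1:, p2:] if any(pred_patches.pad) else out


def _fit_sphere(points: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre through boundary points (rows, mm)."""
    a = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def extract_gh_crop(
    vol: CTVolume,
    labels: LabelVolume,
    crop_edge: int = 80,
    truth: ConditionLabels | None = None,
) -> GHCrop:
    """Crop a ``crop_edge``^3 window centred on the glenohumeral joint.

    The humeral-head centre comes from a least-squares sphere fit to the
    boundary voxels of the superior third of the humerus label; the glenoid
    point is the scapula voxel closest to that centre; the crop is centred at
    the midpoint of the two, zero-padded where it leaves the volume.
    """
    data = labels.data
    if not (data == 1).any() or not (data == 2).any():
        raise ValueError("GH crop needs both humerus (1) and scapula (2) labels")
    sp = np.asarray(labels.spacing_mm)

    hum = data == 1
    z_idx = np.nonzero(hum.any(axis=(1, 2)))[0]
    z_top = z_idx.max()
    z_cut = z_top - max(1, (z_top - z_idx.min() + 1) // 3)
    band = np.zeros_like(hum)
    band[z_cut:] = hum[z_cut:]
    boundary = band & ~ndimage.binary_erosion(hum)
    pts = np.argwhere(boundary) * sp
    try:
        if len(pts) < 10:
            raise np.linalg.LinAlgError
        center_mm = _fit_sphere(pts)
        if not np.isfinite(center_mm).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("sphere fit degenerate; falling back to humerus centroid")
        center_mm = np.argwhere(hum).mean(axis=0) * sp

    scap_pts = np.argwhere(data == 2) * sp
    glenoid_mm = scap_pts[np.argmin(((scap_pts - center_mm) ** 2).sum(axis=1))]
    mid_vox = np.round((center_mm + glenoid_mm) / (2.0 * sp)).astype(int)

    half = crop_edge // 2
    out = np.zeros((crop_edge,) * 3, dtype=vol.data.dtype)
    src_lo = mid_vox - half
    for_axes = []
    for ax in range(3):
        s0 = max(0, src_lo[ax])
        s1 = min(vol.data.shape[ax], src_lo[ax] + crop_edge)
        d0 = s0 - src_lo[ax]
        for_axes.append((slice(s0, s1), slice(d0, d0 + (s1 - s0))))
    out[for_axes[0][1], for_axes[1][1], for_axes[2][1]] = vol.data[
        for_axes[0][0], for_axes[1][0], for_axes[2][0]
    ]
    return GHCrop(out, vol.spacing_mm, labels=truth,
                  center_voxel=tuple(int(v) for v in mid_vox))


def sagittal_flip(crop: GHCrop) -> GHCrop:
    """Mirror the crop along the left-right axis; condition labels unchanged."""
    return GHCrop(crop.data[:, :, ::-1].copy(), crop.spacing_mm,
                  labels=crop.labels, center_voxel=crop.center_voxel)


# -- training corpora -------------------------------------------------------

def build_dseg(phantoms, patch_edge: int | None = None):
    """Segmentation corpus from phantoms: normalized CT + labels, optionally
    label-cropped and patched into ``patch_edge`` sub-volumes."""
    corpus = []
    for ph in phantoms:
        vol = hu_normalize(ph.ct)
        labels = ph.labels
        if patch_edge is not None:
            vol_c, lab_c, _ = crop_to_labels(vol, labels)
            vp = extract_patches(vol_c, patch_edge=patch_edge)
            lp = extract_patches(lab_c, patch_edge=patch_edge)
            for (v, _), (l, _) in zip(vp.patches, lp.patches):
                corpus.append((
                    CTVolume(v, vol.spacing_mm, units="normalized"),
                    LabelVolume(l, labels.spacing_mm),
                ))
        else:
            corpus.append((vol, labels))
    return corpus


def build_dcls(phantoms, crop_edge: int = 80, augment_flips: bool = True
               ) -> list[GHCrop]:
    """Classification corpus: GH-centred crops (and their sagittal mirrors,
    which leave the condition labels unchanged)."""
    crops = []
    for ph in phantoms:
        vol = hu_normalize(ph.ct)
        crop = extract_gh_crop(vol, ph.labels, crop_edge=crop_edge,
                               truth=ph.truth)
        crops.append(crop)
        if augment_flips:
            crops.append(sagittal_flip(crop))
    return crops


# -- NIfTI IO ---------------------------------------------------------------

def load_nifti(path: str | Path, as_labels: bool = False):
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    arr = np.asanyarray(img.dataobj)
    if as_labels:
        return LabelVolume(arr.astype(np.int16), spacing)
    return CTVolume(arr.astype(np.float32), spacing, units="HU")


def save_nifti(vol: CTVolume | LabelVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))
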