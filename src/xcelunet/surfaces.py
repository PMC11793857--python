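"""Surface reconstruction and evaluation of segmentation outputs.

Meshes come from marching cubes on binary class masks; reconstruction error
is the one-way vertex distance from each target-mesh vertex to its nearest
predicted-mesh vertex, summarized as RMSE and Hausdorff (maximum) distance.
Voxel overlap is reported per class as Dice, precision and recall.  The
osteophyte-size auto-labeler grades the maximum distance between the
morphologic and osteophyte-cleared humerus surfaces against the 3/7 mm
class thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .core import LabelVolume, SurfaceMesh

__all__ = [
    "DistanceReport",
    "OverlapReport",
    "labels_to_mesh",
    "one_way_distances",
    "overlap_metrics",
    "os_autolabel",
    "load_mesh",
    "save_mesh",
]


@dataclass
class DistanceReport:
    distances_mm: np.ndarray
    rmse: float
    hausdorff: float
    mean: float


@dataclass
class OverlapReport:
    dice: dict[int, float | None]
    precision: dict[int, float | None]
    recall: dict[int, float | None]


def labels_to_mesh(labels: LabelVolume | np.ndarray, class_id: int,
                   spacing_mm: tuple[float, float, float] | None = None
                   ) -> SurfaceMesh:
    """Marching-cubes surface (iso-level 0.5) of one class; largest
    connected surface component kept; vertices in mm."""
    if isinstance(labels, LabelVolume):
        data, spacing = labels.data, labels.spacing_mm
    else:
        data = np.asarray(labels)
        spacing = (1.0,) * 3 if spacing_mm is None else tuple(spacing_mm)
    mask = data == class_id
    if not mask.any():
        raise ValueError(f"class {class_id} absent from label volume")
    verts, faces, _, _ = marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=tuple(spacing)
    )
    verts = verts + 0.5 * np.asarray(spacing)  # voxel-centre world frame
    mesh = _largest_component(verts, faces)
    return mesh


def _largest_component(verts: np.ndarray, faces: np.ndarray) -> SurfaceMesh:
    import trimesh

    tm = trimesh.Trimesh(verts, faces, process=False)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: len(p.vertices))
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def one_way_distances(target: SurfaceMesh, predicted: SurfaceMesh,
                      mode: str = "vertex") -> DistanceReport:
    """Distance from every target vertex to the predicted surface.

    ``mode='vertex'`` (default) measures to the nearest predicted *vertex*;
    ``mode='surface'`` measures to the nearest point on a predicted triangle.
    The direction is target -> predicted only.
    """
    if len(target.vertices) == 0 or len(predicted.vertices) == 0:
        raise ValueError("empty mesh")
    if mode == "vertex":
        tree = cKDTree(predicted.vertices)
        d, _ = tree.query(target.vertices)
    elif mode == "surface":
        import trimesh

        tm = trimesh.Trimesh(predicted.vertices, predicted.faces,
                             process=False)
        _, d, _ = trimesh.proximity.closest_point(tm, target.vertices)
    else:
        raise ValueError("mode must be 'vertex' or 'surface'")
    d = np.asarray(d, dtype=np.float64)
    return DistanceReport(
        distances_mm=d,
        rmse=float(np.sqrt((d**2).mean())),
        hausdorff=float(d.max()),
        mean=float(d.mean()),
    )


def overlap_metrics(pred_labels: LabelVolume | np.ndarray,
                    target_labels: LabelVolume | np.ndarray,
                    classes: tuple[int, ...] = (1, 2)) -> OverlapReport:
    """Per-class Dice = 2TP/(2TP+FP+FN), precision, recall; a class absent
    from both volumes is reported as missing (None)."""
    pred = pred_labels.data if isinstance(pred_labels, LabelVolume) else np.asarray(pred_labels)
    tgt = (target_labels.data if isinstance(target_labels, LabelVolume)
           else np.asarray(target_labels))
    if pred.shape != tgt.shape:
        raise ValueError("prediction and target shapes differ")
    dice, prec, rec = {}, {}, {}
    for k in classes:
        p, t = pred == k, tgt == k
        tp = int((p & t).sum())
        fp = int((p & ~t).sum())
        fn = int((~p & t).sum())
        if tp + fp + fn == 0:
            dice[k] = prec[k] = rec[k] = None
            continue
        dice[k] = 2 * tp / (2 * tp + fp + fn)
        prec[k] = tp / (tp + fp) if tp + fp else 0.0
        rec[k] = tp / (tp + fn) if tp + fn else 0.0
    return OverlapReport(dice=dice, precision=prec, recall=rec)


def os_autolabel(morph: SurfaceMesh, cleared: SurfaceMesh
                 ) -> tuple[int, float]:
    """Osteophyte-size grade from the paired humerus surfaces.

    The protrusion ``s_o`` is the maximum one-way distance from the
    morphologic mesh (which carries osteophytes) to the cleared mesh;
    grades: ``s_o < 3`` mm -> 0, ``3 <= s_o <= 7`` -> 1, ``> 7`` -> 2.
    Returns ``(grade, s_o)``.
    """
    report = one_way_distances(morph, cleared)
    s_o = report.hausdorff
    if s_o < 3.0:
        grade = 0
    elif s_o <= 7.0:
        grade = 1
    else:
        grade = 2
    return grade, float(s_o)


# -- mesh IO ----------------------------------------------------------------

def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    import trimesh

    trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(str(path))


def load_mesh(path: str | Path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), force="mesh", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
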