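"""Shared domain containers for volumes, crops, meshes and condition labels.

Conventions used throughout the package:

* volume axis order is ``(axial, coronal, sagittal)``: axis 0 runs
  caudo-cranially (larger index = more cranial), axis 1 antero-posteriorly,
  axis 2 medio-laterally (the sagittal/left-right axis);
* voxel indices are 0-based, crop intervals half-open;
* a voxel with index ``i`` has its centre at ``(i + 0.5) * spacing_mm``,
  so mirroring the grid mirrors world coordinates exactly;
* mesh vertices are in millimetres in that same world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CTVolume",
    "LabelVolume",
    "ConditionLabels",
    "GHCrop",
    "SurfaceMesh",
]


@dataclass
class CTVolume:
    """3D scalar grid with isotropic-per-axis physical voxel spacing."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    units: str = "HU"  # "HU" or "normalized"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CTVolume.data must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")


@dataclass
class LabelVolume:
    """Integer grid over {0 background, 1 humerus, 2 scapula}."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume.data must be 3D")
        if not np.isin(np.unique(self.data), [0, 1, 2]).all():
            raise ValueError("labels must lie in {0, 1, 2}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)


@dataclass(frozen=True)
class ConditionLabels:
    """Severity grades of the three glenohumeral conditions.

    ``os_grade``: osteophyte size class (0: <3 mm, 1: 3-7 mm, 2: >7 mm,
    Samilson-Prieto style).  ``js_grade``: joint-space class (0 physiological,
    1 narrowed, 2 non-detectable).  ``hsa``: humeroscapular alignment
    (0 concentric, 1 eccentric).
    """

    os_grade: int
    js_grade: int
    hsa: int

    def __post_init__(self):
        if self.os_grade not in (0, 1, 2):
            raise ValueError("os_grade must be 0, 1 or 2")
        if self.js_grade not in (0, 1, 2):
            raise ValueError("js_grade must be 0, 1 or 2")
        if self.hsa not in (0, 1):
            raise ValueError("hsa must be 0 or 1")


@dataclass
class GHCrop:
    """Fixed-size glenohumeral-joint-centred normalized sub-volume."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    labels: ConditionLabels | None = None
    center_voxel: tuple[int, int, int] | None = None


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices in mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if len(self.vertices) < 4:
            raise ValueError("a surface needs at least 4 vertices")
        if not np.isfinite(self.vertices).all():
            raise ValueError("non-finite vertex coordinates")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a missing vertex")
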