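"""Seeded generator of shoulder phantoms with known ground truth.

Each phantom is built from analytic signed-distance fields (SDFs): a
spherical humeral head continued by a cylindrical shaft, optional
spherical-cap osteophytes fused to the infero-lateral head, and a scapula
made of a concave glenoid shell (concentric with the nominal head position)
plus a thin medial plate.  The SDFs are voxelized into a CT-like intensity
volume (bone vs soft-tissue HU with partial-volume blending and optional
noise) and a {0, 1, 2} label volume, and iso-surfaced at level 0 into
ground-truth meshes with sub-voxel accuracy.

Two humerus surfaces are produced per phantom — the "morphologic" one with
osteophytes and an "osteophyte-cleared" one without — mirroring the paired
reference surfaces used for automated osteophyte-size labelling.  Condition
grades follow the generating parameters:

* osteophyte size (OS): protrusion < 3 mm -> 0, 3-7 mm -> 1, > 7 mm -> 2;
* joint space (JS): gap >= 3 mm -> 0 (physiological), >= 1 voxel -> 1
  (narrowed), below one voxel -> 2 (non-detectable);
* alignment (HSA): eccentric (1) iff the cranial head shift is >= 2 mm.

Osteophyte caps are placed so their apex sits exactly ``osteophyte_height_mm``
above the unperturbed head sphere, hence the morph-to-cleared maximum surface
distance equals the generating height by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.measure import marching_cubes

from .core import ConditionLabels, CTVolume, LabelVolume, SurfaceMesh

__all__ = [
    "GeometryError",
    "PhantomParams",
    "Phantom",
    "generate_phantom",
    "generate_dataset",
    "os_grade_from_height",
    "js_grade_from_gap",
    "hsa_from_shift",
    "save_phantom",
    "TABLE_OS_MIX",
    "TABLE_JS_MIX",
    "TABLE_HSA_MIX",
]

# Observed class frequencies of the clinical grading tasks, used as default
# sampling mixes so generated datasets match the study's class balance.
TABLE_OS_MIX = (0.311, 0.361, 0.328)
TABLE_JS_MIX = (0.382, 0.272, 0.346)
TABLE_HSA_MIX = (0.561, 0.439)

OS_THRESHOLDS_MM = (3.0, 7.0)
JS_PHYSIOLOGICAL_MM = 3.0
HSA_ECCENTRIC_MM = 2.0


class GeometryError(ValueError):
    """The requested anatomy does not fit inside the voxel grid."""


def os_grade_from_height(height_mm: float, count: int = 1) -> int:
    """Samilson-Prieto-style size class from the osteophyte protrusion."""
    if count == 0 or height_mm < OS_THRESHOLDS_MM[0]:
        return 0
    if height_mm <= OS_THRESHOLDS_MM[1]:
        return 1
    return 2


def js_grade_from_gap(gap_mm: float, spacing_mm: float) -> int:
    """Joint-space class; a gap below one voxel is non-detectable."""
    if gap_mm >= JS_PHYSIOLOGICAL_MM:
        return 0
    if gap_mm >= spacing_mm:
        return 1
    return 2


def hsa_from_shift(shift_mm: float) -> int:
    return int(shift_mm >= HSA_ECCENTRIC_MM)


@dataclass(frozen=True)
class PhantomParams:
    """Generating parameters of one shoulder phantom (lengths in mm)."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.0
    head_radius_mm: float = 20.0
    osteophyte_height_mm: float = 0.0
    osteophyte_count: int = 0
    joint_gap_mm: float = 4.0
    eccentric_shift_mm: float = 0.0
    bone_hu: float = 1200.0
    tissue_hu: float = 40.0
    noise_sd_hu: float = 20.0
    side: str = "right"
    glenoid_thickness_mm: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.spacing_mm <= 0 or self.head_radius_mm <= 0:
            raise ValueError("spacing and head radius must be positive")
        if min(self.osteophyte_height_mm, self.joint_gap_mm,
               self.eccentric_shift_mm) < 0:
            raise ValueError("heights, gaps and shifts must be >= 0")
        if self.osteophyte_count < 0:
            raise ValueError("osteophyte_count must be >= 0")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")


@dataclass
class Phantom:
    ct: CTVolume
    labels: LabelVolume
    humerus_morph_mesh: SurfaceMesh
    humerus_cleared_mesh: SurfaceMesh
    scapula_mesh: SurfaceMesh
    truth: ConditionLabels
    params: PhantomParams = field(repr=False, default=None)


# ----------------------------------------------------------------------------
# analytic geometry
# ----------------------------------------------------------------------------

def _geometry(params: PhantomParams):
    """World-frame centres and directions (mm) of the phantom anatomy."""
    sp = params.spacing_mm
    extent = np.array(params.grid_shape, dtype=np.float64) * sp
    g = 1.0 if params.side == "right" else -1.0  # medial direction sign on axis 2
    r = params.head_radius_mm
    # nominal head centre: cranial on axis 0, lateral on axis 2 to leave room
    # for the glenoid medially
    c0 = np.array([0.58 * extent[0], 0.5 * extent[1],
                   0.5 * extent[2] - g * 0.10 * extent[2]])
    head = c0 + np.array([params.eccentric_shift_mm, 0.0, 0.0])
    medial = np.array([0.0, 0.0, g])
    lateral = -medial
    cranial = np.array([1.0, 0.0, 0.0])
    return c0, head, medial, lateral, cranial, extent


def _osteophyte_dirs(count: int, medial: np.ndarray, cranial: np.ndarray
                     ) -> np.ndarray:
    """Unit directions on the infero-lateral head, symmetric about axis 1."""
    if count == 0:
        return np.zeros((0, 3))
    theta = np.deg2rad(125.0)  # polar angle from the cranial axis -> inferior
    azimuths = np.deg2rad(np.linspace(-45.0, 45.0, count))
    anterior = np.array([0.0, 1.0, 0.0])
    dirs = []
    for phi in azimuths:
        d = (np.cos(theta) * cranial
             + np.sin(theta) * (np.cos(phi) * (-medial) + np.sin(phi) * anterior))
        dirs.append(d / np.linalg.norm(d))
    return np.array(dirs)


def _check_fit(params: PhantomParams) -> None:
    c0, head, medial, lateral, cranial, extent = _geometry(params)
    r = params.head_radius_mm
    margin = params.spacing_mm
    reach_cranial = head[0] + r
    reach_medial = (c0 + medial * (r + params.joint_gap_mm
                                   + params.glenoid_thickness_mm))
    # true osteophyte tip positions (caps point infero-laterally)
    dirs = _osteophyte_dirs(params.osteophyte_count, medial, cranial)
    tip = r + params.osteophyte_height_mm
    if len(dirs):
        lat_extent = max(abs((head + tip * u)[2] - c0[2]) for u in dirs)
        reach_lateral = c0 + lateral * lat_extent
    else:
        reach_lateral = c0 + lateral * r
    for point, axis in ((reach_medial, 2), (reach_lateral, 2)):
        if not (margin <= point[axis] <= extent[axis] - margin):
            raise GeometryError(
                f"grid {params.grid_shape} too small: anatomy reaches "
                f"{point[axis]:.1f} mm on axis {axis} (extent {extent[axis]:.1f})"
            )
    if reach_cranial > extent[0] - margin:
        raise GeometryError(
            f"grid too small cranially: head top at {reach_cranial:.1f} mm "
            f"exceeds {extent[0] - margin:.1f}"
        )


def _sdfs(params: PhantomParams, coords: tuple[np.ndarray, ...]):
    """Return (morph, cleared, scapula) signed-distance fields (negative inside)."""
    c0, head, medial, lateral, cranial, _ = _geometry(params)
    r = params.head_radius_mm
    z, y, x = coords  # broadcastable world-coordinate grids (mm)

    def sphere(c, radius):
        return np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) - radius

    head_sdf = sphere(head, r)
    # shaft: cylinder along the caudal axis, capped at the head centre
    radial = np.sqrt((y - head[1]) ** 2 + (x - head[2]) ** 2)
    shaft_sdf = np.maximum(radial - 0.55 * r, z - head[0])
    cleared = np.minimum(head_sdf, shaft_sdf)

    morph = cleared
    if params.osteophyte_count and params.osteophyte_height_mm > 0:
        s_o = params.osteophyte_height_mm
        r_b = max(2.0, 0.75 * s_o)  # cap sphere radius; > s_o/2 keeps it fused
        for u in _osteophyte_dirs(params.osteophyte_count, medial, cranial):
            c_b = head + u * (r - r_b + s_o)
            morph = np.minimum(morph, sphere(c_b, r_b))

    # glenoid: concave spherical shell concentric with the nominal head
    # position, restricted to a cone about the medial axis, plus a plate body
    rad0 = np.sqrt((z - c0[0]) ** 2 + (y - c0[1]) ** 2 + (x - c0[2]) ** 2)
    inner = r + params.joint_gap_mm
    outer = inner + params.glenoid_thickness_mm
    shell = np.maximum(rad0 - outer, inner - rad0)
    q_med = (x - c0[2]) * medial[2]
    d_perp = np.sqrt((z - c0[0]) ** 2 + (y - c0[1]) ** 2)
    half_angle = np.deg2rad(50.0)
    cone = d_perp * np.cos(half_angle) - q_med * np.sin(half_angle)
    glenoid = np.maximum(shell, cone)
    plate = np.maximum(
        np.maximum(np.abs(y - c0[1]) - 2.0, (inner + 1.0) - q_med),
        np.abs(z - c0[0]) - 0.9 * r,
    )
    scapula = np.minimum(glenoid, plate)
    return morph, cleared, scapula


def _mesh_from_sdf(sdf: np.ndarray, spacing: float) -> SurfaceMesh:
    verts, faces, _, _ = marching_cubes(sdf, level=0.0,
                                        spacing=(spacing,) * 3)
    return SurfaceMesh(vertices=verts + 0.5 * spacing, faces=faces)


def generate_phantom(params: PhantomParams) -> Phantom:
    """Build one phantom; identical parameters give bit-identical output."""
    _check_fit(params)
    sp = params.spacing_mm
    shape = tuple(int(s) for s in params.grid_shape)
    axes = [((np.arange(n) + 0.5) * sp).astype(np.float64) for n in shape]
    coords = (axes[0][:, None, None], axes[1][None, :, None],
              axes[2][None, None, :])
    morph_sdf, cleared_sdf, scap_sdf = _sdfs(params, coords)

    humerus = morph_sdf <= 0.0
    scapula = (scap_sdf <= 0.0) & ~humerus
    labels = np.zeros(shape, dtype=np.int16)
    labels[humerus] = 1
    labels[scapula] = 2

    # CT intensity with one-voxel partial-volume blending at bone surfaces
    union_sdf = np.minimum(morph_sdf, scap_sdf)
    occupancy = np.clip(0.5 - union_sdf / sp, 0.0, 1.0)
    ct = params.tissue_hu + (params.bone_hu - params.tissue_hu) * occupancy
    if params.noise_sd_hu > 0:
        rng = np.random.default_rng(params.seed)
        ct = ct + rng.normal(0.0, params.noise_sd_hu, size=shape)
    ct = ct.astype(np.float32)

    truth = ConditionLabels(
        os_grade=os_grade_from_height(params.osteophyte_height_mm,
                                      params.osteophyte_count),
        js_grade=js_grade_from_gap(params.joint_gap_mm, sp),
        hsa=hsa_from_shift(params.eccentric_shift_mm),
    )
    morph_mesh = _mesh_from_sdf(morph_sdf, sp)
    no_bumps = (params.osteophyte_count == 0
                or params.osteophyte_height_mm == 0)
    cleared_mesh = morph_mesh if no_bumps else _mesh_from_sdf(cleared_sdf, sp)
    return Phantom(
        ct=CTVolume(ct, (sp,) * 3, units="HU"),
        labels=LabelVolume(labels, (sp,) * 3),
        humerus_morph_mesh=morph_mesh,
        humerus_cleared_mesh=cleared_mesh,
        scapula_mesh=_mesh_from_sdf(scap_sdf, sp),
        truth=truth,
        params=params,
    )


# ----------------------------------------------------------------------------
# dataset sampling
# ----------------------------------------------------------------------------

def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items to weights (sum == n)."""
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return counts

# per-grade generating ranges, kept >= 1 mm clear of the 3/7 mm OS class
# boundaries so auto-labelling from meshes is unambiguous
_OS_RANGES = ((0.0, 2.0), (4.0, 6.0), (8.0, 11.0))
_JS_RANGES = ((3.5, 5.5), (1.25, 2.5), (0.0, 0.45))
_HSA_RANGES = ((0.0, 0.0), (2.5, 4.0))


def generate_dataset(
    n: int,
    class_mix: tuple[float, float, float] | None = None,
    seed: int = 0,
    *,
    js_mix: tuple[float, float, float] = TABLE_JS_MIX,
    hsa_mix: tuple[float, float] = TABLE_HSA_MIX,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    spacing_mm: float = 1.0,
    head_radius_mm: float | None = None,
    noise_sd_hu: float = 20.0,
) -> list[Phantom]:
    """Sample ``n`` phantoms with OS grades apportioned to ``class_mix``.

    OS-grade counts use largest-remainder apportionment of ``n * class_mix``
    (exact stratification for uniform mixes, within one case of the expected
    count otherwise); JS and HSA grades are drawn per phantom from their
    mixes.  Everything is reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(TABLE_OS_MIX if class_mix is None else class_mix,
                     dtype=float)
    if mix.size == 0 or mix.sum() <= 0 or (mix < 0).any():
        raise ValueError("class_mix must be non-negative with positive sum")
    rng = np.random.default_rng(seed)
    counts = _apportion(n, mix)
    os_grades = np.repeat(np.arange(len(mix)), counts)
    rng.shuffle(os_grades)

    if head_radius_mm is None:
        head_radius_mm = 0.19 * min(grid_shape) * spacing_mm

    phantoms = []
    for i, os_grade in enumerate(os_grades):
        js_grade = int(rng.choice(len(js_mix), p=np.asarray(js_mix) / sum(js_mix)))
        hsa = int(rng.choice(2, p=np.asarray(hsa_mix) / sum(hsa_mix)))
        lo, hi = _OS_RANGES[os_grade]
        s_o = float(rng.uniform(lo, hi))
        count = 0 if (os_grade == 0 and s_o < 1.0) else int(rng.integers(1, 4))
        lo, hi = _JS_RANGES[js_grade]
        gap = float(rng.uniform(lo, min(hi, 0.45 * spacing_mm)
                                if js_grade == 2 else hi))
        lo, hi = _HSA_RANGES[hsa]
        shift = float(rng.uniform(lo, hi)) if hi > lo else lo
        radius = float(head_radius_mm * rng.uniform(0.9, 1.1))
        base = dict(
            grid_shape=tuple(grid_shape),
            spacing_mm=spacing_mm,
            osteophyte_height_mm=s_o,
            osteophyte_count=count,
            joint_gap_mm=gap,
            eccentric_shift_mm=shift,
            noise_sd_hu=noise_sd_hu,
            side="right" if rng.random() < 0.5 else "left",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # large osteophytes on small grids: shrink the head until it fits
        for attempt in range(6):
            try:
                phantoms.append(generate_phantom(
                    PhantomParams(head_radius_mm=radius, **base)
                ))
                break
            except GeometryError:
                if attempt == 5:
                    raise
                radius *= 0.88
    return phantoms


# ----------------------------------------------------------------------------
# on-disk layout
# ----------------------------------------------------------------------------

def save_phantom(phantom: Phantom, out_dir: str | Path, stem: str) -> dict:
    """Write ct/labels as NIfTI, meshes as PLY, truth as one CSV row."""
    import nibabel as nib
    import trimesh

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.ct.spacing_mm) + [1.0])
    paths = {}
    for tag, arr in (("ct", phantom.ct.data.astype(np.float32)),
                     ("labels", phantom.labels.data.astype(np.int16))):
        p = out / f"{stem}_{tag}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), p)
        paths[tag] = p
    for tag, mesh in (("humerus_morph", phantom.humerus_morph_mesh),
                      ("humerus_cleared", phantom.humerus_cleared_mesh),
                      ("scapula", phantom.scapula_mesh)):
        p = out / f"{stem}_{tag}.ply"
        trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(p)
        paths[tag] = p
    row = out / f"{stem}_truth.csv"
    with open(row, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "os", "js", "hsa"])
        writer.writerow([stem, phantom.truth.os_grade,
                         phantom.truth.js_grade, phantom.truth.hsa])
    paths["truth"] = row
    return paths
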