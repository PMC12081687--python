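"""Lesion morphometrics.

Connected components (26-connectivity), volume, Wadell sphericity,
centroid, Euclidean distance to the gray-white matter interface, and
atlas region membership.  These are the per-lesion statistics every
downstream analysis consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .grid import Grid

__all__ = [
    "Lesion",
    "InterfaceDistanceMap",
    "extract_lesions",
    "compute_sphericity",
    "interface_distance_map",
    "lesion_interface_distance",
    "assign_membership",
    "fill_morphometrics",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"

#: background-centroid rescue radius for atlas membership, in mm
MEMBERSHIP_RESCUE_MM = 5.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)

#: staircase inflation of marching-cubes area on binary volumes, calibrated
#: on digitized balls (ratio mesh/analytic area is 1.0946-1.0953 for radii
#: 3-10 voxels and 1.087 for a 2:1 ellipsoid); dividing by this constant
#: makes mesh areas track the continuum limit within ~1% for convex bodies
_MC_STAIRCASE_FACTOR = 1.095


@dataclass
class Lesion:
    """One connected metastasis: a voxel set plus derived morphometrics."""

    voxels: np.ndarray  # (n, 3) int voxel indices, one 26-connected component
    volume_cc: float
    patient_id: str = ""
    lesion_id: str = ""
    sphericity: float = float("nan")
    centroid_mm: np.ndarray | None = None
    interface_distance_mm: float = float("nan")
    memberships: dict[str, object] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def centroid(self, grid: Grid) -> np.ndarray:
        """Unweighted mean of voxel centers, in physical mm."""
        return grid.voxel_centers_mm(self.voxels).mean(axis=0)


@dataclass(frozen=True)
class InterfaceDistanceMap:
    """Euclidean distance (mm) to the gray-white interface voxel set."""

    distance_mm: np.ndarray
    interface_voxels: np.ndarray  # boolean mask
    grid: Grid


def extract_lesions(mask: np.ndarray, grid: Grid) -> list[Lesion]:
    """Split a binary mask into 26-connected components.

    Returns one :class:`Lesion` per component with voxel set and volume
    filled; the remaining morphometrics are computed by
    :func:`fill_morphometrics`.  An empty mask yields an empty list.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    labeled, n = ndimage.label(mask, structure=_STRUCT_26)
    lesions = []
    for comp in range(1, n + 1):
        vox = np.argwhere(labeled == comp)
        lesions.append(
            Lesion(voxels=vox, volume_cc=vox.shape[0] * grid.voxel_volume_cc)
        )
    return lesions


def _voxel_face_area(mask: np.ndarray, spacing_mm: float) -> float:
    """Total exposed face area of a voxelized solid, in mm^2."""
    face = spacing_mm**2
    padded = np.pad(mask, 1)
    exposed = 0
    for ax in range(3):
        d = np.diff(padded.astype(np.int8), axis=ax)
        exposed += int(np.abs(d).sum())
    return exposed * face


def compute_sphericity(lesion: Lesion, grid: Grid, method: str = "mesh") -> float:
    """Wadell sphericity pi^(1/3) (6V)^(2/3) / A of a lesion.

    V is the voxel volume; A is the surface area from a triangulated
    isosurface (``mesh``, default) or exposed voxel-face counting
    (``voxel_faces``).  The mesh estimate tracks the continuum limit;
    face counting overestimates A and biases sphericity low, but is
    exactly testable.  Mesh values are clipped to 1 when discretization
    overshoots; lesions too small to mesh fall back to ``voxel_faces``
    and are flagged.
    """
    if method not in ("mesh", "voxel_faces"):
        raise ValueError(f"unknown surface method {method!r}")
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion")
    vol_mm3 = lesion.n_voxels * grid.spacing_mm**3

    lo = lesion.voxels.min(axis=0)
    hi = lesion.voxels.max(axis=0)
    crop = np.zeros(hi - lo + 1, dtype=bool)
    crop[tuple((lesion.voxels - lo).T)] = True

    if method == "mesh":
        try:
            padded = np.pad(crop.astype(np.float32), 1)
            verts, faces, _, _ = measure.marching_cubes(
                padded, level=0.5, spacing=(grid.spacing_mm,) * 3
            )
            area = measure.mesh_surface_area(verts, faces) / _MC_STAIRCASE_FACTOR
        except (ValueError, RuntimeError):
            lesion.flags.append("sphericity_mesh_fallback")
            area = _voxel_face_area(crop, grid.spacing_mm)
            method = "voxel_faces"
    else:
        area = _voxel_face_area(crop, grid.spacing_mm)

    s = np.pi ** (1 / 3) * (6 * vol_mm3) ** (2 / 3) / area
    if method == "mesh":
        s = min(s, 1.0)
    return float(s)


def interface_distance_map(
    gray: np.ndarray, white: np.ndarray, grid: Grid
) -> InterfaceDistanceMap:
    """Distance transform to the gray-white interface.

    The interface voxel set is gray voxels 6-adjacent to white plus white
    voxels 6-adjacent to gray; the map is the Euclidean distance transform
    (in mm, between voxel centers) to that set.
    """
    gray = np.asarray(gray).astype(bool)
    white = np.asarray(white).astype(bool)
    if np.any(gray & white):
        raise ValueError("gray and white masks overlap")
    if not gray.any() or not white.any():
        raise ValueError("gray and white masks must both be nonempty")
    near_white = ndimage.binary_dilation(white, structure=_STRUCT_6)
    near_gray = ndimage.binary_dilation(gray, structure=_STRUCT_6)
    interface = (gray & near_white) | (white & near_gray)
    if not interface.any():
        raise ValueError("gray and white masks are nowhere adjacent: no interface")
    dist = ndimage.distance_transform_edt(~interface, sampling=grid.spacing_mm)
    return InterfaceDistanceMap(distance_mm=dist, interface_voxels=interface, grid=grid)


def lesion_interface_distance(
    lesion: Lesion,
    dmap: InterfaceDistanceMap,
    brain_mask: np.ndarray | None = None,
    mode: str = "centroid",
) -> float:
    """Interface distance of a lesion, in mm.

    Default samples the distance map at the voxel containing the centroid
    (nearest-voxel); ``mode='boundary'`` returns the minimum over the
    lesion's voxels instead.  A centroid outside the brain mask is flagged
    but the distance is still returned.
    """
    if mode == "boundary":
        return float(dmap.distance_mm[tuple(lesion.voxels.T)].min())
    c = lesion.centroid(dmap.grid)
    idx = dmap.grid.containing_voxel(c)[0]
    if brain_mask is not None and not brain_mask[tuple(idx)]:
        lesion.flags.append("centroid_outside_brain")
    return float(dmap.distance_mm[tuple(idx)])


def assign_membership(
    lesion: Lesion, atlas: np.ndarray, grid: Grid, rescue_mm: float = MEMBERSHIP_RESCUE_MM
):
    """Atlas label at the lesion centroid.

    If the centroid voxel is background, the nearest labeled voxel within
    ``rescue_mm`` is used; beyond that the lesion is ``"unassigned"``.
    """
    atlas = np.asarray(atlas)
    idx = tuple(grid.containing_voxel(lesion.centroid(grid))[0])
    label = int(atlas[idx])
    if label != 0:
        return label
    dist, nearest = ndimage.distance_transform_edt(
        atlas == 0, sampling=grid.spacing_mm, return_indices=True
    )
    if dist[idx] <= rescue_mm:
        return int(atlas[tuple(nearest[(slice(None),) + idx])])
    return UNASSIGNED


def fill_morphometrics(
    lesions: list[Lesion],
    grid: Grid,
    dmap: InterfaceDistanceMap | None = None,
    atlases: dict[str, np.ndarray] | None = None,
    brain_mask: np.ndarray | None = None,
    sphericity_method: str = "mesh",
) -> list[Lesion]:
    """Fill sphericity, centroid, interface distance and memberships in place.

    Nearest-label rescue indices are precomputed once per atlas, so this is
    the efficient path for whole cohorts.
    """
    rescue = {}
    if atlases:
        for name, atlas in atlases.items():
            dist, nearest = ndimage.distance_transform_edt(
                np.asarray(atlas) == 0, sampling=grid.spacing_mm, return_indices=True
            )
            rescue[name] = (np.asarray(atlas), dist, nearest)
    for les in lesions:
        les.centroid_mm = les.centroid(grid)
        les.sphericity = compute_sphericity(les, grid, sphericity_method)
        if dmap is not None:
            les.interface_distance_mm = lesion_interface_distance(les, dmap, brain_mask)
        idx = tuple(grid.containing_voxel(les.centroid_mm)[0])
        for name, (atlas, dist, nearest) in rescue.items():
            label = int(atlas[idx])
            if label == 0:
                if dist[idx] <= MEMBERSHIP_RESCUE_MM:
                    label = int(atlas[tuple(nearest[(slice(None),) + idx])])
                else:
                    label = UNASSIGNED
            les.memberships[name] = label
    return lesions
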