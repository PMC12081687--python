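"""Readers, writers, contour rasterization and tabular persistence.

Volumes travel as NIfTI with an affine of ``diag(spacing) @ origin``;
integer volumes round-trip bit-exactly.  Planar contour sets (closed
polygons in physical mm, each tagged with an axis-aligned plane) are
rasterized by the voxel-center rule: a voxel is included iff its center
lies inside the polygon of its plane (even-odd rule; multiple polygons
on one plane XOR, so holes are representable).  Cohort tables persist in
a single-file SQLite database.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .geometry import Lesion
from .grid import Grid
from .phantom import Patient, PatientCohort, Phantom

__all__ = [
    "read_volume",
    "write_volume",
    "ContourSet",
    "rasterize_contours",
    "load_contours_json",
    "CohortStore",
    "write_phantom",
    "write_cohort",
    "read_cohort",
    "lesion_table",
    "config_hash",
]

_AXES = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# NIfTI volumes


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def write_volume(vol: np.ndarray, grid: Grid, path) -> None:
    vol = np.asarray(vol)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    img = nib.Nifti1Image(vol, _affine(grid))
    img.header.set_zooms((grid.spacing_mm,) * 3)
    nib.save(img, str(path))


def read_volume(path, expect_spacing_mm: float | None = None) -> tuple[np.ndarray, Grid]:
    """Load a NIfTI volume; rejects anisotropic or mismatched spacing."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"{path}: anisotropic spacing {zooms}; this pipeline is isotropic")
    spacing = float(zooms[0])
    if expect_spacing_mm is not None and not np.isclose(spacing, expect_spacing_mm):
        raise ValueError(
            f"{path}: spacing {spacing} mm does not match session grid {expect_spacing_mm} mm"
        )
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = np.asarray(img.dataobj)
    return data, Grid(shape=tuple(data.shape), spacing_mm=spacing, origin_mm=origin)


# ---------------------------------------------------------------------------
# contours


@dataclass
class Polygon:
    """A closed planar loop in physical mm on an axis-aligned plane."""

    plane_axis: str  # "x", "y" or "z"
    plane_mm: float
    vertices_mm: np.ndarray  # (n, 2), in-plane coordinates, axis order preserved

    def __post_init__(self) -> None:
        self.vertices_mm = np.asarray(self.vertices_mm, dtype=float)
        if self.vertices_mm.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.plane_axis not in _AXES:
            raise ValueError(f"plane axis must be x/y/z, got {self.plane_axis!r}")


@dataclass
class ContourSet:
    """Per-lesion polygon stacks plus the target grid specification."""

    polygons: list[Polygon]
    grid: Grid


def load_contours_json(path) -> ContourSet:
    """Read the repo's simple JSON contour format.

    ``{"grid": {"shape": [..], "spacing_mm": s, "origin_mm": [..]},
    "polygons": [{"plane_axis": "z", "plane_mm": p, "vertices_mm": [[u,v],..]}, ..]}``
    """
    spec = json.loads(Path(path).read_text())
    g = spec["grid"]
    grid = Grid(
        shape=tuple(g["shape"]),
        spacing_mm=float(g["spacing_mm"]),
        origin_mm=tuple(g.get("origin_mm", (0.0, 0.0, 0.0))),
    )
    polys = [
        Polygon(p["plane_axis"], float(p["plane_mm"]), np.asarray(p["vertices_mm"]))
        for p in spec["polygons"]
    ]
    return ContourSet(polygons=polys, grid=grid)


def rasterize_contours(contours: ContourSet) -> np.ndarray:
    """Voxelize a contour set by the voxel-center even-odd rule.

    Robust to non-square grids; disconnected polygon stacks are allowed.
    A polygon's plane must coincide (within half a voxel) with a grid
    plane of voxel centers.
    """
    grid = contours.grid
    mask = np.zeros(grid.shape, dtype=bool)
    for poly in contours.polygons:
        ax = _AXES[poly.plane_axis]
        centers = grid.axis_centers_mm(ax)
        k = int(np.argmin(np.abs(centers - poly.plane_mm)))
        if abs(centers[k] - poly.plane_mm) > 0.01 * grid.spacing_mm:
            raise ValueError(
                f"polygon plane {poly.plane_mm} mm not aligned with a grid plane "
                f"(axis {poly.plane_axis})"
            )
        in_axes = [a for a in range(3) if a != ax]
        u = grid.axis_centers_mm(in_axes[0])
        v = grid.axis_centers_mm(in_axes[1])
        uu, vv = np.meshgrid(u, v, indexing="ij")
        pts = np.column_stack([uu.ravel(), vv.ravel()])
        inside = MplPath(poly.vertices_mm).contains_points(pts).reshape(len(u), len(v))
        sl = [slice(None)] * 3
        sl[ax] = k
        mask[tuple(sl)] ^= inside  # XOR: even-odd across stacked polygons
    return mask


# ---------------------------------------------------------------------------
# phantom / cohort serialization


def write_phantom(phantom: Phantom, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = phantom.grid
    write_volume(phantom.brain_mask, g, out / "brain_mask.nii")
    write_volume(phantom.gray_mask, g, out / "gray_mask.nii")
    write_volume(phantom.white_mask, g, out / "white_mask.nii")
    write_volume(phantom.perfusion.astype(np.float32), g, out / "perfusion.nii")
    for name, atlas in phantom.atlases.items():
        write_volume(atlas, g, out / f"atlas_{name}.nii")
        phantom.region_tables[name].to_csv(out / f"regions_{name}.csv", index=False)


def write_cohort(cohort: PatientCohort, out_dir) -> Path:
    """Per-patient lesion label volumes plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in cohort.patients:
        vol = np.zeros(cohort.grid.shape, dtype=np.int16)
        for li, les in enumerate(patient.lesions, start=1):
            vol[tuple(les.voxels.T)] = li
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "site": patient.site,
                    "primary": patient.primary,
                    "lesion_id": les.lesion_id,
                    "lesion_index": li,
                    "file": f"{patient.patient_id}_lesions.nii",
                }
            )
        write_volume(vol, cohort.grid, out / f"{patient.patient_id}_lesions.nii")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def read_cohort(manifest_path) -> PatientCohort:
    base = Path(manifest_path).parent
    manifest = pd.read_csv(manifest_path)
    patients: list[Patient] = []
    grid = None
    for pid, group in manifest.groupby("patient_id", sort=True):
        vol, g = read_volume(base / group["file"].iloc[0])
        grid = grid or g
        grid.check_same(g)
        lesions = []
        for _, row in group.iterrows():
            vox = np.argwhere(vol == row["lesion_index"])
            lesions.append(
                Lesion(
                    voxels=vox,
                    volume_cc=vox.shape[0] * g.voxel_volume_cc,
                    patient_id=str(pid),
                    lesion_id=str(row["lesion_id"]),
                )
            )
        patients.append(
            Patient(
                patient_id=str(pid),
                site=str(group["site"].iloc[0]),
                primary=str(group["primary"].iloc[0]),
                lesions=lesions,
            )
        )
    if grid is None:
        raise ValueError("empty manifest")
    return PatientCohort(grid=grid, patients=patients)


def lesion_table(cohort: PatientCohort) -> pd.DataFrame:
    """Flat per-lesion metrics table (the CSV the geometry stage emits)."""
    rows = []
    for patient, les in cohort.iter_lesions():
        c = les.centroid_mm if les.centroid_mm is not None else les.centroid(cohort.grid)
        row = {
            "patient_id": patient.patient_id,
            "site": patient.site,
            "primary": patient.primary,
            "lesion_id": les.lesion_id,
            "volume_cc": les.volume_cc,
            "sphericity": les.sphericity,
            "centroid_x_mm": c[0],
            "centroid_y_mm": c[1],
            "centroid_z_mm": c[2],
            "interface_distance_mm": les.interface_distance_mm,
        }
        for atlas_name, label in les.memberships.items():
            row[f"{atlas_name}_label"] = label
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class CohortStore:
    """Single-file SQLite persistence for patients, lesions and runs."""

    def __init__(self, path) -> None:
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self._create()

    def _create(self) -> None:
        cur = self.conn.cursor()
        cur.executescript(
            """
            CREATE TABLE IF NOT EXISTS patients (
                patient_id TEXT PRIMARY KEY,
                site TEXT NOT NULL,
                "primary" TEXT NOT NULL,
                n_lesions INTEGER NOT NULL
            );
            CREATE TABLE IF NOT EXISTS lesions (
                lesion_id TEXT PRIMARY KEY,
                patient_id TEXT NOT NULL REFERENCES patients(patient_id),
                volume_cc REAL, sphericity REAL,
                centroid_x_mm REAL, centroid_y_mm REAL, centroid_z_mm REAL,
                interface_distance_mm REAL,
                coarse_label TEXT, fine_label TEXT,
                functional_label TEXT, vascular_label TEXT
            );
            CREATE TABLE IF NOT EXISTS runs (
                run_id INTEGER PRIMARY KEY AUTOINCREMENT,
                config_hash TEXT NOT NULL,
                seed INTEGER NOT NULL,
                created_utc TEXT DEFAULT CURRENT_TIMESTAMP,
                UNIQUE(config_hash, seed)
            );
            """
        )
        self.conn.commit()

    def store_cohort(self, cohort: PatientCohort) -> None:
        cur = self.conn.cursor()
        for patient in cohort.patients:
            cur.execute(
                'INSERT OR REPLACE INTO patients (patient_id, site, "primary", n_lesions)'
                " VALUES (?,?,?,?)",
                (patient.patient_id, patient.site, patient.primary, len(patient.lesions)),
            )
            for les in patient.lesions:
                c = les.centroid_mm if les.centroid_mm is not None else [None] * 3
                cur.execute(
                    "INSERT OR REPLACE INTO lesions VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
                    (
                        les.lesion_id,
                        patient.patient_id,
                        les.volume_cc,
                        None if np.isnan(les.sphericity) else les.sphericity,
                        c[0], c[1], c[2],
                        None
                        if np.isnan(les.interface_distance_mm)
                        else les.interface_distance_mm,
                        str(les.memberships.get("coarse", "")),
                        str(les.memberships.get("fine", "")),
                        str(les.memberships.get("functional", "")),
                        str(les.memberships.get("vascular", "")),
                    ),
                )
        self.conn.commit()

    def record_run(self, cfg_hash: str, seed: int) -> None:
        self.conn.execute(
            "INSERT OR IGNORE INTO runs (config_hash, seed) VALUES (?,?)", (cfg_hash, seed)
        )
        self.conn.commit()

    def counts(self) -> tuple[int, int]:
        cur = self.conn.cursor()
        (np_,) = cur.execute("SELECT COUNT(*) FROM patients").fetchone()
        (nl,) = cur.execute("SELECT COUNT(*) FROM lesions").fetchone()
        return np_, nl

    def close(self) -> None:
        self.conn.close()
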