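"""Perfusion-related analyses.

Normalized perfusion (99th-percentile scaling to [0, 1]), joint
histograms of lesion burden against perfusion and interface distance,
the perfusion x distance subspace occupancy (the fraction of total
lesion volume at moderate-to-high perfusion and close to the gray-white
interface), and the per-region perfusion-density trend.

Arterial-territory contributions reuse
:func:`bmrisk.riskmap.region_contribution` with the vascular atlas;
there is no separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import InterfaceDistanceMap
from .phantom import PatientCohort
from .riskmap import RegionStats

__all__ = [
    "normalize_perfusion",
    "subspace_fraction",
    "joint_count_histogram",
    "joint_volume_histogram",
    "density_vs_perfusion_by_region",
]

#: normalization percentile; robust to hot-spot outliers in perfusion maps
NORM_PCTL = 99.0
DEFAULT_P_RANGE = (0.6, 0.95)
DEFAULT_D_MAX_MM = 5.0


def normalize_perfusion(raw: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Scale a perfusion map into [0, 1] by its in-brain 99th percentile."""
    raw = np.asarray(raw, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    vals = raw[brain]
    if vals.size == 0:
        raise ValueError("empty brain mask")
    if np.any(vals < 0):
        raise ValueError("perfusion must be non-negative")
    p99 = np.percentile(vals, NORM_PCTL)
    if p99 <= 0 or np.isclose(vals.min(), vals.max()):
        raise ValueError("perfusion constant within brain; normalization undefined")
    out = np.clip(raw / p99, 0.0, 1.0)
    out[~brain] = 0.0
    return out


def _lesion_voxel_arrays(cohort: PatientCohort):
    vox = [les.voxels for _, les in cohort.iter_lesions()]
    if not vox:
        raise ValueError("empty cohort")
    return np.concatenate(vox, axis=0)


def subspace_fraction(
    cohort: PatientCohort,
    perfusion_norm: np.ndarray,
    dmap: InterfaceDistanceMap,
    p_range: tuple[float, float] = DEFAULT_P_RANGE,
    d_max_mm: float = DEFAULT_D_MAX_MM,
) -> float:
    """Fraction of total lesion volume inside a perfusion-distance subspace.

    Evaluated per lesion voxel (volume-weighted): a voxel counts if its
    normalized perfusion lies in ``p_range`` (inclusive) and its interface
    distance is at most ``d_max_mm``.  Monotone non-decreasing in
    ``d_max_mm`` and in widening ``p_range``.
    """
    vox = _lesion_voxel_arrays(cohort)
    p = perfusion_norm[tuple(vox.T)]
    d = dmap.distance_mm[tuple(vox.T)]
    inside = (p >= p_range[0]) & (p <= p_range[1]) & (d <= d_max_mm)
    return float(inside.mean())


def joint_count_histogram(
    counts: np.ndarray,
    perfusion_norm: np.ndarray,
    brain_mask: np.ndarray,
    voxel_volume_cc: float,
    p_bins: int = 20,
    max_count: int | None = None,
) -> pd.DataFrame:
    """2-D histogram of (perfusion bin x lesion count per voxel).

    Weighted by brain volume (cc); conserves total brain volume exactly.
    """
    brain = np.asarray(brain_mask, dtype=bool)
    p = perfusion_norm[brain]
    c = counts[brain]
    cmax = int(c.max()) if max_count is None else max_count
    p_edges = np.linspace(0.0, 1.0, p_bins + 1)
    h, _, _ = np.histogram2d(
        p, np.clip(c, 0, cmax), bins=[p_edges, np.arange(cmax + 2) - 0.5]
    )
    df = pd.DataFrame(
        h * voxel_volume_cc,
        index=pd.Index(p_edges[:-1], name="perfusion_bin_lo"),
        columns=pd.Index(np.arange(cmax + 1), name="lesion_count"),
    )
    return df


def joint_volume_histogram(
    cohort: PatientCohort,
    perfusion_norm: np.ndarray,
    dmap: InterfaceDistanceMap,
    p_bins: int = 20,
    d_bin_mm: float = 1.0,
) -> pd.DataFrame:
    """2-D histogram of (perfusion bin x interface distance bin).

    Weighted by lesion volume (cc); conserves total lesion volume exactly.
    """
    vox = _lesion_voxel_arrays(cohort)
    p = perfusion_norm[tuple(vox.T)]
    d = dmap.distance_mm[tuple(vox.T)]
    p_edges = np.linspace(0.0, 1.0, p_bins + 1)
    d_edges = np.arange(np.ceil(d.max() / d_bin_mm) + 2) * d_bin_mm
    h, _, _ = np.histogram2d(p, d, bins=[p_edges, d_edges])
    vox_cc = cohort.grid.voxel_volume_cc
    return pd.DataFrame(
        h * vox_cc,
        index=pd.Index(p_edges[:-1], name="perfusion_bin_lo"),
        columns=pd.Index(d_edges[:-1], name="distance_bin_lo_mm"),
    )


def density_vs_perfusion_by_region(
    region_stats: RegionStats,
    atlas: np.ndarray,
    perfusion_norm: np.ndarray,
    parenchyma: np.ndarray,
) -> tuple[pd.DataFrame, float, float]:
    """Per-region mean perfusion against the density enrichment ratio.

    Mean normalized perfusion is volume-weighted over the region's
    parenchymal voxels.  Returns the per-region table plus Spearman rho
    and p across regions with defined density.
    """
    par = np.asarray(parenchyma, dtype=bool)
    rows = []
    for _, reg in region_stats.table.iterrows():
        sel = (np.asarray(atlas) == reg["label"]) & par
        if not sel.any():
            continue
        rows.append(
            {
                "label": reg["label"],
                "name": reg["name"],
                "mean_perfusion": float(perfusion_norm[sel].mean()),
                "density": reg["density"],
                "percent_contribution": reg["percent_contribution"],
            }
        )
    df = pd.DataFrame(rows).dropna(subset=["density"])
    if len(df) >= 3:
        rho, p = sps.spearmanr(df["mean_perfusion"], df["density"])
    else:
        rho, p = float("nan"), float("nan")
    return df, float(rho), float(p)
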