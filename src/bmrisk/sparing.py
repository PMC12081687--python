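"""Function-sparing whole-brain radiotherapy targets and expected coverage.

A sparing plan excludes an isotropically expanded union of spared
structures from the whole-brain target.  The canonical plans:

- ``WBRT``: nothing spared, target = whole brain (coverage 100% by
  construction for any in-brain cohort);
- ``WBRT-HA``: hippocampal avoidance — hippocampi + margin;
- ``WBRT-PROTECT``: a 3 mm isotropic expansion of the union of the
  hippocampi, amygdala, thalamus, pallidus, caudate, putamen, brainstem
  and ventricles, with the target defined as whole brain minus that
  expanded ("neuroprotect") volume.

Expected coverage is the percentage of cohort lesions inside the target,
counted by centroid (default) or by lesion volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import PatientCohort, Phantom, SUBCORTICAL_NAMES

__all__ = [
    "SparingPlan",
    "CoverageReport",
    "build_target",
    "expected_coverage",
    "tradeoff_curve",
    "dilate_mask",
    "PLAN_PRESETS",
]

log = logging.getLogger(__name__)

DEFAULT_MARGIN_MM = 3.0

#: preset spared-structure sets (coarse-atlas region names)
PLAN_PRESETS: dict[str, tuple[str, ...]] = {
    "wbrt": (),
    "wbrt-ha": ("hippocampus_l", "hippocampus_r"),
    "wbrt-protect": tuple(SUBCORTICAL_NAMES) + ("brainstem", "ventricles"),
}


@dataclass
class SparingPlan:
    name: str
    spared_labels: tuple[int, ...]
    margin_mm: float
    target_mask: np.ndarray
    spared_volume_fraction: float
    degenerate: bool = False


@dataclass
class CoverageReport:
    plan: str
    expected_coverage_pct: float
    per_primary_pct: dict[str, float]
    spared_volume_fraction: float
    mode: str
    n_lesions: int
    n_uncovered_unassigned: int = 0


def dilate_mask(mask: np.ndarray, spacing_mm: float, margin_mm: float) -> np.ndarray:
    """Isotropic Euclidean dilation by thresholding the distance transform.

    Exact in mm and spacing-independent, unlike iterated structuring
    elements.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return dist <= margin_mm


def build_target(
    phantom: Phantom,
    spared_names=(),
    margin_mm: float = DEFAULT_MARGIN_MM,
    name: str = "custom",
) -> SparingPlan:
    """Boolean target construction: brain minus expanded spared union."""
    table = phantom.region_table
    name_to_label = dict(zip(table["name"], table["label"]))
    labels = []
    for sn in spared_names:
        if sn not in name_to_label:
            raise KeyError(f"unknown region {sn!r}; valid: {sorted(name_to_label)}")
        labels.append(int(name_to_label[sn]))
    spared = np.isin(phantom.atlases["coarse"], labels)
    expanded = dilate_mask(spared, phantom.grid.spacing_mm, margin_mm) & phantom.brain_mask
    target = phantom.brain_mask & ~expanded
    frac = float(expanded.sum() / phantom.brain_mask.sum())
    degenerate = not target.any()
    if degenerate:
        log.warning("plan %s has an empty target (entire brain spared)", name)
    return SparingPlan(
        name=name,
        spared_labels=tuple(labels),
        margin_mm=margin_mm,
        target_mask=target,
        spared_volume_fraction=frac,
        degenerate=degenerate,
    )


def expected_coverage(
    cohort: PatientCohort, plan: SparingPlan, mode: str = "centroid"
) -> CoverageReport:
    """Percentage of cohort lesions covered by the plan's target.

    ``centroid`` mode counts lesions whose centroid voxel is inside the
    target; ``volume`` mode counts total lesion volume inside the target.
    Reported overall and per primary histology.  A lesion whose centroid
    falls outside the grid-resolvable brain counts as uncovered.
    """
    if mode not in ("centroid", "volume"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    if cohort.n_lesions == 0:
        raise ValueError("empty cohort")
    grid = cohort.grid
    covered_w: dict[str, float] = {}
    total_w: dict[str, float] = {}
    n_unassigned = 0
    for patient, les in cohort.iter_lesions():
        if mode == "centroid":
            idx = tuple(grid.containing_voxel(les.centroid(grid))[0])
            w_tot = 1.0
            w_cov = float(plan.target_mask[idx])
        else:
            w_tot = float(les.n_voxels)
            w_cov = float(plan.target_mask[tuple(les.voxels.T)].sum())
        covered_w[patient.primary] = covered_w.get(patient.primary, 0.0) + w_cov
        total_w[patient.primary] = total_w.get(patient.primary, 0.0) + w_tot
    per_primary = {
        prim: 100.0 * covered_w[prim] / total_w[prim] for prim in total_w if total_w[prim] > 0
    }
    overall = 100.0 * sum(covered_w.values()) / sum(total_w.values())
    return CoverageReport(
        plan=plan.name,
        expected_coverage_pct=overall,
        per_primary_pct=per_primary,
        spared_volume_fraction=plan.spared_volume_fraction,
        mode=mode,
        n_lesions=cohort.n_lesions,
        n_uncovered_unassigned=n_unassigned,
    )


def tradeoff_curve(
    cohort: PatientCohort, plans: list[SparingPlan], mode: str = "centroid"
) -> pd.DataFrame:
    """Coverage vs spared-volume tradeoff table down a nesting of plans.

    For plans nested by spared set, coverage is monotone non-increasing.
    Non-nested plans are computed anyway with a warning; monotonicity is
    then not asserted.
    """
    nested = all(
        set(plans[i].spared_labels) <= set(plans[i + 1].spared_labels)
        for i in range(len(plans) - 1)
    )
    if not nested:
        warnings.warn("plans are not nested; coverage need not be monotone", stacklevel=2)
    rows = []
    for plan in plans:
        rep = expected_coverage(cohort, plan, mode)
        row = {
            "plan": plan.name,
            "spared_volume_fraction": plan.spared_volume_fraction,
            "coverage_pct": rep.expected_coverage_pct,
        }
        for prim, pct in sorted(rep.per_primary_pct.items()):
            row[f"coverage_pct_{prim}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
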