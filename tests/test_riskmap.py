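"""Accumulation identities and regional contribution statistics."""

import numpy as np
import pytest

from bmrisk.geometry import Lesion
from bmrisk.grid import Grid
from bmrisk.phantom import Patient, PatientCohort
from bmrisk.riskmap import (
    accumulate,
    dilate_labels,
    expansion_sensitivity,
    laterality_compare,
    region_contribution,
)
from oracles import exhaustive_dilation


def _cohort(grid, patients):
    return PatientCohort(grid=grid, patients=patients)


def _patient(pid, voxels_list, site="site_A", primary="lung", grid=None):
    lesions = [
        Lesion(
            voxels=np.asarray(v),
            volume_cc=len(v) * grid.voxel_volume_cc,
            patient_id=pid,
            lesion_id=f"{pid}_L{i}",
        )
        for i, v in enumerate(voxels_list)
    ]
    return Patient(patient_id=pid, site=site, primary=primary, lesions=lesions)


class TestAccumulate:
    def test_single_lesion_identity(self, unit_grid):
        g = unit_grid((10, 10, 10))
        vox = [(1, 1, 1), (1, 1, 2)]
        cohort = _cohort(g, [_patient("P0", [vox], grid=g)])
        rm = accumulate(cohort)
        assert rm.c_max == 1 and rm.counts.sum() == 2
        assert rm.counts[1, 1, 1] == 1 and rm.counts[1, 1, 2] == 1

    def test_identical_patients_add(self, unit_grid):
        g = unit_grid((10, 10, 10))
        vox = [(2, 3, 4)]
        cohort = _cohort(
            g, [_patient("P0", [vox], grid=g), _patient("P1", [vox], site="site_B", grid=g)]
        )
        rm = accumulate(cohort)
        assert rm.counts[2, 3, 4] == 2 and rm.c_max == 2
        total = rm.per_site_counts["site_A"] + rm.per_site_counts["site_B"]
        assert np.array_equal(total, rm.counts)

    def test_conservation_on_simulated_cohort(self, small_cohort):
        rm = accumulate(small_cohort)
        tally = sum(les.n_voxels for _, les in small_cohort.iter_lesions())
        assert int(rm.counts.sum()) == tally
        assert rm.n_lesions == small_cohort.n_lesions

    def test_additivity_and_permutation_invariance(self, small_cohort):
        g = small_cohort.grid
        half = len(small_cohort.patients) // 2
        a = _cohort(g, small_cohort.patients[:half])
        b = _cohort(g, small_cohort.patients[half:])
        rm_all = accumulate(small_cohort)
        assert np.array_equal(rm_all.counts, accumulate(a).counts + accumulate(b).counts)
        shuffled = _cohort(g, list(reversed(small_cohort.patients)))
        assert np.array_equal(rm_all.counts, accumulate(shuffled).counts)

    def test_off_grid_lesion_named_in_error(self, unit_grid):
        g = unit_grid((5, 5, 5))
        cohort = _cohort(g, [_patient("P9", [[(7, 1, 1)]], grid=g)])
        with pytest.raises(ValueError, match="P9"):
            accumulate(cohort)


class TestRegionContribution:
    def _toy(self, unit_grid):
        import pandas as pd

        g = unit_grid((12, 12, 12))
        atlas = np.zeros(g.shape, dtype=int)
        atlas[:, :, :6] = 1  # region A: half the grid
        atlas[:, :, 6:] = 2  # region B
        table = pd.DataFrame(
            {
                "label": [1, 2],
                "name": ["A", "B"],
                "partner": [0, 0],
                "volume_cc": [
                    np.count_nonzero(atlas == 1) * g.voxel_volume_cc,
                    np.count_nonzero(atlas == 2) * g.voxel_volume_cc,
                ],
            }
        )
        return g, atlas, table

    def test_all_lesions_in_one_region(self, unit_grid):
        g, atlas, table = self._toy(unit_grid)
        pts = [_patient(f"P{i}", [[(3, 3, 2)]], site=f"site_{i%2}", grid=g) for i in range(4)]
        stats = region_contribution(_cohort(g, pts), atlas, table, grid=g)
        t = stats.table.set_index("name")
        assert t.loc["A", "percent_contribution"] == 100.0
        assert t.loc["B", "percent_contribution"] == 0.0

    def test_percent_sums_to_100(self, phantom, small_cohort):
        stats = region_contribution(
            small_cohort, phantom.atlases["coarse"], phantom.region_table
        )
        assert stats.table["percent_contribution"].sum() == pytest.approx(100.0, abs=1e-6)
        assert stats.n_assigned + stats.n_unassigned == small_cohort.n_lesions

    def test_density_is_enrichment_ratio(self, unit_grid):
        g, atlas, table = self._toy(unit_grid)
        # 3 lesions in A (50% of volume), 1 in B -> density A = 75/50 = 1.5
        pts = [
            _patient("P0", [[(3, 3, 2)], [(4, 4, 2)], [(5, 5, 2)], [(3, 3, 9)]], grid=g)
        ]
        stats = region_contribution(_cohort(g, pts), atlas, table, grid=g)
        t = stats.table.set_index("name")
        assert t.loc["A", "density"] == pytest.approx(1.5)
        assert t.loc["B", "density"] == pytest.approx(0.5)


class TestExpansion:
    def test_margin_zero_is_identity(self, phantom, small_cohort):
        base = region_contribution(
            small_cohort, phantom.atlases["coarse"], phantom.region_table
        )
        exp = expansion_sensitivity(
            small_cohort, phantom.atlases["coarse"], phantom.region_table, margins_mm=[0.0]
        )[0.0]
        assert np.array_equal(
            base.table["lesion_count"].to_numpy(), exp.table["lesion_count"].to_numpy()
        )

    def test_dilation_matches_exhaustive_oracle(self, unit_grid):
        rng = np.random.default_rng(5)
        g = unit_grid((14, 14, 14), spacing=2.0)
        atlas = np.zeros(g.shape, dtype=int)
        atlas[3:5, 3:5, 3:5] = 1
        atlas[9:11, 9:11, 9:11] = 2
        dil = dilate_labels(atlas, g, 5.0)
        for label in (1, 2):
            ref = exhaustive_dilation(atlas == label, 2.0, 5.0)
            # a voxel in the oracle dilation of this label must be labeled,
            # with ties going to the nearest original region
            claimed = dil == label
            other = exhaustive_dilation(atlas == (3 - label), 2.0, 5.0)
            assert np.all(claimed <= ref)
            assert np.all((ref & ~other) <= claimed)

    def test_distant_lesions_unaffected_by_expansion(self, unit_grid):
        g = unit_grid((30, 30, 30))
        atlas = np.zeros(g.shape, dtype=int)
        atlas[2:5, 2:5, 2:5] = 1
        atlas[25:28, 25:28, 25:28] = 2
        dil = dilate_labels(atlas, g, 5.0)
        # voxel >5 mm from both regions stays background
        assert dil[15, 15, 15] == 0
        assert dil[3, 3, 3] == 1 and dil[26, 26, 26] == 2

    def test_margin_beyond_grid_rejected(self, unit_grid):
        g = unit_grid((10, 10, 10))
        with pytest.raises(ValueError):
            dilate_labels(np.ones(g.shape, dtype=int), g, 1000.0)


class TestLaterality:
    def test_mirrored_cohort_p_equals_one(self, phantom):
        g = phantom.grid
        coarse = phantom.atlases["coarse"]
        table = phantom.region_table
        f_l = np.argwhere(coarse == 1)[0]
        f_r = f_l.copy()
        f_r[0] = g.shape[0] - 1 - f_l[0]
        if coarse[tuple(f_r)] != 2:
            f_r = np.argwhere(coarse == 2)[0]
        pts = []
        for i in range(8):
            pts.append(
                _patient(
                    f"P{i}",
                    [[tuple(f_l)], [tuple(f_r)]],
                    site=f"site_{i % 4}",
                    grid=g,
                )
            )
        res = laterality_compare(_cohort(g, pts), coarse, table, grid=g)
        frontal = res.set_index("pair").loc["frontal"]
        assert frontal["p_value"] == 1.0

    def test_forced_left_is_total(self, phantom):
        g = phantom.grid
        coarse = phantom.atlases["coarse"]
        left_vox = tuple(np.argwhere(coarse == 1)[0])
        pts = [
            _patient(f"P{i}", [[left_vox]], site=f"site_{i % 4}", grid=g) for i in range(8)
        ]
        res = laterality_compare(_cohort(g, pts), coarse, phantom.region_table, grid=g)
        frontal = res.set_index("pair").loc["frontal"]
        assert frontal["left_pct"] == 100.0 and frontal["right_pct"] == 0.0
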