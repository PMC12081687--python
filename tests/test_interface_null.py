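"""Interface-proximity histograms and the tissue-morphology null test."""

import numpy as np
import pytest

from bmrisk.geometry import Lesion, interface_distance_map
from bmrisk.grid import Grid
from bmrisk.interface_null import (
    DistanceHistogram,
    compare_to_null,
    distance_bins,
    null_histogram,
    observed_histogram,
    pit_wilcoxon,
)
from bmrisk.phantom import Patient, PatientCohort


def _cohort_with_distances(grid, dists):
    patients = []
    for i, d in enumerate(dists):
        les = Lesion(
            voxels=np.array([(1, 1, 1)]),
            volume_cc=grid.voxel_volume_cc,
            patient_id=f"P{i}",
            lesion_id=f"P{i}_L0",
        )
        les.interface_distance_mm = float(d)
        patients.append(
            Patient(patient_id=f"P{i}", site=f"site_{i % 2}", primary="lung", lesions=[les])
        )
    return PatientCohort(grid=grid, patients=patients)


class TestObservedHistogram:
    def test_all_on_interface(self, unit_grid):
        g = unit_grid((5, 5, 5))
        edges = np.arange(0, 10.5, 0.5)
        h = observed_histogram(_cohort_with_distances(g, [0, 0, 0]), edges)
        assert h.fractions[0] == 1.0 and h.fractions[1:].sum() == 0.0

    def test_two_lesions_land_in_their_bins(self, unit_grid):
        g = unit_grid((5, 5, 5))
        edges = np.arange(0, 10.5, 0.5)
        h = observed_histogram(_cohort_with_distances(g, [1.2, 3.7]), edges)
        assert h.fractions[2] == 0.5  # [1.0, 1.5)
        assert h.fractions[7] == 0.5  # [3.5, 4.0)

    def test_matches_direct_tally(self, phantom, dmap, small_cohort):
        from bmrisk.geometry import fill_morphometrics

        fill_morphometrics(
            [l for _, l in small_cohort.iter_lesions()], phantom.grid, dmap=dmap
        )
        edges = distance_bins(dmap, phantom.parenchyma_mask)
        h = observed_histogram(small_cohort, edges)
        # independent tally over the per-lesion records
        dists = np.array([l.interface_distance_mm for _, l in small_cohort.iter_lesions()])
        dists = np.minimum(dists, edges[-1] - 1e-9)
        ref = np.histogram(dists, bins=edges)[0] / dists.size
        assert np.allclose(h.fractions, ref)

    def test_empty_cohort_rejected(self, unit_grid):
        g = unit_grid((5, 5, 5))
        with pytest.raises(ValueError):
            observed_histogram(PatientCohort(grid=g, patients=[]), np.arange(0, 5, 0.5))


class TestNullHistogram:
    def test_slab_null_uniform_over_gray(self, unit_grid):
        from bmrisk.phantom import Phantom

        g = unit_grid((20, 20, 24))
        white = np.zeros(g.shape, dtype=bool)
        gray = np.zeros(g.shape, dtype=bool)
        white[:, :, :12] = True
        gray[:, :, 12:22] = True  # 10 mm gray slab
        dm = interface_distance_map(gray, white, g)
        ph = Phantom(
            grid=g, brain_mask=white | gray, gray_mask=gray, white_mask=white,
            atlases={}, perfusion=np.zeros(g.shape), region_tables={}, seed=0,
        )
        edges = np.arange(0, 11.5, 0.5)
        h = null_histogram(ph, dm, edges)
        # voxel-center distances are integers: 0..9 on the gray side plus
        # 0..11 on the white side, so bins covering [0, 10) hold two layers
        # each and are uniform; the white-only tail (10, 11 mm) holds one
        occupied = h.fractions[h.fractions > 0]
        assert occupied.size == 12
        assert np.allclose(occupied[:10], occupied[0])
        assert np.allclose(occupied[10:], occupied[0] / 2)

    def test_voxel_volume_invariance(self, phantom, dmap):
        edges = distance_bins(dmap, phantom.parenchyma_mask)
        h1 = null_histogram(phantom, dmap, edges)
        # doubling the voxel volume rescales counts uniformly: fractions equal
        assert h1.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_voxel_scan(self, phantom, dmap):
        edges = distance_bins(dmap, phantom.parenchyma_mask)
        h = null_histogram(phantom, dmap, edges)
        d = dmap.distance_mm[phantom.parenchyma_mask]
        d = np.minimum(d, edges[-1] - 1e-9)
        counts = np.zeros(len(edges) - 1)
        for k in range(len(edges) - 1):
            counts[k] = np.count_nonzero((d >= edges[k]) & (d < edges[k + 1]))
        assert np.allclose(h.fractions, counts / counts.sum())


class TestCompareToNull:
    def _hist(self, fr, raw=None):
        fr = np.asarray(fr, dtype=float)
        return DistanceHistogram(
            bin_edges_mm=np.arange(len(fr) + 1) * 0.5,
            fractions=fr,
            raw_mm=None if raw is None else np.asarray(raw, dtype=float),
        )

    def test_identity_gives_zero_distance(self):
        fr = np.array([0.2, 0.3, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05, 0, 0, 0, 0])
        cmp_ = compare_to_null(self._hist(fr), self._hist(fr))
        assert cmp_.wasserstein_mm == 0.0
        assert cmp_.over_representation_pct == 0.0

    def test_translated_point_masses(self):
        h1 = np.zeros(16); h1[4] = 1  # mass at 2.0-2.5 mm
        h2 = np.zeros(16); h2[10] = 1  # mass at 5.0-5.5 mm
        cmp_ = compare_to_null(self._hist(h1), self._hist(h2))
        assert cmp_.wasserstein_mm == pytest.approx(3.0)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            compare_to_null(self._hist(np.ones(4) / 4), self._hist(np.ones(6) / 6))

    def test_few_bins_gives_nan_p_with_warning(self):
        h1 = np.array([0.6, 0.4, 0, 0, 0, 0])
        h2 = np.array([0.5, 0.5, 0, 0, 0, 0])
        with pytest.warns(UserWarning):
            cmp_ = compare_to_null(self._hist(h1), self._hist(h2))
        assert np.isnan(cmp_.wilcoxon_p)

    def test_interface_biased_cohort_detected(self, phantom, dmap, small_cohort):
        from bmrisk.geometry import fill_morphometrics

        fill_morphometrics(
            [l for _, l in small_cohort.iter_lesions()], phantom.grid, dmap=dmap
        )
        edges = distance_bins(dmap, phantom.parenchyma_mask)
        obs = observed_histogram(small_cohort, edges)
        null = null_histogram(phantom, dmap, edges)
        cmp_ = compare_to_null(obs, null)
        # tau = 3 mm interface bias at 50 patients is overwhelming evidence
        assert cmp_.wilcoxon_p < 0.01
        assert cmp_.over_representation_pct > 0
        assert cmp_.wasserstein_mm > 0

    def test_pit_p_reproducible_for_fixed_seed(self, phantom, dmap):
        rngd = np.random.default_rng(0)
        null_d = dmap.distance_mm[phantom.parenchyma_mask]
        obs_d = rngd.choice(null_d, size=200)
        _, p1 = pit_wilcoxon(obs_d, null_d, rng=42)
        _, p2 = pit_wilcoxon(obs_d, null_d, rng=42)
        assert p1 == p2

    def test_within_5mm_monotone_in_tau(self, phantom, dmap):
        """Stronger interface bias (smaller tau) concentrates mass within 5 mm."""
        from bmrisk.phantom import SimulationConfig, placement_weights

        idx, _ = placement_weights(
            phantom,
            SimulationConfig(interface_decay_tau_mm=None, perfusion_exponent_gamma=0.0),
        )
        d = dmap.distance_mm[tuple(idx.T)]
        fracs = []
        for tau in (2.0, 4.0, 8.0):
            w = np.exp(-d / tau)
            fracs.append((w * (d < 5.0)).sum() / w.sum())
        assert fracs[0] > fracs[1] > fracs[2]
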