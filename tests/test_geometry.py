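"""Lesion morphometrics: connectivity, sphericity, interface distances."""

import numpy as np
import pytest

from bmrisk.geometry import (
    UNASSIGNED,
    Lesion,
    assign_membership,
    compute_sphericity,
    extract_lesions,
    interface_distance_map,
    lesion_interface_distance,
)
from oracles import bfs_label_26, exhaustive_distance_map


class TestExtractLesions:
    def test_two_disjoint_blocks(self, unit_grid):
        g = unit_grid((20, 20, 20))
        mask = np.zeros(g.shape, dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[10:13, 10:13, 10:13] = True
        lesions = extract_lesions(mask, g)
        assert len(lesions) == 2
        assert all(les.volume_cc == pytest.approx(0.027) for les in lesions)

    def test_corner_touching_blocks_are_one_component(self, unit_grid):
        g = unit_grid((10, 10, 10))
        mask = np.zeros(g.shape, dtype=bool)
        mask[0:3, 0:3, 0:3] = True
        mask[3:6, 3:6, 3:6] = True  # touch only at voxel corner (2,2,2)-(3,3,3)
        assert len(extract_lesions(mask, g)) == 1

    def test_component_count_matches_bfs_oracle(self, unit_grid):
        rng = np.random.default_rng(0)
        g = unit_grid((25, 25, 25))
        mask = rng.random(g.shape) < 0.15
        assert len(extract_lesions(mask, g)) == bfs_label_26(mask)

    def test_empty_mask_gives_empty_list(self, unit_grid):
        g = unit_grid((8, 8, 8))
        assert extract_lesions(np.zeros(g.shape, dtype=bool), g) == []

    def test_volumes_sum_to_mask_volume(self, unit_grid):
        rng = np.random.default_rng(1)
        g = unit_grid((20, 20, 20), spacing=2.0)
        mask = rng.random(g.shape) < 0.2
        lesions = extract_lesions(mask, g)
        assert sum(l.volume_cc for l in lesions) == pytest.approx(
            mask.sum() * g.voxel_volume_cc
        )


def _one_voxel_lesion(grid, at=(2, 2, 2)):
    return Lesion(voxels=np.array([at]), volume_cc=grid.voxel_volume_cc)


class TestSphericity:
    def test_unit_cube_voxel_faces_closed_form(self, unit_grid):
        g = unit_grid((5, 5, 5))
        s = compute_sphericity(_one_voxel_lesion(g), g, method="voxel_faces")
        assert s == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-12)

    def test_rod_less_spherical_than_cube(self, unit_grid):
        g = unit_grid((30, 5, 5))
        rod = Lesion(
            voxels=np.array([(i, 2, 2) for i in range(1, 21)]),
            volume_cc=20 * g.voxel_volume_cc,
        )
        s_rod = compute_sphericity(rod, g, method="voxel_faces")
        s_cube = compute_sphericity(_one_voxel_lesion(g), g, method="voxel_faces")
        assert s_rod < s_cube

    def test_digitized_sphere_mesh_near_one(self, unit_grid):
        g = unit_grid((25, 25, 25))
        center = np.array([12.5, 12.5, 12.5])
        idx = np.argwhere(np.ones(g.shape, dtype=bool))
        inside = ((g.voxel_centers_mm(idx) - center) ** 2).sum(axis=1) <= 10.0**2
        sphere = Lesion(voxels=idx[inside], volume_cc=inside.sum() * g.voxel_volume_cc)
        s = compute_sphericity(sphere, g, method="mesh")
        assert abs(s - 1.0) < 0.03

    def test_digitized_prolate_spheroid_matches_analytic(self, unit_grid):
        # 2:1 prolate spheroid, semi-axes (6, 6, 12) mm: analytic Wadell
        # sphericity 0.9287 from the closed-form spheroid surface area
        g = unit_grid((30, 30, 30))
        center = np.array([15.0, 15.0, 15.0])
        idx = np.argwhere(np.ones(g.shape, dtype=bool))
        u = (g.voxel_centers_mm(idx) - center) / np.array([6.0, 6.0, 12.0])
        inside = (u**2).sum(axis=1) <= 1.0
        les = Lesion(voxels=idx[inside], volume_cc=inside.sum() * g.voxel_volume_cc)
        a, c = 6.0, 12.0
        e = np.sqrt(1 - (a / c) ** 2)
        s_true = (
            np.pi ** (1 / 3)
            * (6 * 4 / 3 * np.pi * a * a * c) ** (2 / 3)
            / (2 * np.pi * a**2 * (1 + c / (a * e) * np.arcsin(e)))
        )
        s = compute_sphericity(les, g, method="mesh")
        assert s == pytest.approx(s_true, rel=0.03)

    def test_scale_invariance_of_mesh_sphericity(self, unit_grid):
        rng = np.random.default_rng(2)
        blob = np.argwhere(rng.random((8, 8, 8)) < 0.6)
        g1 = unit_grid((8, 8, 8), spacing=1.0)
        g2 = unit_grid((8, 8, 8), spacing=3.0)
        l1 = Lesion(voxels=blob, volume_cc=blob.shape[0] * g1.voxel_volume_cc)
        l2 = Lesion(voxels=blob, volume_cc=blob.shape[0] * g2.voxel_volume_cc)
        s1 = compute_sphericity(l1, g1, method="mesh")
        s2 = compute_sphericity(l2, g2, method="mesh")
        assert s1 == pytest.approx(s2, rel=1e-6)

    def test_single_voxel_mesh_falls_back_flagged(self, unit_grid):
        g = unit_grid((5, 5, 5))
        les = _one_voxel_lesion(g)
        s = compute_sphericity(les, g, method="mesh")
        # marching cubes handles a padded single voxel; either a valid mesh
        # value or the flagged voxel-face fallback is acceptable
        assert 0 < s <= 1.0


class TestInterfaceDistance:
    def test_slab_distances_are_planar(self, unit_grid):
        g = unit_grid((20, 20, 20))
        white = np.zeros(g.shape, dtype=bool)
        gray = np.zeros(g.shape, dtype=bool)
        white[:, :, :10] = True
        gray[:, :, 10:] = True
        dm = interface_distance_map(gray, white, g)
        # interface voxels: gray side z=10 and white side z=9
        assert dm.distance_mm[5, 5, 9] == 0 and dm.distance_mm[5, 5, 10] == 0
        for k in range(11, 20):
            assert dm.distance_mm[3, 7, k] == pytest.approx(k - 10)

    def test_interface_voxels_have_zero_distance(self, dmap):
        assert np.all(dmap.distance_mm[dmap.interface_voxels] == 0)

    def test_lipschitz_in_physical_coordinates(self, dmap, phantom):
        d = dmap.distance_mm
        for ax in range(3):
            step = np.abs(np.diff(d, axis=ax))
            assert step.max() <= phantom.grid.spacing_mm + 1e-9

    def test_matches_exhaustive_search_on_crops(self, unit_grid):
        rng = np.random.default_rng(3)
        for shape in [(12, 12, 12), (20, 16, 18)]:
            g = unit_grid(shape, spacing=1.5)
            gray = rng.random(shape) < 0.3
            white = ~gray & (rng.random(shape) < 0.4)
            dm = interface_distance_map(gray, white, g)
            ref = exhaustive_distance_map(dm.interface_voxels, 1.5)
            assert np.allclose(dm.distance_mm, ref, atol=1e-10)

    def test_disjointness_required(self, unit_grid):
        g = unit_grid((8, 8, 8))
        m = np.ones(g.shape, dtype=bool)
        with pytest.raises(ValueError):
            interface_distance_map(m, m, g)

    def test_no_adjacency_is_an_error(self, unit_grid):
        g = unit_grid((12, 12, 12))
        gray = np.zeros(g.shape, dtype=bool)
        white = np.zeros(g.shape, dtype=bool)
        gray[0:2, 0:2, 0:2] = True
        white[8:10, 8:10, 8:10] = True
        with pytest.raises(ValueError, match="interface"):
            interface_distance_map(gray, white, g)


class TestLesionDistanceAndMembership:
    def _slab_dmap(self, unit_grid):
        g = unit_grid((20, 20, 20))
        white = np.zeros(g.shape, dtype=bool)
        gray = np.zeros(g.shape, dtype=bool)
        white[:, :, :10] = True
        gray[:, :, 10:] = True
        return g, interface_distance_map(gray, white, g)

    def test_centroid_on_interface_is_zero(self, unit_grid):
        g, dm = self._slab_dmap(unit_grid)
        les = Lesion(voxels=np.array([(5, 5, 10)]), volume_cc=g.voxel_volume_cc)
        assert lesion_interface_distance(les, dm) == 0.0

    def test_slab_centroid_at_z15_is_5mm(self, unit_grid):
        g, dm = self._slab_dmap(unit_grid)
        les = Lesion(voxels=np.array([(5, 5, 15)]), volume_cc=g.voxel_volume_cc)
        assert lesion_interface_distance(les, dm) == pytest.approx(5.0)

    def test_matches_nearest_voxel_lookup(self, phantom, dmap):
        rng = np.random.default_rng(4)
        brain_idx = np.argwhere(phantom.parenchyma_mask)
        for _ in range(100):
            v = brain_idx[rng.integers(len(brain_idx))]
            les = Lesion(voxels=v[None, :], volume_cc=phantom.grid.voxel_volume_cc)
            d = lesion_interface_distance(les, dmap)
            assert d == dmap.distance_mm[tuple(v)]

    def test_membership_inside_region(self, unit_grid):
        g = unit_grid((10, 10, 10))
        atlas = np.zeros(g.shape, dtype=int)
        atlas[2:8, 2:8, 2:8] = 3
        les = Lesion(voxels=np.array([(4, 4, 4)]), volume_cc=g.voxel_volume_cc)
        assert assign_membership(les, atlas, g) == 3

    def test_membership_rescue_within_5mm(self, unit_grid):
        g = unit_grid((20, 20, 20))
        atlas = np.zeros(g.shape, dtype=int)
        atlas[10:15, 10:15, 10:15] = 7
        les = Lesion(voxels=np.array([(8, 12, 12)]), volume_cc=g.voxel_volume_cc)
        assert assign_membership(les, atlas, g) == 7  # 2 mm from region 7

    def test_membership_beyond_5mm_unassigned(self, unit_grid):
        g = unit_grid((30, 30, 30))
        atlas = np.zeros(g.shape, dtype=int)
        atlas[20:25, 20:25, 20:25] = 7
        les = Lesion(voxels=np.array([(2, 2, 2)]), volume_cc=g.voxel_volume_cc)
        assert assign_membership(les, atlas, g) == UNASSIGNED
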