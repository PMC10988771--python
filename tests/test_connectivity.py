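"""Electrode snapping, seed spheres, FC maps, surface projection and the
tumour-network statistic."""

import numpy as np
import pytest

import gliocircuit as g
from gliocircuit.connectivity import (
    _masked_gaussian_smooth,
    pearson_p_exact,
    world_coords,
)


class TestSnapping:
    def test_on_mask_coordinate_is_unchanged(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 3, 1] = True
        assert g.snap_electrode_to_cortex((2.0, 3.0, 1.0), mask, np.eye(4)) == (2, 3, 1)

    def test_tie_break_prefers_10mm_spacing(self):
        """Two candidates equidistant from the coordinate; the one 10 mm from
        the previously snapped electrode wins over the one 14 mm away."""
        mask = np.zeros((30, 5, 5), dtype=bool)
        mask[10, 2, 2] = True   # 10 mm from neighbour at x=0 (1 mm voxels)
        mask[14, 2, 2] = True   # 14 mm from neighbour
        coord = (12.0, 2.0, 2.0)  # equidistant (2 mm) from both
        chosen = g.snap_electrode_to_cortex(
            coord, mask, np.eye(4), snapped_neighbours_mm=[(0.0, 2.0, 2.0)]
        )
        assert chosen == (10, 2, 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(g.DegenerateInputError):
            g.snap_electrode_to_cortex((0, 0, 0), np.zeros((3, 3, 3), dtype=bool), np.eye(4))

    def test_distant_coordinate_warns_but_snaps(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.warns(UserWarning, match="mm"):
            out = g.snap_electrode_to_cortex((40.0, 0.0, 0.0), mask, np.eye(4))
        assert out == (0, 0, 0)


class TestSeedSphere:
    def test_lattice_count_at_radius_2_5(self):
        """On a 1-mm grid a 2.5-mm sphere at a voxel centre covers 81 voxels
        (brute-force count of integer offsets with |v| <= 2.5)."""
        brute = sum(
            1
            for dx in range(-3, 4)
            for dy in range(-3, 4)
            for dz in range(-3, 4)
            if dx * dx + dy * dy + dz * dz <= 2.5**2
        )
        mask = np.ones((9, 9, 9), dtype=bool)
        seed = g.make_seed((4, 4, 4), 2.5, mask, np.eye(4))
        assert len(seed.voxels) == brute == 81

    def test_sub_voxel_radius_keeps_only_centre(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        seed = g.make_seed((2, 2, 2), 0.4, mask, np.eye(4))
        np.testing.assert_array_equal(seed.voxels, [[2, 2, 2]])

    def test_parenchyma_masking_drops_out_of_mask_voxels(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        mask[5:, :, :] = False  # half-space removed
        seed = g.make_seed((4, 4, 4), 2.5, mask, np.eye(4))
        assert len(seed.voxels) < 81
        assert (seed.voxels[:, 0] <= 4).all()

    def test_empty_intersection_rejected(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[8, 8, 8] = True
        with pytest.raises(g.DegenerateInputError):
            g.make_seed((0, 0, 0), 1.0, mask, np.eye(4))


class TestFisherZ:
    def test_known_value(self):
        assert g.fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)

    def test_strictly_increasing_and_finite_at_unit_r(self):
        r = np.linspace(-1.0, 1.0, 201)
        z = g.fisher_z(r)
        assert np.all(np.diff(z) >= 0)
        assert np.isfinite(z).all()
        assert z[-1] == pytest.approx(np.arctanh(1 - 1e-7))


@pytest.fixture(scope="module")
def fc_setup(bold_world):
    masks = bold_world["masks"]
    seed_vox = np.argwhere(masks["tumour"])[0]
    seed = g.make_seed(seed_vox, 2.5, masks["parenchyma"], bold_world["affine"])
    return bold_world, seed


class TestSeedFC:
    def test_seed_self_correlation_is_clipped_finite(self, fc_setup):
        world, seed = fc_setup
        cmap = g.seed_fc_map(world["bold"], seed, world["masks"]["parenchyma"],
                             world["affine"], fwhm_mm=0.0)
        assert np.nanmax(np.abs(cmap.data)) <= np.arctanh(1 - 1e-7) + 1e-9

    def test_null_voxels_have_small_z(self, rng):
        """Independent white-noise voxels: |z| < 0.25 for >= 95% of voxels at
        200 time points (Fisher z null sd is about 1/sqrt(n-3))."""
        bold = rng.normal(size=(12, 12, 8, 200))
        parenchyma = np.ones(bold.shape[:3], dtype=bool)
        seed = g.make_seed((6, 6, 4), 0.4, parenchyma, np.eye(4))
        cmap = g.seed_fc_map(bold, seed, parenchyma, np.eye(4), fwhm_mm=0.0)
        z = cmap.data[parenchyma]
        z = z[np.abs(z) < 5]  # drop the seed voxel itself
        assert (np.abs(z) < 0.25).mean() >= 0.95

    def test_zero_variance_voxel_flagged_r_zero(self, rng):
        bold = rng.normal(size=(6, 6, 6, 50))
        bold[0, 0, 0, :] = 7.0
        parenchyma = np.ones((6, 6, 6), dtype=bool)
        seed = g.make_seed((3, 3, 3), 0.4, parenchyma, np.eye(4))
        cmap = g.seed_fc_map(bold, seed, parenchyma, np.eye(4), fwhm_mm=0.0)
        assert cmap.zero_variance[0, 0, 0]
        assert cmap.data[0, 0, 0] == 0.0

    def test_smoothing_preserves_spatial_mean(self, fc_setup):
        """Masked Gaussian smoothing is linear and mass-preserving over the
        mask interior: the parenchyma mean of (z + 1) changes by < 1%."""
        world, seed = fc_setup
        raw = g.seed_fc_map(world["bold"], seed, world["masks"]["parenchyma"],
                            world["affine"], fwhm_mm=0.0)
        mask = world["masks"]["parenchyma"]
        shifted = raw.data + 1.0
        smoothed = _masked_gaussian_smooth(shifted, mask, sigma_vox=np.array([1.0] * 3))
        before = np.nanmean(shifted[mask])
        after = np.nanmean(smoothed[mask])
        assert abs(after - before) / abs(before) < 0.01

    def test_value_at_world_coordinate_invariant_to_storage_order(self, fc_setup):
        """Permuting the storage axes (with the matching affine) leaves the
        map's value at any world coordinate unchanged."""
        world, _ = fc_setup
        bold, masks, affine = world["bold"], world["masks"], world["affine"]
        centre = np.argwhere(masks["tumour"])[0]
        seed = g.make_seed(centre, 2.5, masks["parenchyma"], affine)
        cmap = g.seed_fc_map(bold, seed, masks["parenchyma"], affine, fwhm_mm=5.0)

        perm = (2, 0, 1)
        P = np.zeros((4, 4))
        P[3, 3] = 1.0
        for new_axis, old_axis in enumerate(perm):
            P[old_axis, new_axis] = 1.0
        bold_p = np.transpose(bold, perm + (3,))
        affine_p = affine @ P
        masks_p = np.transpose(masks["parenchyma"], perm)
        seed_p = g.make_seed(centre[list(perm)], 2.5, masks_p, affine_p)
        cmap_p = g.seed_fc_map(bold_p, seed_p, masks_p, affine_p, fwhm_mm=5.0)
        np.testing.assert_allclose(
            cmap_p.data, np.transpose(cmap.data, perm), rtol=1e-9, atol=1e-12
        )


class TestVolumeToSurface:
    def test_constant_map_projects_constant(self, fc_setup, sphere_and_parcels):
        world, seed = fc_setup
        mesh, _ = sphere_and_parcels
        cmap = g.seed_fc_map(world["bold"], seed, world["masks"]["parenchyma"],
                             world["affine"], fwhm_mm=0.0)
        cmap.data[world["masks"]["parenchyma"]] = 2.5
        vm = mesh.vertices * 16.0  # parenchyma shell radius in mm
        smap = g.volume_to_surface(cmap, mesh, vm, max_dist_mm=6.0)
        assert smap.valid.all()
        np.testing.assert_allclose(smap.values, 2.5)

    def test_vertex_at_voxel_centre_takes_that_value(self, rng):
        data = rng.normal(size=(5, 5, 5))
        cmap = g.ConnectivityMap(data=data, affine=np.eye(4),
                                 parenchyma=np.ones((5, 5, 5), dtype=bool),
                                 zero_variance=np.zeros((5, 5, 5), dtype=bool))
        mesh = g.SurfaceMesh(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
                             np.array([[0, 1, 2]]))
        smap = g.volume_to_surface(cmap, mesh, np.array([[2.0, 3.0, 1.0]] * 3))
        assert smap.values[0] == data[2, 3, 1]

    def test_far_vertices_masked_invalid(self, rng):
        data = rng.normal(size=(4, 4, 4))
        cmap = g.ConnectivityMap(data=data, affine=np.eye(4),
                                 parenchyma=np.ones((4, 4, 4), dtype=bool),
                                 zero_variance=np.zeros((4, 4, 4), dtype=bool))
        mesh = g.SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))
        coords = np.array([[1.0, 1.0, 1.0], [30.0, 0.0, 0.0], [0.0, 40.0, 0.0]])
        smap = g.volume_to_surface(cmap, mesh, coords, max_dist_mm=3.0)
        np.testing.assert_array_equal(smap.valid, [True, False, False])
        with pytest.raises(g.DegenerateInputError):
            g.volume_to_surface(cmap, mesh, coords + 100.0, max_dist_mm=3.0)


class TestTumourNetwork:
    def test_coupled_network_survives_with_positive_mean(self, bold_world):
        res = g.tumour_network_connectivity(
            bold_world["bold"], bold_world["masks"]["tumour"],
            bold_world["masks"]["network_1"],
        )
        assert res.n_survivors == len(res.r)
        assert res.mean_connectivity == pytest.approx(0.51, abs=0.1)

    def test_noiseless_full_coupling_gives_r_one(self):
        bold, masks, _, _ = g.simulate_bold(
            g.BoldSimSpec(tumour_coupling={3: 1.0}, noise_sd=0.0, n_volumes=40, rng_seed=2)
        )
        res = g.tumour_network_connectivity(bold, masks["tumour"], masks["network_3"])
        assert res.n_survivors == len(res.r)
        assert res.mean_connectivity == pytest.approx(1.0, abs=1e-9)

    def test_null_coupling_yields_no_survivors(self, rng):
        """Bonferroni control: 500 independent null voxels, 200 time points."""
        bold = rng.normal(size=(10, 10, 10, 200))
        tumour = np.zeros((10, 10, 10), dtype=bool)
        tumour.ravel()[:500] = True
        network = np.zeros((10, 10, 10), dtype=bool)
        network[9, 9, 5:] = True
        res = g.tumour_network_connectivity(bold, tumour, network)
        assert res.n_overlap_excluded == 0
        assert len(res.r) == 500
        assert res.n_survivors == 0
        assert res.mean_connectivity is None

    def test_total_overlap_is_an_error(self, bold_world):
        tumour = bold_world["masks"]["network_2"].copy()
        with pytest.raises(g.DegenerateInputError, match="overlap"):
            g.tumour_network_connectivity(bold_world["bold"], tumour, tumour)

    def test_survivors_shrink_as_alpha_tightens(self, bold_world):
        bold = bold_world["bold"]
        masks = bold_world["masks"]
        counts = [
            g.tumour_network_connectivity(bold, masks["tumour"], masks["network_1"],
                                          alpha_fwer=a).n_survivors
            for a in (0.5, 0.05, 1e-8, 1e-30)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_exact_t_pvalue_matches_scipy(self, rng):
        r = rng.uniform(-0.9, 0.9, size=20)
        n = 30
        expected = [2 * __import__("scipy").stats.t.sf(abs(ri * np.sqrt((n - 2) / (1 - ri**2))), n - 2)
                    for ri in r]
        np.testing.assert_allclose(pearson_p_exact(r, n), expected, rtol=1e-12)


def test_world_coords_applies_affine():
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-10.0, 0.0, 5.0]
    np.testing.assert_allclose(world_coords(np.array([3, 4, 5]), affine), [[-4.0, 8.0, 15.0]])
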