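"""Membrane-channel reconstruction: smoothing, masking, region construction."""

import numpy as np
import pytest
from scipy import ndimage

import nanouptake as nu
from nanouptake.cell_reconstruction import NoCellFoundError


def _shell_stack(radius_um, voxel_size=(0.1, 0.1, 0.1), thickness_um=0.4,
                 margin_um=1.5, psf=(0.1, 0.1)):
    """Noiseless spherical-shell membrane stack (outer surface at radius_um)."""
    params = nu.ScenarioParams(
        cell_shape="sphere", cell_radius_um=radius_um, voxel_size=voxel_size,
        membrane_thickness_um=thickness_um, psf_sigma_um=psf,
        poisson_scale=0.0, read_noise_sd=0.0, background_level=0.0,
        field_margin_um=margin_um, seed=0,
    )
    membrane, _, _ = nu.generate_cell_stack(params)
    return membrane


class TestSmoothing:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(1)
        g = nu.VoxelGrid(rng.uniform(0, 100, (5, 12, 12)), (0.25, 0.11, 0.11))
        out = nu.smooth_membrane(g, nu.ReconstructionParams(smoothing_sigma_um=0.0))
        np.testing.assert_array_equal(out.data, g.data)

    def test_constant_stack_unchanged(self):
        g = nu.VoxelGrid(np.full((5, 12, 12), 7.0), (0.25, 0.11, 0.11))
        out = nu.smooth_membrane(g, nu.ReconstructionParams(smoothing_sigma_um=0.3))
        np.testing.assert_allclose(out.data, 7.0)

    def test_interior_blob_intensity_conserved(self):
        data = np.zeros((30, 40, 40))
        data[13:17, 18:23, 18:23] = 50.0
        g = nu.VoxelGrid(data, (0.25, 0.11, 0.11))
        out = nu.smooth_membrane(g, nu.ReconstructionParams(smoothing_sigma_um=0.2))
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-3)


class TestCellMask:
    def test_sphere_volume_matches_analytic(self):
        membrane = _shell_stack(8.0)
        params = nu.ReconstructionParams(smoothing_sigma_um=0.0)
        mask = nu.make_cell_mask(membrane, params)
        volume = mask.sum() * 0.1**3
        assert volume == pytest.approx(4 / 3 * np.pi * 8.0**3, rel=0.05)

    def test_all_zero_stack_raises(self):
        g = nu.VoxelGrid(np.zeros((5, 16, 16)), (0.25, 0.11, 0.11))
        with pytest.raises(NoCellFoundError):
            nu.make_cell_mask(g, nu.ReconstructionParams())

    def test_larger_of_two_cells_kept(self):
        # two disjoint spherical shells drawn by hand in one stack
        shape, vs = (60, 120, 60), (0.2, 0.2, 0.2)
        zz, yy, xx = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, vs)],
                                 indexing="ij")
        data = np.zeros(shape)
        for center, r in [((6.0, 7.0, 6.0), 5.0), ((6.0, 18.0, 6.0), 3.0)]:
            d = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                        + (xx - center[2]) ** 2)
            data[(d <= r) & (d >= r - 0.5)] = 1000.0
        g = nu.VoxelGrid(data, vs)
        mask = nu.make_cell_mask(g, nu.ReconstructionParams(smoothing_sigma_um=0.0))
        com = ndimage.center_of_mass(mask)
        assert com[1] * vs[1] == pytest.approx(7.0, abs=0.5)  # the r=5 cell
        assert mask.sum() * np.prod(vs) == pytest.approx(4 / 3 * np.pi * 125, rel=0.15)

    def test_otsu_scale_invariant(self):
        membrane = _shell_stack(5.0, voxel_size=(0.2, 0.2, 0.2))
        params = nu.ReconstructionParams(smoothing_sigma_um=0.0)
        m1 = nu.make_cell_mask(membrane, params)
        m2 = nu.make_cell_mask(membrane.with_data(membrane.data * 7.3), params)
        np.testing.assert_array_equal(m1, m2)


class TestRegions:
    def test_sphere_shell_thickness_and_intra_radius(self):
        membrane = _shell_stack(8.0)
        mask = nu.make_cell_mask(membrane, nu.ReconstructionParams(smoothing_sigma_um=0.0))
        regions = nu.build_regions(mask, 1.4, membrane.voxel_size)
        th = nu.measure_shell_thickness(regions, n_rays=100)
        assert th.mean() == pytest.approx(1.4, abs=0.2)
        r_intra = (3 * regions.intracellular.sum() * 0.1**3 / (4 * np.pi)) ** (1 / 3)
        assert r_intra == pytest.approx(7.3, abs=0.3)

    def test_one_voxel_shell_is_single_erosion_of_cube(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[5:15, 5:15, 5:15] = True
        vs = (0.2, 0.2, 0.2)
        regions = nu.build_regions(mask, 2 * 0.2, vs)
        eroded = ndimage.binary_erosion(
            mask, structure=ndimage.generate_binary_structure(3, 1)
        )
        np.testing.assert_array_equal(regions.intracellular, eroded)

    def test_anisotropic_shell_thickness_equal_along_axes(self):
        membrane = _shell_stack(4.0, voxel_size=(0.25, 0.1, 0.1), margin_um=1.2)
        mask = nu.make_cell_mask(membrane, nu.ReconstructionParams(smoothing_sigma_um=0.0))
        regions = nu.build_regions(mask, 1.4, membrane.voxel_size)
        center = np.round(ndimage.center_of_mass(mask)).astype(int)
        z_profile = regions.membrane_shell[:, center[1], center[2]]
        x_profile = regions.membrane_shell[center[0], center[1], :]
        half = len(z_profile) // 2
        z_thick = z_profile[half:].sum() * 0.25
        x_thick = x_profile[x_profile.size // 2:].sum() * 0.1
        assert abs(z_thick - x_thick) <= 0.25 + 1e-9  # within one (z) voxel

    def test_thin_cell_warns_empty_intracellular(self):
        mask = np.zeros((10, 20, 20), bool)
        mask[4:6, 5:15, 5:15] = True  # 0.4 µm thick slab at 0.2 µm voxels
        with pytest.warns(UserWarning, match="thinner"):
            regions = nu.build_regions(mask, 1.4, (0.2, 0.2, 0.2))
        assert not regions.intracellular.any()


def _random_blob(rng, shape=(36, 36, 36)):
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=6)
    mask = smooth > np.quantile(smooth, 0.8)
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())[1:]
    blob = labels == (1 + counts.argmax())
    blob[:2], blob[-2:] = False, False
    blob[:, :2], blob[:, -2:] = False, False
    blob[:, :, :2], blob[:, :, -2:] = False, False
    return blob


class TestRegionInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_partition_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        mask = _random_blob(rng)
        if mask is None or mask.sum() < 50:
            pytest.skip("degenerate random geometry")
        vs = (0.25, 0.1, 0.1)
        narrow = nu.build_regions(mask, 0.8, vs)
        wide = nu.build_regions(mask, 1.6, vs)
        for r in (narrow, wide):
            total = (r.intracellular.astype(int) + r.membrane_shell.astype(int)
                     + r.extracellular.astype(int))
            assert (total == 1).all()
        # a wider shell contains the narrow shell, and shrinks both other regions
        assert (wide.membrane_shell | ~narrow.membrane_shell).all()
        assert not np.any(wide.intracellular & ~narrow.intracellular)
        assert not np.any(wide.extracellular & ~narrow.extracellular)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_isotropic_matches_ball_morphology(self, seed):
        from skimage.morphology import ball

        rng = np.random.default_rng(100 + seed)
        mask = _random_blob(rng, shape=(32, 32, 32))
        if mask is None or mask.sum() < 50:
            pytest.skip("degenerate random geometry")
        w, a = 4.0, 1.0  # shell width 4 voxels on a unit isotropic grid
        regions = nu.build_regions(mask, w, (a, a, a))
        selem = ball(int(w // 2))
        dilated = ndimage.binary_dilation(mask, structure=selem)
        eroded = ndimage.binary_erosion(mask, structure=selem)
        np.testing.assert_array_equal(regions.membrane_shell, dilated & ~eroded)
        np.testing.assert_array_equal(regions.intracellular, eroded)
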