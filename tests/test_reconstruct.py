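"""Image products: confocal, PSF, enhancement, tiling, MIP, z-scan."""

import warnings

import numpy as np
import pytest

from conjclass.basis import from_conjugate_basis, to_conjugate_basis
from conjclass.geometry import AcquisitionGeometry, Grid, GridMismatchError
from conjclass.matrix import ReflectionMatrix
from conjclass.metrics import airy_fwhm_amplitude
from conjclass.reconstruct import (TileLayout, accumulate_spectrum,
                                   confocal_image, estimate_psf,
                                   max_intensity_projection,
                                   scan_conjugate_distance,
                                   signal_enhancement, tile_and_merge)
from conjclass.screens import ScreenSpec, make_test_object
from conjclass.simulate import simulate_reflection_matrix
from conjclass.solver import SolverConfig, run_conjugate_class
from conftest import gauss_blobs


@pytest.fixture(scope="module")
def dp_geo_local():
    return AcquisitionGeometry(sample_pixel_pitch=0.65, scan_step=0.65,
                               scan_shape=(8, 8), detection_extent=0.65 * 128,
                               conjugate_distance=40.0)


@pytest.fixture(scope="module")
def dp_point(dp_geo_local):
    """Unaberrated double-pass matrix of a single point reflector."""
    grid = dp_geo_local.detection_grid()
    obj, _ = make_test_object("point_scatterers", grid,
                              {"positions": [(0.0, 0.0)]})
    return simulate_reflection_matrix(obj, None, dp_geo_local,
                                      model="double_pass",
                                      basis="sample", effective_na=0.35)


@pytest.fixture(scope="module")
def dp_mirror(dp_geo_local):
    """Unaberrated double-pass matrix of a uniform reflector — the
    shift-invariant case the aligned-mean PSF estimator assumes."""
    grid = dp_geo_local.detection_grid()
    return simulate_reflection_matrix(np.ones(grid.shape), None, dp_geo_local,
                                      model="double_pass",
                                      basis="sample", effective_na=0.35)


class TestConfocal:
    def test_point_reflector_lights_one_pixel(self, dp_point):
        img, cgrid = confocal_image(dp_point.matrix)
        iy, ix = np.unravel_index(img.argmax(), img.shape)
        y, x = cgrid.axes()
        assert abs(y[iy]) < 0.7 and abs(x[ix]) < 0.7
        assert img.max() > 10 * np.median(img)

    def test_missing_diagonal_sample_raises(self, geo_tiny):
        grid = Grid.centered((4, 4), 0.65)  # too small to hold the scan
        n = geo_tiny.scan_shape[0] ** 2
        fields = np.ones((n, 4, 4), complex)
        m = ReflectionMatrix(fields, geo_tiny.scan_positions(), grid, geo_tiny,
                             basis="sample", descanned=False)
        with pytest.raises(GridMismatchError):
            confocal_image(m)


class TestPSF:
    def test_unaberrated_width_matches_airy_closed_form(self, dp_mirror):
        psf = estimate_psf(dp_mirror.matrix, upsample=4)
        expected = airy_fwhm_amplitude(1.3, 0.35)
        assert psf["defined"]
        assert abs(psf["fwhm"] - expected) / expected < 0.2

    def test_symmetric_psf_has_equal_cuts(self, dp_mirror):
        psf = estimate_psf(dp_mirror.matrix, upsample=4)
        assert abs(psf["fwhm_x"] - psf["fwhm_y"]) < 0.65  # within one pixel

    def test_undefined_width_reported_as_infinite(self, geo_tiny):
        n = geo_tiny.scan_shape[0] ** 2
        grid = geo_tiny.detection_grid()
        m = ReflectionMatrix(np.ones((n,) + grid.shape, complex),
                             geo_tiny.scan_positions(), grid, geo_tiny,
                             basis="sample", descanned=False)
        psf = estimate_psf(m, upsample=1)
        assert not psf["defined"]
        assert psf["fwhm"] == float("inf")


class TestEnhancement:
    def test_identical_reconstructions_give_unity(self, geo_tiny):
        grid = geo_tiny.detection_grid()
        res = simulate_reflection_matrix(gauss_blobs(grid, 2.0, 1, 3, 4),
                                         ScreenSpec(1.0, 3.0, seed=2),
                                         geo_tiny, basis="conjugate")
        rec = accumulate_spectrum(res.matrix)
        out = signal_enhancement(rec, rec)
        assert out["peak_ratio"] == pytest.approx(1.0)
        assert out["energy_ratio"] == pytest.approx(1.0)

    def test_zero_before_energy_raises(self, geo_tiny):
        grid = geo_tiny.detection_grid()
        res = simulate_reflection_matrix(gauss_blobs(grid, 2.0, 1, 3, 4),
                                         None, geo_tiny, basis="conjugate")
        rec = accumulate_spectrum(res.matrix)
        import copy
        dead = copy.deepcopy(rec)
        dead.spectrum[:] = 0
        with pytest.raises(ValueError):
            signal_enhancement(dead, rec)

    def test_decrease_triggers_warning(self, geo_tiny):
        grid = geo_tiny.detection_grid()
        res = simulate_reflection_matrix(gauss_blobs(grid, 2.0, 1, 3, 4),
                                         None, geo_tiny, basis="conjugate")
        rec = accumulate_spectrum(res.matrix)
        import copy
        weak = copy.deepcopy(rec)
        weak.spectrum = 0.1 * weak.spectrum
        with pytest.warns(RuntimeWarning):
            signal_enhancement(rec, weak)


class TestTiling:
    def test_default_layout_reproduces_the_instrument_grid(self):
        # 160 μm field, 64 μm tiles, 50% overlap → 5×5 subregions
        lay = TileLayout(tile_size=64.0, overlap=0.5)
        origins = lay.grid_for_field((160.0, 160.0), (-80.0, -80.0))
        assert origins.shape == (25, 2)

    def test_weights_form_a_partition_of_unity(self):
        lay = TileLayout(tile_size=16.0, overlap=0.5)
        x = np.linspace(-40, 40, 801)
        total = np.zeros_like(x)
        for x0 in np.arange(-40, 32, 8.0):
            total += lay.weight_profile(x, x0)
        interior = (x > -30) & (x < 20)
        assert np.abs(total[interior] - 1.0).max() < 1e-12

    def test_overlap_bounds_enforced(self):
        with pytest.raises(ValueError):
            TileLayout(tile_size=10.0, overlap=0.95)

    def test_sparse_tiles_are_skipped_with_warning(self, geo_standard):
        grid = geo_standard.detection_grid()
        res = simulate_reflection_matrix(gauss_blobs(grid, 3.0, 2, 4, 4),
                                         None, geo_standard, basis="sample")
        lay = TileLayout(tile_size=1.3, overlap=0.0)  # 2×2 columns per tile
        with pytest.warns(RuntimeWarning, match="skipped"):
            out = tile_and_merge(res.matrix, lay,
                                 SolverConfig(max_iterations=2), z=100.0)
        assert out["tiles"] == []


class TestMIP:
    def test_single_slice_range_returns_that_slice(self):
        imgs = [np.full((4, 4), v) for v in (1.0, 2.0, 3.0)]
        out = max_intensity_projection(imgs, [0, 3, 6], (2.9, 3.1))
        assert np.array_equal(out, imgs[1])

    def test_projection_keeps_every_bright_voxel(self):
        imgs = []
        for i in range(5):
            im = np.zeros((8, 8))
            im[i, i] = 1.0
            imgs.append(im)
        out = max_intensity_projection(imgs, [0, 3, 6, 9, 12], (0, 12))
        assert all(out[i, i] == 1.0 for i in range(5))

    def test_slice_count_for_interval_sampling(self):
        # 3 μm steps spanning a ±15 μm window select 11 slices
        depths = np.arange(0, 31, 3.0)
        imgs = [np.zeros((2, 2)) + d for d in depths]
        sel = [d for d in depths if 0 <= d <= 30]
        assert len(sel) == 11
        out = max_intensity_projection(imgs, depths, (0, 30))
        assert out[0, 0] == 30.0

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            max_intensity_projection([np.zeros((2, 2))], [5.0], (10, 20))


class TestScanZ:
    def test_single_candidate_is_returned_trivially(self, geo_tiny):
        grid = geo_tiny.detection_grid()
        res = simulate_reflection_matrix(gauss_blobs(grid, 2.0, 1, 3, 4),
                                         ScreenSpec(1.0, 3.0, seed=4),
                                         geo_tiny, basis="sample")
        out = scan_conjugate_distance(res.matrix, [100.0],
                                      SolverConfig(max_iterations=3))
        assert out["best_z"] == 100.0
        assert np.all(np.isfinite(out["metric"])) and np.all(out["metric"] > 0)
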