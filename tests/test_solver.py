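"""Solver core: shear bookkeeping, inner-product oracles, recovery, gauge."""

import numpy as np
import pytest

from conjclass.basis import from_conjugate_basis, to_conjugate_basis
from conjclass.geometry import AcquisitionGeometry, Grid
from conjclass.matrix import ReflectionMatrix, wrap_phase
from conjclass.reconstruct import accumulate_spectrum
from conjclass.screens import ScreenSpec, make_test_object
from conjclass.simulate import simulate_reflection_matrix
from conjclass.solver import (SolverConfig, apply_phase_correction,
                              decompose_aberration, estimate_input_phase,
                              estimate_output_phase, run_conjugate_class,
                              shear_to_W, unshear)
from conjclass.metrics import circular_rms, image_correlation


def _toy_matrix(n_side=4, win=6, seed=0):
    """Random complex toy matrix in conjugate basis on a tiny lattice."""
    rng = np.random.default_rng(seed)
    geo = AcquisitionGeometry(sample_pixel_pitch=1.0, scan_step=1.0,
                              scan_shape=(n_side, n_side),
                              detection_extent=float(win),
                              conjugate_distance=50.0)
    grid = Grid.centered((win, win), 1.0)
    fields = rng.standard_normal((n_side**2, win, win)) \
        + 1j * rng.standard_normal((n_side**2, win, win))
    return ReflectionMatrix(fields, geo.scan_positions(), grid, geo,
                            basis="conjugate", descanned=False)


def _brute_force_input_phases(sheared, reference):
    """Independent double-loop over W coordinates using dicts."""
    n, ny, nx = sheared.fields.shape
    maps = []
    for i in range(n):
        oy, ox = sheared.offsets[i]
        d = {(oy + iy, ox + ix): sheared.fields[i, iy, ix]
             for iy in range(ny) for ix in range(nx)}
        maps.append(d)
    z = np.zeros(n, complex)
    if reference == "zero":
        ref = maps[sheared.gauge_column]
        for i in range(n):
            z[i] = sum(v * np.conj(ref[w]) for w, v in maps[i].items() if w in ref)
    else:
        for i in range(n):
            acc = 0.0 + 0.0j
            for w, v in maps[i].items():
                s = sum(maps[j][w] for j in range(n) if j != i and w in maps[j])
                acc += v * np.conj(s)
            z[i] = acc
    phase = np.where(np.abs(z) > 0, np.angle(z), 0.0)
    phase = wrap_phase(phase - phase[sheared.gauge_column])
    phase[sheared.gauge_column] = 0.0
    return phase


def _brute_force_output_phases(sheared, reference):
    n, ny, nx = sheared.fields.shape
    z = np.zeros((ny, nx), complex)
    if reference == "zero":
        gy, gx = ny // 2, nx // 2
        for dy in range(ny):
            for dx in range(nx):
                acc = 0.0 + 0.0j
                for i in range(n):
                    # W match: offsets[j] == offsets[i] + (p − p0)
                    tgt = (sheared.offsets[i][0] + dy - gy,
                           sheared.offsets[i][1] + dx - gx)
                    for j in range(n):
                        if tuple(sheared.offsets[j]) == tgt:
                            acc += sheared.fields[i, dy, dx] * np.conj(
                                sheared.fields[j, gy, gx])
                z[dy, dx] = acc
    else:
        s, _ = sheared.accumulate()
        for i in range(n):
            oy, ox = sheared.offsets[i]
            view = s[oy:oy + ny, ox:ox + nx]
            z += sheared.fields[i] * np.conj(view - sheared.fields[i])
    gy, gx = ny // 2, nx // 2
    phase = np.where(np.abs(z) > 0, np.angle(z), 0.0)
    phase = wrap_phase(phase - phase[gy, gx])
    phase[gy, gx] = 0.0
    phase[np.abs(z) == 0] = 0.0
    return phase


class TestShear:
    def test_shear_then_unshear_is_bit_exact(self):
        m = _toy_matrix()
        sh = shear_to_W(m)
        back = unshear(sh, m)
        assert np.array_equal(back.fields, m.fields)

    def test_single_column_keeps_its_indexing(self):
        m = _toy_matrix(n_side=1)
        sh = shear_to_W(m)
        assert sh.w_grid.shape == m.grid.shape
        assert np.array_equal(sh.fields[0], m.fields[0])

    def test_sample_basis_matrix_rejected(self, geo_tiny):
        grid = geo_tiny.detection_grid()
        m = simulate_reflection_matrix(np.ones(grid.shape), None, geo_tiny,
                                       basis="sample").matrix
        with pytest.raises(ValueError, match="conjugate or pupil"):
            shear_to_W(m)


class TestPhaseEstimationOracles:
    @pytest.mark.parametrize("reference", ["zero", "sum"])
    def test_input_phase_matches_brute_force(self, reference):
        sh = shear_to_W(_toy_matrix(seed=5))
        phase, weight = estimate_input_phase(sh, reference=reference)
        ref = _brute_force_input_phases(sh, reference)
        assert np.abs(wrap_phase(phase - ref)).max() < 1e-12

    @pytest.mark.parametrize("reference", ["zero", "sum"])
    def test_output_phase_matches_brute_force(self, reference):
        sh = shear_to_W(_toy_matrix(seed=6))
        phase, weight = estimate_output_phase(sh, reference=reference)
        ref = _brute_force_output_phases(sh, reference)
        assert np.abs(wrap_phase(phase - ref)).max() < 1e-12

    def test_identical_columns_give_zero_phase(self):
        m = _toy_matrix(seed=7)
        m.keys[:] = 0.0  # all columns at the same lattice point
        m.fields[:] = m.fields[0]
        m.key_pitch = 0.0
        sh = shear_to_W(m)
        phase, _ = estimate_input_phase(sh, reference="zero")
        assert np.abs(phase).max() < 1e-12

    def test_pure_input_phase_recovered_in_one_step(self):
        # with no output aberration the inner-product angle reduces to
        # the input phase exactly
        rng = np.random.default_rng(8)
        m = _toy_matrix(n_side=4, win=8, seed=8)
        base = rng.standard_normal(m.grid.shape) + 1j * rng.standard_normal(m.grid.shape)
        phi_true = rng.uniform(-np.pi, np.pi, m.n_in)
        sh0 = shear_to_W(m)
        for i in range(m.n_in):
            oy, ox = sh0.offsets[i]
            canvas = np.zeros((14, 14), complex)
            canvas[:] = 0
            # column i sees the common W-spectrum restricted to its window
            full = np.pad(base, ((0, 6), (0, 6)))
            m.fields[i] = np.exp(1j * phi_true[i]) * full[oy:oy + 8, ox:ox + 8]
        sh = shear_to_W(m)
        phase, _ = estimate_input_phase(sh, reference="zero")
        expect = wrap_phase(phi_true - phi_true[sh.gauge_column])
        assert np.abs(wrap_phase(phase - expect)).max() < 1e-9


@pytest.fixture(scope="module")
def zero_aberration_run(geo_standard):
    grid = geo_standard.detection_grid()
    obj, _ = make_test_object("point_scatterers", grid, {"n": 30, "seed": 5})
    res = simulate_reflection_matrix(obj, None, geo_standard, basis="conjugate")
    out = run_conjugate_class(res.matrix,
                              SolverConfig(max_iterations=30, tolerance=1e-4))
    return res, out


class TestConjugateSolver:
    def test_zero_screen_leaves_only_the_quadratic_phase(self, zero_aberration_run):
        res, out = zero_aberration_run
        est = out["estimate"]
        assert circular_rms(est.phi_in, est.phi_quad_in, est.in_grid) < 0.05
        assert circular_rms(est.phi_out, est.phi_quad_out, est.out_grid) < 0.05

    def test_gauge_pixels_are_exactly_zero(self, zero_aberration_run):
        _, out = zero_aberration_run
        est = out["estimate"]
        gy, gx = est.in_grid.shape[0] // 2, est.in_grid.shape[1] // 2
        assert est.phi_in[gy, gx] == 0.0
        oy, ox = est.out_grid.shape[0] // 2, est.out_grid.shape[1] // 2
        assert est.phi_out[oy, ox] == 0.0

    def test_spectrum_energy_is_monotone_on_noise_free_input(self, geo_standard):
        grid = geo_standard.detection_grid()
        obj, _ = make_test_object("usaf_bars", grid, {"period_px": 8})
        res = simulate_reflection_matrix(obj, ScreenSpec(2.0, 5.0, seed=13),
                                         geo_standard, basis="conjugate")
        out = run_conjugate_class(res.matrix,
                                  SolverConfig(max_iterations=20, tolerance=1e-6))
        e = np.asarray(out["estimate"].spectrum_energy)
        assert np.all(np.diff(e) >= -1e-9 * e[:-1])

    def test_coherent_gain_identity_with_true_phases(self, geo_standard):
        grid = geo_standard.detection_grid()
        obj, _ = make_test_object("usaf_bars", grid, {"period_px": 8})
        res = simulate_reflection_matrix(obj, ScreenSpec(2.0, 5.0, seed=14),
                                         geo_standard, basis="conjugate")
        cor = apply_phase_correction(res.matrix, res.truth["phi_in_columns"],
                                     res.truth["phi_o_map"])
        sh = shear_to_W(cor)
        s, cnt = sh.accumulate()
        full = cnt == sh.n_in
        oy, ox = sh.offsets[0]
        ny, nx = sh.window
        sview = s[oy:oy + ny, ox:ox + nx]
        fview = full[oy:oy + ny, ox:ox + nx]
        ratio = np.abs(sview[fview]) / (sh.n_in * np.abs(cor.fields[0][fview]))
        assert np.abs(ratio - 1).max() < 1e-6

    def test_screen_recovery_on_simulated_truth(self, geo_standard):
        grid = geo_standard.detection_grid()
        obj, _ = make_test_object("usaf_bars", grid, {"period_px": 8})
        res = simulate_reflection_matrix(obj, ScreenSpec(2.0, 10.0, seed=21),
                                         geo_standard, basis="conjugate")
        out = run_conjugate_class(res.matrix, SolverConfig(max_iterations=30))
        est = out["estimate"]
        truth = np.array([res.truth["screen"][grid.index_of(tuple(k))]
                          for k in res.matrix.keys]).reshape(est.in_grid.shape)
        from conjclass.metrics import phase_recovery_metric
        assert phase_recovery_metric(est.phi_screen_in, truth, est.in_grid) > 0.99

    def test_tilted_screen_translates_the_object_only(self, geo_standard):
        grid = geo_standard.detection_grid()
        from conftest import gauss_blobs
        obj = gauss_blobs(grid, sigma_px=3.0, seed=2, n=5)
        base = ScreenSpec(1.0, 10.0, seed=17)
        phi0 = np.zeros(grid.shape)
        from conjclass.screens import make_phase_screen
        phi0 = make_phase_screen(base, grid)
        yy, xx = grid.mesh()
        a = 0.12  # rad/μm tilt along x
        cfg = SolverConfig(max_iterations=30)
        imgs = []
        for phi in (phi0, phi0 + a * xx):
            res = simulate_reflection_matrix(obj, ScreenSpec(phase_map=phi),
                                             geo_standard, basis="conjugate")
            out = run_conjugate_class(res.matrix, cfg)
            imgs.append(np.abs(out["reconstruction"].reflectance))
        # pattern intact up to a lateral shift
        assert image_correlation(imgs[1], imgs[0], align=True) > 0.95


class TestDecompose:
    def test_quadratic_phase_closed_form(self, geo_standard):
        z = geo_standard.conjugate_distance
        k = geo_standard.wavenumber
        w_pi = np.sqrt(2 * z * np.pi / k)
        # evaluate (k/2z)|w|² at |w| = sqrt(2πz/k): exactly π
        assert (k / (2 * z)) * w_pi**2 == pytest.approx(np.pi)

    def test_pure_quadratic_estimate_has_zero_screen_part(self, geo_standard):
        in_grid = Grid.centered((16, 16), 0.65)
        out_grid = geo_standard.detection_grid()
        k, z = geo_standard.wavenumber, geo_standard.conjugate_distance
        from conjclass.matrix import AberrationEstimate
        est = AberrationEstimate(
            phi_in=wrap_phase((k / (2 * z)) * in_grid.rsq()),
            phi_out=wrap_phase((k / (2 * z)) * out_grid.rsq()),
            in_grid=in_grid, out_grid=out_grid)
        decompose_aberration(est, geo_standard)
        assert np.abs(est.phi_screen_in).max() < 1e-9
        assert np.abs(est.phi_screen_out).max() < 1e-9
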