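"""Physical forward models producing synthetic reflection matrices.

Two forward models are provided:

``analytic``
    Evaluates the conjugate-basis matrix model exactly on the lattice:

        E(w_o; w_in) = -(e^{2ikz}/λ²z²) e^{iφ_in(w_in)}
                        Õ_M(k(w_o+w_in)/z) e^{iφ_o(w_o)} + E_M,

    with φ(w) = φ_s(w) + (k/2z)|w|² and Õ_M the Fourier transform of
    O(r)·exp{i(k/z)|r|²}, evaluated by an exact chirp DFT.  This is the
    model the solver assumes, so it serves as the solver-matched oracle.

``double_pass``
    Physically propagates a focused, NA-limited illumination through the
    phase screen to the object and back (Fresnel transfer-function
    propagation), including the detection-side NA filter.  Independent of
    the solver's approximations; used as the physics cross-check.

Multiple-scattering noise E_M is circular complex Gaussian, scaled to a
requested power ratio relative to the ballistic signal.  Ground truth
(object, screen, per-column phases, seeds) is recorded alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .basis import from_conjugate_basis, from_pupil_basis, to_conjugate_basis, _momentum_grid
from .chirpdft import q_axes_for_w_grid, spectrum_from_object
from .geometry import AcquisitionGeometry, AliasingError, Grid, validate_geometry
from .matrix import ReflectionMatrix
from .propagate import fresnel_transform_stack, max_distance_without_aliasing
from .screens import NoiseSpec, ScreenSpec, make_phase_screen

__all__ = ["simulate_reflection_matrix", "simulate_pupil_aberrated_matrix",
           "SimulationResult"]


@dataclass
class SimulationResult:
    """A simulated matrix together with its ground truth."""

    matrix: ReflectionMatrix
    truth: Dict = field(default_factory=dict)


def _global_grid(geometry: AcquisitionGeometry) -> Grid:
    return geometry.detection_grid()


def _screen_on_grid(screen_spec: Optional[ScreenSpec], grid: Grid) -> np.ndarray:
    if screen_spec is None:
        return np.zeros(grid.shape)
    return make_phase_screen(screen_spec, grid)


def _sample_at_keys(map2d: np.ndarray, grid: Grid, keys: np.ndarray) -> np.ndarray:
    vals = np.empty(len(keys))
    for i, key in enumerate(keys):
        iy, ix = grid.index_of(tuple(key))
        vals[i] = map2d[iy, ix]
    return vals


def _add_noise(fields: np.ndarray, noise: Optional[NoiseSpec]) -> np.ndarray:
    if noise is None or noise.multiple_scattering_power_ratio == 0:
        return np.zeros_like(fields)
    rng = np.random.default_rng(noise.seed)
    ballistic = np.mean(np.abs(fields) ** 2)
    sigma = np.sqrt(noise.multiple_scattering_power_ratio * ballistic / 2.0)
    em = sigma * (rng.standard_normal(fields.shape)
                  + 1j * rng.standard_normal(fields.shape))
    return em


def simulate_reflection_matrix(obj: np.ndarray,
                               screen: Optional[ScreenSpec],
                               geometry: AcquisitionGeometry,
                               noise: Optional[NoiseSpec] = None,
                               model: str = "analytic",
                               basis: str = "conjugate",
                               effective_na: float = 0.25,
                               check_sampling: bool = True,
                               screen_in: Optional[ScreenSpec] = None) -> SimulationResult:
    """Simulate a reflection matrix for a known object and phase screen.

    Parameters
    ----------
    obj:
        Real non-negative reflectance O(r) on the geometry's detection grid
        (used as the global sample-plane grid; the scan lattice must fit
        inside it).
    screen:
        ScreenSpec for the aberrating layer at ``geometry.conjugate_distance``
        (None = no aberration).
    noise:
        NoiseSpec for the multiple-scattering term (None = noise-free).
    model:
        ``analytic`` or ``double_pass``.
    basis:
        Basis of the returned matrix: ``conjugate`` or ``sample``.
    effective_na:
        NA used for the simulated focus/detection filter in the
        ``double_pass`` model (kept paraxial; the lattice cannot support
        the experimental NA without vectorial optics).
    """
    grid = _global_grid(geometry)
    obj = np.asarray(obj, dtype=np.float64)
    if obj.shape != grid.shape:
        raise ValueError(f"object shape {obj.shape} != detection grid {grid.shape}")
    problems = validate_geometry(geometry, conjugate=(model == "analytic"
                                                      and check_sampling))
    if any("aliases" in p for p in problems):
        # The analytic model evaluates the conjugate-plane quadratic phase
        # on the lattice; an undersampled chirp would make the emitted
        # matrix unrepresentative of any physical field.
        raise AliasingError("; ".join(p for p in problems if "aliases" in p))
    if problems:
        raise ValueError("; ".join(problems))
    if model == "double_pass":
        dmax = max_distance_without_aliasing(geometry.detection_shape,
                                             geometry.sample_pixel_pitch,
                                             geometry.wavelength,
                                             geometry.medium_index)
        if geometry.conjugate_distance > dmax:
            raise AliasingError(
                f"double-pass propagation over z={geometry.conjugate_distance} μm "
                f"aliases the transfer function (limit {dmax:.1f} μm on this grid); "
                f"enlarge the detection window or reduce z")

    keys = geometry.scan_positions()
    z = geometry.conjugate_distance
    k = geometry.wavenumber
    lam = geometry.wavelength_medium
    screen_map = _screen_on_grid(screen, grid)
    # In the model the input and output retardations are treated as
    # independent unknowns; physically they share one screen (reciprocity),
    # which is the default, but an explicit ``screen_in`` breaks the
    # symmetry (e.g. illumination/detection path mismatch).
    screen_map_in = screen_map if screen_in is None else _screen_on_grid(screen_in, grid)
    quad_map = (k / (2 * z)) * grid.rsq()
    phi_o_map = screen_map + quad_map
    phi_in_cols = (_sample_at_keys(screen_map_in, grid, keys)
                   + (k / (2 * z)) * (keys ** 2).sum(axis=1))

    if model == "analytic":
        fields = _analytic_fields(obj, grid, keys, geometry, phi_o_map, phi_in_cols)
        em = _add_noise(fields, noise)
        fields = fields + em
        matrix = ReflectionMatrix(fields, keys, grid, geometry,
                                  basis="conjugate", descanned=False,
                                  key_pitch=geometry.scan_step)
        if basis == "sample":
            matrix = from_conjugate_basis(matrix)
        elif basis != "conjugate":
            raise ValueError(f"unknown basis {basis!r}")
    elif model == "double_pass":
        if screen_in is not None:
            raise ValueError("double_pass physically shares one screen; "
                             "screen_in applies to the analytic model only")
        fields = _double_pass_fields(obj, grid, keys, geometry, screen_map,
                                     effective_na)
        em = _add_noise(fields, noise)
        fields = fields + em
        matrix = ReflectionMatrix(fields, keys, grid, geometry,
                                  basis="sample", descanned=False,
                                  key_pitch=geometry.scan_step)
        if basis == "conjugate":
            matrix = to_conjugate_basis(matrix, z)
        elif basis != "sample":
            raise ValueError(f"unknown basis {basis!r}")
    else:
        raise ValueError(f"unknown model {model!r}")

    truth = {
        "object": obj.copy(),
        "object_grid": grid,
        "screen": screen_map,
        "screen_in": screen_map_in,
        "phi_o_map": phi_o_map,
        "phi_in_columns": phi_in_cols,
        "quad_map": quad_map,
        "keys": keys.copy(),
        "model": model,
        "noise_fields": em,
        "screen_seed": None if screen is None else screen.seed,
        "noise_seed": None if noise is None else noise.seed,
    }
    return SimulationResult(matrix=matrix, truth=truth)


def _analytic_fields(obj: np.ndarray, grid: Grid, keys: np.ndarray,
                     geometry: AcquisitionGeometry, phi_o_map: np.ndarray,
                     phi_in_cols: np.ndarray) -> np.ndarray:
    z = geometry.conjugate_distance
    k = geometry.wavenumber
    lam = geometry.wavelength_medium
    ny, nx = grid.shape
    ratio = geometry.step_ratio
    nsy, nsx = geometry.scan_shape
    # Object spectrum Õ_M on the Minkowski-sum (W) lattice.
    o_m = obj * np.exp(1j * (k / z) * grid.rsq())
    span_y, span_x = (nsy - 1) * ratio, (nsx - 1) * ratio
    w_grid = Grid((ny + span_y, nx + span_x), grid.pitch,
                  (grid.origin[0] + keys[:, 0].min(),
                   grid.origin[1] + keys[:, 1].min()))
    qy, qx = q_axes_for_w_grid(w_grid, k, z)
    spectrum = spectrum_from_object(o_m, grid, qy, qx)
    prefactor = -np.exp(2j * k * z) / (lam ** 2 * z ** 2)
    phase_o = np.exp(1j * phi_o_map)
    fields = np.empty((len(keys),) + grid.shape, dtype=np.complex128)
    iy0 = np.round((keys[:, 0] - keys[:, 0].min()) / grid.pitch).astype(int)
    ix0 = np.round((keys[:, 1] - keys[:, 1].min()) / grid.pitch).astype(int)
    for i in range(len(keys)):
        window = spectrum[iy0[i]:iy0[i] + ny, ix0[i]:ix0[i] + nx]
        fields[i] = prefactor * np.exp(1j * phi_in_cols[i]) * window * phase_o
    return fields


def _na_mask(grid: Grid, k: float, na: float) -> np.ndarray:
    fy = np.fft.fftfreq(grid.shape[0], d=grid.pitch)
    fx = np.fft.fftfreq(grid.shape[1], d=grid.pitch)
    kperp = 2 * np.pi * np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return (kperp <= k * na).astype(np.float64)


def _double_pass_fields(obj: np.ndarray, grid: Grid, keys: np.ndarray,
                        geometry: AcquisitionGeometry, screen_map: np.ndarray,
                        effective_na: float) -> np.ndarray:
    z = geometry.conjugate_distance
    k = geometry.wavenumber
    lam = geometry.wavelength_medium
    mask = _na_mask(grid, k, effective_na)
    y, x = grid.axes()
    fy = np.fft.fftfreq(grid.shape[0], d=grid.pitch)
    fx = np.fft.fftfreq(grid.shape[1], d=grid.pitch)
    phase_screen = np.exp(1j * screen_map)

    def prop(f: np.ndarray, d: float) -> np.ndarray:
        return fresnel_transform_stack(f, grid.pitch, d, geometry.wavelength,
                                       geometry.medium_index, axes=(-2, -1))

    oy, ox = grid.origin
    fields = np.empty((len(keys),) + grid.shape, dtype=np.complex128)
    for i, (ky, kx) in enumerate(keys):
        # NA-limited focus at r_in, built in the spectral domain with the
        # appropriate linear phase (exact off-lattice placement); the grid
        # origin offset keeps the focus on the centred coordinate lattice.
        spec = mask * np.exp(-2j * np.pi * (fy[:, None] * (ky - oy)
                                            + fx[None, :] * (kx - ox)))
        focus = np.fft.ifft2(spec)
        e = prop(focus, -z)          # ideal converging wave at the layer
        e = phase_screen * e         # first pass through the screen
        e = prop(e, +z)              # aberrated illumination at the sample
        e = obj * e                  # reflection off the object
        e = prop(e, +z)              # back up to the layer
        e = phase_screen * e         # second pass through the screen
        e = prop(e, -z)              # relay to the sample-conjugate camera
        e = np.fft.ifft2(np.fft.fft2(e) * mask)  # detection NA filter
        fields[i] = e
    return fields


def simulate_pupil_aberrated_matrix(obj: np.ndarray,
                                    geometry: AcquisitionGeometry,
                                    pupil_screen: Optional[ScreenSpec] = None,
                                    noise: Optional[NoiseSpec] = None,
                                    basis: str = "sample") -> SimulationResult:
    """Simulate a matrix whose aberration lives in the pupil (momentum) plane.

    The pupil-basis matrix is built directly with the separable isoplanatic
    structure R(κ_o; κ_in) = e^{iβ(κ_o)} Õ(κ_o+κ_in) e^{iβ_in(κ_in)}, where
    β is the angle-dependent phase retardation (sampled from
    ``pupil_screen`` on the momentum grids) and Õ is the plain Fourier
    spectrum of the object.  This is the regime in which the pupil-basis
    solver is exact.
    """
    grid = _global_grid(geometry)
    obj = np.asarray(obj, dtype=np.float64)
    if obj.shape != grid.shape:
        raise ValueError(f"object shape {obj.shape} != detection grid {grid.shape}")
    nsy, nsx = geometry.scan_shape
    ny, nx = grid.shape
    kout = _momentum_grid((ny, nx), grid.pitch)
    kin = _momentum_grid((nsy, nsx), geometry.scan_step)
    ratio = kin.pitch / kout.pitch
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            "pupil shear requires the detection extent to be an integer "
            "multiple of the scan extent")
    beta_out = _screen_on_grid(pupil_screen, kout)
    kyi, kxi = kin.axes()
    kin_keys = np.column_stack([np.repeat(kyi, nsx), np.tile(kxi, nsy)])
    beta_in = _sample_at_keys(np.pad(beta_out, 0), kout, kin_keys) \
        if pupil_screen is not None else np.zeros(len(kin_keys))

    # Plain object spectrum on the momentum Minkowski-sum lattice.
    span_y = (nsy - 1) * int(round(ratio))
    span_x = (nsx - 1) * int(round(ratio))
    w_grid = Grid((ny + span_y, nx + span_x), kout.pitch,
                  (kout.origin[0] + kyi.min(), kout.origin[1] + kxi.min()))
    qy_ax = w_grid.axes()[0]
    qx_ax = w_grid.axes()[1]
    spectrum = spectrum_from_object(obj.astype(np.complex128), grid, qy_ax, qx_ax)

    phase_o = np.exp(1j * beta_out)
    fields = np.empty((len(kin_keys), ny, nx), dtype=np.complex128)
    iy0 = np.round((kin_keys[:, 0] - kyi.min()) / kout.pitch).astype(int)
    ix0 = np.round((kin_keys[:, 1] - kxi.min()) / kout.pitch).astype(int)
    for i in range(len(kin_keys)):
        window = spectrum[iy0[i]:iy0[i] + ny, ix0[i]:ix0[i] + nx]
        fields[i] = np.exp(1j * beta_in[i]) * window * phase_o
    fields += _add_noise(fields, noise)
    pupil = ReflectionMatrix(fields, kin_keys, kout, geometry,
                             basis="pupil", descanned=False, key_pitch=kin.pitch)
    truth = {
        "object": obj.copy(),
        "object_grid": grid,
        "beta_out": beta_out,
        "beta_in": beta_in,
        "kin_keys": kin_keys,
    }
    if basis == "pupil":
        return SimulationResult(pupil, truth)
    if basis == "sample":
        keys = geometry.scan_positions()
        samp = from_pupil_basis(pupil, keys, grid, geometry.scan_step)
        return SimulationResult(samp, truth)
    raise ValueError(f"unknown basis {basis!r}")
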