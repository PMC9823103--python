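"""Unitary basis changes of the reflection matrix.

Three bases are supported:

* ``sample`` — illumination and detection indexed by sample-plane position.
* ``conjugate`` — both indices referred to the plane conjugate to the
  aberrating layer at distance z, reached by discrete Fresnel free-space
  propagation applied over the output index (each column) and over the
  input index (each row).
* ``pupil`` — both indices Fourier-transformed to transverse momentum.

All conversions use exactly unitary operators on the stored lattice
(unimodular Fresnel transfer function / unitary centred DFT), so they
preserve the Frobenius norm and invert to machine precision, and the sum
coordinate ``W = w_o + w_in`` stays on the pixel lattice because the
illumination lattice pitch is an integer multiple of the pixel pitch.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np

from .geometry import Grid, GridMismatchError, quadratic_phase_step_at_edge
from .matrix import ReflectionMatrix
from .propagate import fresnel_transform_stack

__all__ = [
    "recenter_descanned",
    "redescan",
    "to_conjugate_basis",
    "from_conjugate_basis",
    "to_pupil_basis",
    "from_pupil_basis",
]


def _scan_lattice_shape(matrix: ReflectionMatrix) -> Tuple[int, int]:
    """(nsy, nsx) of the key lattice; keys must be complete and row-major."""
    ys = np.unique(np.round(matrix.keys[:, 0], 9))
    xs = np.unique(np.round(matrix.keys[:, 1], 9))
    if len(ys) * len(xs) != matrix.n_in:
        raise GridMismatchError("illumination keys do not form a complete lattice")
    expect = np.column_stack([np.repeat(ys, len(xs)), np.tile(xs, len(ys))])
    if not np.allclose(expect, matrix.keys, atol=1e-6):
        raise GridMismatchError("illumination keys are not in row-major lattice order")
    return len(ys), len(xs)


def recenter_descanned(matrix: ReflectionMatrix) -> ReflectionMatrix:
    """Undo the optical descan: shift each map by +r_in onto the global grid.

    Each detected map of a descanned matrix is centred on its own
    illumination point; this translates every map by its ``r_in`` (an exact
    integer number of pixels, enforced by the commensurate-grid rule) into
    a common global grid padded with zeros outside the detection window.
    """
    matrix.require(basis="sample", descanned=True)
    pitch = matrix.grid.pitch
    shifts = matrix.keys / pitch
    ishifts = np.round(shifts).astype(int)
    if not np.allclose(shifts, ishifts, atol=1e-6):
        raise GridMismatchError("descan shifts are not integer lattice steps")
    ny, nx = matrix.grid.shape
    sy_min, sx_min = ishifts.min(axis=0)
    sy_max, sx_max = ishifts.max(axis=0)
    out_shape = (ny + sy_max - sy_min, nx + sx_max - sx_min)
    origin = (matrix.grid.origin[0] + sy_min * pitch,
              matrix.grid.origin[1] + sx_min * pitch)
    out_grid = Grid(out_shape, pitch, origin)
    fields = np.zeros((matrix.n_in,) + out_shape, dtype=np.complex128)
    for i, (dy, dx) in enumerate(ishifts):
        oy, ox = dy - sy_min, dx - sx_min
        fields[i, oy:oy + ny, ox:ox + nx] = matrix.fields[i]
    return ReflectionMatrix(fields, matrix.keys.copy(), out_grid, matrix.geometry,
                            basis="sample", descanned=False,
                            key_pitch=matrix.key_pitch)


def redescan(matrix: ReflectionMatrix, window_shape: Tuple[int, int]) -> ReflectionMatrix:
    """Inverse of :func:`recenter_descanned`: crop each column back to a
    window of ``window_shape`` centred on its own illumination point."""
    matrix.require(basis="sample", descanned=False)
    pitch = matrix.grid.pitch
    ny, nx = window_shape
    rel_grid = Grid.centered(window_shape, pitch)
    fields = np.empty((matrix.n_in, ny, nx), dtype=np.complex128)
    for i, key in enumerate(matrix.keys):
        cy = key[0] + rel_grid.origin[0]
        cx = key[1] + rel_grid.origin[1]
        iy = int(round((cy - matrix.grid.origin[0]) / pitch))
        ix = int(round((cx - matrix.grid.origin[1]) / pitch))
        if iy < 0 or ix < 0 or iy + ny > matrix.grid.shape[0] or ix + nx > matrix.grid.shape[1]:
            raise GridMismatchError("descan window extends beyond the global grid")
        fields[i] = matrix.fields[i, iy:iy + ny, ix:ix + nx]
    return ReflectionMatrix(fields, matrix.keys.copy(), rel_grid, matrix.geometry,
                            basis="sample", descanned=True,
                            key_pitch=matrix.key_pitch)


def _check_conjugate_sampling(matrix: ReflectionMatrix, z: float) -> None:
    """Warn when the quadratic conjugate-plane phase is undersampled.

    The conversion itself remains an exact unitary re-expression of the
    recorded matrix, and per-pixel phase estimation is unaffected, but
    displayed aberration maps will wrap rapidly and lattice-evaluated
    model formulas are unrepresentative in this regime.
    """
    g = matrix.geometry.with_(conjugate_distance=z)
    ny, nx = matrix.grid.shape
    ratio = max(int(round(matrix.key_pitch / matrix.grid.pitch)), 1)
    nsy, nsx = _scan_lattice_shape(matrix)
    wgrid = Grid.centered((ny + nsy * ratio, nx + nsx * ratio), matrix.grid.pitch)
    step = quadratic_phase_step_at_edge(g, wgrid)
    if step > np.pi:
        warnings.warn(
            f"conjugate-plane quadratic phase is undersampled at z={z} μm "
            f"(per-pixel step {step:.2f} rad > pi at the W-lattice edge)",
            RuntimeWarning)


def _propagate_both_indices(matrix: ReflectionMatrix, distance: float) -> np.ndarray:
    """Fresnel transfer function applied over the output grid (axes 1, 2)
    and over the input lattice (keys reshaped to their 2D scan grid)."""
    geo = matrix.geometry
    nsy, nsx = _scan_lattice_shape(matrix)
    out = fresnel_transform_stack(matrix.fields, matrix.grid.pitch, distance,
                                  geo.wavelength, geo.medium_index, axes=(1, 2))
    ny, nx = matrix.grid.shape
    out = out.reshape(nsy, nsx, ny, nx)
    out = fresnel_transform_stack(out, matrix.key_pitch, distance,
                                  geo.wavelength, geo.medium_index, axes=(0, 1))
    return out.reshape(matrix.n_in, ny, nx)


def to_conjugate_basis(matrix: ReflectionMatrix, z: float) -> ReflectionMatrix:
    """Re-express a sample-basis matrix at the plane conjugate to the
    aberrating layer, a distance ``z`` (μm, > 0) from the sample plane."""
    matrix.require(basis="sample", descanned=False)
    if z <= 0:
        raise ValueError("conjugate distance z must be positive")
    _check_conjugate_sampling(matrix, z)
    fields = _propagate_both_indices(matrix, +z)
    geo = matrix.geometry.with_(conjugate_distance=z)
    return ReflectionMatrix(fields, matrix.keys.copy(), matrix.grid, geo,
                            basis="conjugate", descanned=False,
                            key_pitch=matrix.key_pitch)


def from_conjugate_basis(matrix: ReflectionMatrix) -> ReflectionMatrix:
    """Inverse of :func:`to_conjugate_basis` (propagates both indices by −z)."""
    matrix.require(basis="conjugate", descanned=False)
    z = matrix.geometry.conjugate_distance
    fields = _propagate_both_indices(matrix, -z)
    return ReflectionMatrix(fields, matrix.keys.copy(), matrix.grid,
                            matrix.geometry, basis="sample", descanned=False,
                            key_pitch=matrix.key_pitch)


def _centered_dft2(arr: np.ndarray, axes: Tuple[int, int], inverse: bool = False
                   ) -> np.ndarray:
    """Unitary 2D DFT matched to centred grids (origin at index n//2),
    forward kernel e^{−i k·r}."""
    shifted = np.fft.ifftshift(arr, axes=axes)
    if inverse:
        spec = np.fft.ifft2(shifted, axes=axes, norm="ortho")
    else:
        spec = np.fft.fft2(shifted, axes=axes, norm="ortho")
    return np.fft.fftshift(spec, axes=axes)


def _momentum_grid(shape: Tuple[int, int], pitch: float) -> Grid:
    return Grid.centered(shape, 2.0 * np.pi / (shape[0] * pitch))


def to_pupil_basis(matrix: ReflectionMatrix) -> ReflectionMatrix:
    """Fourier transform both indices to transverse momentum (rad/μm).

    The momentum lattice of the input index has pitch 2π/(scan extent); for
    the shear solver it must be an integer multiple of the output momentum
    pitch 2π/(detection extent), i.e. the detection extent must be an
    integer multiple of the scan extent.
    """
    matrix.require(basis="sample", descanned=False)
    nsy, nsx = _scan_lattice_shape(matrix)
    ny, nx = matrix.grid.shape
    if ny != nx or nsy != nsx:
        raise GridMismatchError("pupil conversion requires square grids")
    out = _centered_dft2(matrix.fields, axes=(1, 2))
    out = out.reshape(nsy, nsx, ny, nx)
    out = _centered_dft2(out, axes=(0, 1))
    out = out.reshape(matrix.n_in, ny, nx)
    kout = _momentum_grid((ny, nx), matrix.grid.pitch)
    kin = _momentum_grid((nsy, nsx), matrix.key_pitch)
    ky, kx = kin.axes()
    keys = np.column_stack([np.repeat(ky, nsx), np.tile(kx, nsy)])
    return ReflectionMatrix(out, keys, kout, matrix.geometry,
                            basis="pupil", descanned=False,
                            key_pitch=kin.pitch)


def from_pupil_basis(matrix: ReflectionMatrix, scan_keys: np.ndarray,
                     sample_grid: Grid, key_pitch: float) -> ReflectionMatrix:
    """Inverse of :func:`to_pupil_basis`.  The original sample-plane key
    lattice and grid must be supplied (momentum metadata does not retain
    the absolute sample-plane origin)."""
    matrix.require(basis="pupil", descanned=False)
    nsy, nsx = _scan_lattice_shape(matrix)
    ny, nx = matrix.grid.shape
    out = matrix.fields.reshape(nsy, nsx, ny, nx)
    out = _centered_dft2(out, axes=(0, 1), inverse=True)
    out = out.reshape(matrix.n_in, ny, nx)
    out = _centered_dft2(out, axes=(1, 2), inverse=True)
    return ReflectionMatrix(out, np.asarray(scan_keys, float), sample_grid,
                            matrix.geometry, basis="sample", descanned=False,
                            key_pitch=key_pitch)
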