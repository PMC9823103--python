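"""Iterative input/output aberration-phase estimation (CLASS family).

The conjugate-basis matrix model is separable in the layer-plane phases:

    E(w_o; w_in) = c · e^{iφ_in(w_in)} Õ_M(k(w_o+w_in)/z) e^{iφ_o(w_o)} + E_M.

Re-indexing each column by the sum coordinate W = w_o + w_in makes the
object spectrum Õ_M(kW/z) shift-invariant with respect to w_in, so the
phase of the inner product of a column with a reference over the shared W
support estimates φ_in(w_in) (and, with the roles of the indices swapped,
φ_o(w_o)).  The two estimates are applied as multiplicative corrections
e^{-iδφ} and iterated until the update magnitudes fall below tolerance;
the corrected columns are then summed coherently over w_in, which grows
the single-scattering object spectrum by N while the multiple-scattering
term grows only as √N.

The same core runs in the pupil (momentum) basis, where the shear
coordinate is the momentum sum; there it is the predecessor pupil-domain
algorithm, exact only within an isoplanatic patch.

The printed reference in the model above is the w_in = 0 column.  By
default the implementation correlates every column against the coherent
sum of all other corrected columns — identical in expectation at the first
iteration (up to gauge) but insensitive to a weak reference column — and
re-gauges so the estimate at w = 0 is exactly zero.  Set
``SolverConfig.reference = "zero"`` for the strict reference-column form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .chirpdft import object_from_spectrum, q_axes_for_w_grid
from .geometry import Grid, GridMismatchError
from .matrix import (AberrationEstimate, ObjectReconstruction, ReflectionMatrix,
                     wrap_phase)

__all__ = [
    "SolverConfig",
    "ShearedMatrix",
    "shear_to_W",
    "estimate_input_phase",
    "estimate_output_phase",
    "run_conjugate_class",
    "run_pupil_class",
    "decompose_aberration",
    "apply_phase_correction",
]


@dataclass
class SolverConfig:
    """Iteration control for the alternating phase estimation.

    ``tolerance`` is the RMS (radians) of the wrapped per-iteration phase
    update below which the loop stops; ``reference`` selects the inner-
    product reference (``"sum"`` = coherent sum of the other corrected
    columns, ``"zero"`` = the w_in = 0 column as printed in the model);
    ``amplitude_weighting`` replaces the plain inner product by a
    magnitude-normalised one (off by default, matching the model).

    Tilt is a gauge freedom of the model (a linear ramp shared by the
    input and output phases only translates the reconstructed object);
    the solver leaves it free, and mosaicking code registers subregion
    reconstructions to each other instead.
    """

    max_iterations: int = 30
    tolerance: float = 1e-2
    reference: str = "sum"
    amplitude_weighting: bool = False
    divergence_patience: int = 5

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.reference not in ("sum", "zero"):
            raise ValueError("reference must be 'sum' or 'zero'")


@dataclass
class ShearedMatrix:
    """Column stack re-indexed by the sum coordinate W = w_o + w_in.

    Stored compactly: ``fields[i]`` occupies the W-canvas window starting
    at integer offset ``offsets[i]``; canvas positions outside a column's
    window are absent (not zero) and excluded from inner products.
    """

    fields: np.ndarray          # (n_in, ny, nx)
    offsets: np.ndarray         # (n_in, 2) integer canvas offsets
    w_grid: Grid                # canvas lattice (W coordinates)
    keys: np.ndarray            # (n_in, 2) w_in values
    gauge_column: int           # index of the w_in lattice point nearest 0

    @property
    def n_in(self) -> int:
        return self.fields.shape[0]

    @property
    def window(self) -> Tuple[int, int]:
        return self.fields.shape[1:]

    def views(self, canvas: np.ndarray):
        ny, nx = self.window
        for i, (oy, ox) in enumerate(self.offsets):
            yield i, canvas[oy:oy + ny, ox:ox + nx]

    def accumulate(self) -> Tuple[np.ndarray, np.ndarray]:
        """Coherent sum over w_in on the W canvas, with presence counts."""
        s = np.zeros(self.w_grid.shape, dtype=np.complex128)
        counts = np.zeros(self.w_grid.shape, dtype=np.int64)
        ny, nx = self.window
        for i, (oy, ox) in enumerate(self.offsets):
            s[oy:oy + ny, ox:ox + nx] += self.fields[i]
            counts[oy:oy + ny, ox:ox + nx] += 1
        return s, counts

    def to_dense(self) -> Tuple[np.ndarray, np.ndarray]:
        """(n_in, NY, NX) dense canvas stack plus presence mask (for toys)."""
        ny, nx = self.window
        dense = np.zeros((self.n_in,) + self.w_grid.shape, dtype=np.complex128)
        mask = np.zeros((self.n_in,) + self.w_grid.shape, dtype=bool)
        for i, (oy, ox) in enumerate(self.offsets):
            dense[i, oy:oy + ny, ox:ox + nx] = self.fields[i]
            mask[i, oy:oy + ny, ox:ox + nx] = True
        return dense, mask


def shear_to_W(matrix: ReflectionMatrix) -> ShearedMatrix:
    """Re-index a conjugate- (or pupil-) basis matrix by W = w_o + w_in."""
    if matrix.basis not in ("conjugate", "pupil"):
        raise ValueError(f"shear requires conjugate or pupil basis, got {matrix.basis}")
    matrix.require(descanned=False)
    pitch = matrix.grid.pitch
    shifts = matrix.keys / pitch
    ishifts = np.round(shifts).astype(int)
    if not np.allclose(shifts, ishifts, atol=1e-6):
        raise GridMismatchError(
            "illumination keys are not integer multiples of the pixel pitch; "
            "the sum coordinate W would fall off-lattice")
    offsets = ishifts - ishifts.min(axis=0)
    span = offsets.max(axis=0)
    ny, nx = matrix.grid.shape
    w_grid = Grid((ny + span[0], nx + span[1]), pitch,
                  (matrix.grid.origin[0] + matrix.keys[:, 0].min(),
                   matrix.grid.origin[1] + matrix.keys[:, 1].min()))
    gauge = int(np.argmin(np.abs(matrix.keys).sum(axis=1)))
    return ShearedMatrix(matrix.fields.copy(), offsets, w_grid,
                         matrix.keys.copy(), gauge)


def unshear(sheared: ShearedMatrix, matrix: ReflectionMatrix) -> ReflectionMatrix:
    """Rebuild a matrix (metadata from ``matrix``) from a sheared stack."""
    out = matrix.copy()
    out.fields = sheared.fields.copy()
    return out


def _inner_products_input(sheared: ShearedMatrix, reference: str,
                          s: Optional[np.ndarray] = None,
                          amplitude_weighting: bool = False) -> np.ndarray:
    """Complex inner product of every column with the reference, over the
    shared W support.  Returns (n_in,) complex."""
    fields = sheared.fields
    n, ny, nx = fields.shape
    z = np.zeros(n, dtype=np.complex128)
    if reference == "zero":
        ref = fields[sheared.gauge_column]
        roff = sheared.offsets[sheared.gauge_column]
        for i in range(n):
            rel = sheared.offsets[i] - roff
            a = _overlap_product(fields[i], ref, rel, amplitude_weighting)
            z[i] = a
    else:
        if s is None:
            s, _ = sheared.accumulate()
        for i, view in sheared.views(s):
            other = view - fields[i]
            if amplitude_weighting:
                w = np.abs(fields[i]) * np.abs(other)
                good = w > 0
                z[i] = np.sum(fields[i][good] * np.conj(other[good]) / w[good])
            else:
                z[i] = np.vdot(other, fields[i])  # Σ E_i · conj(other)
    return z


def _overlap_product(a: np.ndarray, b: np.ndarray, rel: np.ndarray,
                     amplitude_weighting: bool) -> complex:
    """Σ a[p]·conj(b[p + rel]) over the valid overlap (absent ⇒ excluded)."""
    ny, nx = a.shape
    ry, rx = int(rel[0]), int(rel[1])
    ay0, ay1 = max(0, -ry), min(ny, ny - ry)
    ax0, ax1 = max(0, -rx), min(nx, nx - rx)
    if ay0 >= ay1 or ax0 >= ax1:
        return 0.0 + 0.0j
    av = a[ay0:ay1, ax0:ax1]
    bv = b[ay0 + ry:ay1 + ry, ax0 + rx:ax1 + rx]
    if amplitude_weighting:
        w = np.abs(av) * np.abs(bv)
        good = w > 0
        return complex(np.sum(av[good] * np.conj(bv[good]) / w[good]))
    return complex(np.sum(av * np.conj(bv)))


def estimate_input_phase(sheared: ShearedMatrix, reference: str = "zero",
                         amplitude_weighting: bool = False
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Estimate δφ_in(w_in) from the sheared stack.

    Returns ``(phase, weight)`` over the w_in lattice: phase is the angle
    of the inner product of each column with the reference over the shared
    W pixels, gauged so the w_in = 0 entry is exactly zero; weight is the
    inner-product magnitude (0 where the shared support is empty, with
    phase reported as 0 there).
    """
    z = _inner_products_input(sheared, reference,
                              amplitude_weighting=amplitude_weighting)
    return _gauged_angle(z, gauge_idx=sheared.gauge_column)


def estimate_output_phase(sheared: ShearedMatrix, reference: str = "zero",
                          amplitude_weighting: bool = False
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Mirror of :func:`estimate_input_phase` with input/output roles
    swapped: δφ_o(w_o) from the angle of the inner product of each output
    row (re-indexed by W = w_o + w_in) with the reference row."""
    fields = sheared.fields
    n, ny, nx = fields.shape
    if reference == "zero":
        # reference output pixel: lattice point nearest the axis
        gy, gx = _gauge_pixel_of_window(sheared)
        z = np.zeros((ny, nx), dtype=np.complex128)
        # row at pixel p occupies W = p + offset_i for column i; the
        # reference row w_o = p0 occupies W = p0 + offset_j.  Matching
        # W ⇒ offset_j = offset_i + (p − p0), valid only on the key lattice.
        offset_index = {tuple(o): j for j, o in enumerate(sheared.offsets)}
        for dy in range(ny):
            for dx in range(nx):
                acc = 0.0 + 0.0j
                for i in range(n):
                    tgt = (sheared.offsets[i][0] + dy - gy,
                           sheared.offsets[i][1] + dx - gx)
                    j = offset_index.get(tgt)
                    if j is None:
                        continue
                    a = fields[i, dy, dx]
                    b = fields[j, gy, gx]
                    if amplitude_weighting:
                        w = abs(a) * abs(b)
                        if w > 0:
                            acc += a * np.conj(b) / w
                    else:
                        acc += a * np.conj(b)
                z[dy, dx] = acc
    else:
        s, _ = sheared.accumulate()
        z = np.zeros((ny, nx), dtype=np.complex128)
        for i, view in sheared.views(s):
            other = view - fields[i]
            if amplitude_weighting:
                w = np.abs(fields[i]) * np.abs(other)
                good = w > 0
                contrib = np.zeros_like(z)
                contrib[good] = fields[i][good] * np.conj(other[good]) / w[good]
                z += contrib
            else:
                z += fields[i] * np.conj(other)
    gy, gx = _gauge_pixel_of_window(sheared)
    return _gauged_angle(z, gauge_idx=(gy, gx))


def _gauge_pixel_of_window(sheared: ShearedMatrix):
    # output window lattice point nearest w_o = 0: windows share the
    # original detection grid, whose gauge is at index n//2 of each axis
    ny, nx = sheared.window
    return ny // 2, nx // 2


def _gauged_angle(z: np.ndarray, gauge_idx) -> Tuple[np.ndarray, np.ndarray]:
    weight = np.abs(z)
    phase = np.where(weight > 0, np.angle(z), 0.0)
    g = phase[gauge_idx]
    phase = wrap_phase(phase - g)
    phase[gauge_idx] = 0.0
    phase[weight == 0] = 0.0
    return phase, weight


def _weighted_rms(phase: np.ndarray, weight: np.ndarray) -> float:
    good = weight > 0
    if not np.any(good):
        return 0.0
    return float(np.sqrt(np.mean(wrap_phase(phase[good]) ** 2)))


def run_conjugate_class(matrix: ReflectionMatrix,
                        config: Optional[SolverConfig] = None) -> Dict:
    """Alternating input/output phase estimation in the conjugate basis.

    Returns a dict with the AberrationEstimate (quadratic/screen split
    already computed), the corrected matrix, the coherently accumulated
    ObjectReconstruction, and the per-iteration history.
    """
    matrix.require(basis="conjugate", descanned=False)
    return _run_class_core(matrix, config, reconstruct_object=True)


def run_pupil_class(matrix: ReflectionMatrix,
                    config: Optional[SolverConfig] = None) -> Dict:
    """Same alternating loop in the pupil (momentum) basis.

    The returned phase maps are angle-dependent retardations on the
    momentum lattices; the reconstructed image is the inverse transform of
    the accumulated momentum spectrum on the sample grid.
    """
    matrix.require(basis="pupil", descanned=False)
    return _run_class_core(matrix, config, reconstruct_object=False)


def _run_class_core(matrix: ReflectionMatrix, config: Optional[SolverConfig],
                    reconstruct_object: bool) -> Dict:
    config = config or SolverConfig()
    sheared = shear_to_W(matrix)
    n = sheared.n_in
    phi_in_total = np.zeros(n)
    phi_out_total = np.zeros(sheared.window)
    rms_in_hist, rms_out_hist, energy_hist = [], [], []
    diverged = False
    converged = False
    prev_rms = np.inf
    min_rms = np.inf
    grow_streak = 0

    for _ in range(config.max_iterations):
        dphi_in, w_in = estimate_input_phase(
            sheared, reference=config.reference,
            amplitude_weighting=config.amplitude_weighting)
        sheared.fields *= np.exp(-1j * dphi_in)[:, None, None]
        phi_in_total += dphi_in

        dphi_out, w_out = estimate_output_phase(
            sheared, reference=config.reference,
            amplitude_weighting=config.amplitude_weighting)
        sheared.fields *= np.exp(-1j * dphi_out)[None, :, :]
        phi_out_total += dphi_out

        rin = _weighted_rms(dphi_in, w_in)
        rout = _weighted_rms(dphi_out, w_out)
        rms_in_hist.append(rin)
        rms_out_hist.append(rout)
        s, counts = sheared.accumulate()
        energy_hist.append(float(np.sum(np.abs(s) ** 2)))
        if rin < config.tolerance and rout < config.tolerance:
            converged = True
            break
        # Divergence = sustained growth well above the best level reached;
        # small transient bumps of the alternating scheme are benign.
        rms_now = max(rin, rout)
        min_rms = min(min_rms, rms_now)
        growing = rms_now > prev_rms and rms_now > 10.0 * min_rms
        grow_streak = grow_streak + 1 if growing else 0
        prev_rms = rms_now
        if grow_streak >= config.divergence_patience:
            diverged = True
            break

    in_grid = _key_lattice_grid(matrix)
    _fix_tilt_gauge(sheared, matrix, in_grid, phi_in_total, phi_out_total,
                    reconstruct_object)

    s, counts = sheared.accumulate()
    spectrum = np.zeros_like(s)
    present = counts > 0
    spectrum[present] = s[present] * (n / counts[present])

    estimate = AberrationEstimate(
        phi_in=wrap_phase(phi_in_total).reshape(in_grid.shape),
        phi_out=wrap_phase(phi_out_total),
        in_grid=in_grid,
        out_grid=matrix.grid,
        update_rms_in=rms_in_hist,
        update_rms_out=rms_out_hist,
        spectrum_energy=energy_hist,
        converged=converged,
        diverged=diverged,
    )

    corrected = matrix.copy()
    corrected.fields = sheared.fields

    recon = ObjectReconstruction(spectrum=spectrum, counts=counts,
                                 w_grid=sheared.w_grid, n_accumulated=n)
    geo = matrix.geometry
    if reconstruct_object:
        decompose_aberration(estimate, geo)
        _fill_object_reconstruction(recon, matrix, geo)
    else:
        _fill_pupil_reconstruction(recon, matrix, geo)

    return {"estimate": estimate, "corrected": corrected,
            "reconstruction": recon, "config": config}


def _fix_tilt_gauge(sheared: ShearedMatrix, matrix: ReflectionMatrix,
                    in_grid: Grid, phi_in_total: np.ndarray,
                    phi_out_total: np.ndarray, conjugate: bool) -> None:
    """Fix the tilt gauge of the converged solution in place.

    A linear ramp added to both correction phases is a flat direction of
    the model (it only translates the reconstruction), so the iteration
    can drift to solutions that push the object far off-centre.  The
    estimate is re-gauged so the layer-screen part of the *output* phase
    (total phase minus the analytic quadratic term in the conjugate
    basis) carries no net amplitude-weighted tilt over the detection
    window — a support shared by every subregion solve of one field, so
    independently solved tiles land on a common lateral registration.
    The same ramp is removed from the input phase and the corrected
    columns are adjusted accordingly, which leaves the coherence of the
    accumulation unchanged.
    """
    keys = matrix.keys
    if conjugate:
        geo = matrix.geometry
        quad_out = (geo.wavenumber / (2 * geo.conjugate_distance)) * matrix.grid.rsq()
    else:
        quad_out = 0.0
    screen_out = wrap_phase(phi_out_total - quad_out)
    weights = np.abs(sheared.fields).mean(axis=0)
    tilt = _fit_tilt(screen_out, matrix.grid, weights)
    if not np.any(tilt):
        return
    ramp_in = keys @ tilt
    yy, xx = matrix.grid.mesh()
    ramp_out = tilt[0] * yy + tilt[1] * xx
    phi_in_total -= ramp_in
    phi_out_total -= ramp_out
    sheared.fields *= np.exp(1j * ramp_in)[:, None, None]
    sheared.fields *= np.exp(1j * ramp_out)[None, :, :]
    # re-pin the piston gauge (the ramp is generally nonzero at w = 0)
    phi_in_total -= phi_in_total[sheared.gauge_column]
    gy, gx = _gauge_pixel_of_window(sheared)
    phi_out_total -= phi_out_total[gy, gx]


def _fit_tilt(phase: np.ndarray, grid: Grid,
              weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Best tilt a (rad/μm, per axis) maximising |Σ w e^{i(φ − a·w)}| on a
    regular lattice: zero-padded-FFT peak (covers the whole unambiguous
    tilt range ±π/pitch), then simplex refinement."""
    from scipy import optimize

    c = np.exp(1j * np.asarray(phase, float))
    if weights is not None:
        c = c * (np.asarray(weights, float) / (weights.max() + 1e-300))
    ny, nx = c.shape
    pad = 4
    buf = np.zeros((pad * ny, pad * nx), dtype=np.complex128)
    buf[:ny, :nx] = c
    spec = np.fft.fft2(buf)
    iy, ix = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
    a0 = 2 * np.pi * np.array([np.fft.fftfreq(pad * ny)[iy],
                               np.fft.fftfreq(pad * nx)[ix]]) / grid.pitch
    yy, xx = grid.mesh()

    def neg(a):
        return -np.abs(np.sum(c * np.exp(-1j * (a[0] * yy + a[1] * xx))))

    res = optimize.minimize(neg, a0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400})
    return res.x if -res.fun >= -neg(a0) else a0


def _key_lattice_grid(matrix: ReflectionMatrix) -> Grid:
    ys = np.unique(np.round(matrix.keys[:, 0], 9))
    xs = np.unique(np.round(matrix.keys[:, 1], 9))
    pitch = matrix.key_pitch if matrix.key_pitch else matrix.grid.pitch
    return Grid((len(ys), len(xs)), pitch, (float(ys.min()), float(xs.min())))


def _fill_object_reconstruction(recon: ObjectReconstruction,
                                matrix: ReflectionMatrix, geo) -> None:
    """Invert the accumulated spectrum to O_M(r), O(r) and |O|² on the
    sample grid, removing the model prefactor −e^{2ikz} N/(λ²z²).

    Every W pixel enters with its per-pixel mean over the present columns
    (scaled by N), so partially covered rim pixels are unbiased estimates
    of the spectrum rather than tapered ones.
    """
    z = geo.conjugate_distance
    k = geo.wavenumber
    lam = geo.wavelength_medium
    qy, qx = q_axes_for_w_grid(recon.w_grid, k, z)
    prefactor = -np.exp(2j * k * z) / (lam ** 2 * z ** 2)
    scaled = recon.spectrum / (prefactor * recon.n_accumulated)
    out_grid = matrix.grid
    o_m = object_from_spectrum(scaled, qy, qx, out_grid)
    recon.object_field = o_m
    recon.object_grid = out_grid
    recon.reflectance = o_m * np.exp(-1j * (k / z) * out_grid.rsq())
    recon.intensity = np.abs(recon.reflectance) ** 2


def _fill_pupil_reconstruction(recon: ObjectReconstruction,
                               matrix: ReflectionMatrix, geo) -> None:
    """Momentum-domain accumulation: inverse transform the summed spectrum
    (plain object spectrum) onto the sample grid."""
    qy, qx = recon.w_grid.axes()
    out_grid = geo.detection_grid()
    o = object_from_spectrum(recon.spectrum / recon.n_accumulated, qy, qx, out_grid)
    recon.object_field = o
    recon.object_grid = out_grid
    recon.reflectance = o
    recon.intensity = np.abs(o) ** 2


def decompose_aberration(estimate: AberrationEstimate, geometry) -> Dict:
    """Split the accumulated corrections into the analytic quadratic phase
    (k/2z)|w|² and the layer-induced screen term φ_s = wrap(φ_c − φ_quad)."""
    z = geometry.conjugate_distance
    if z <= 0:
        raise ValueError("conjugate distance must be known and positive")
    k = geometry.wavenumber
    quad_in = (k / (2 * z)) * estimate.in_grid.rsq()
    quad_out = (k / (2 * z)) * estimate.out_grid.rsq()
    estimate.phi_quad_in = quad_in
    estimate.phi_screen_in = wrap_phase(estimate.phi_in - quad_in)
    estimate.phi_quad_out = quad_out
    estimate.phi_screen_out = wrap_phase(estimate.phi_out - quad_out)
    return {"phi_quad_in": quad_in, "phi_s_in": estimate.phi_screen_in,
            "phi_quad_out": quad_out, "phi_s_out": estimate.phi_screen_out}


def apply_phase_correction(matrix: ReflectionMatrix, phi_in: np.ndarray,
                           phi_out: np.ndarray) -> ReflectionMatrix:
    """Multiply e^{−iφ_out(w_o)} E e^{−iφ_in(w_in)} (the correction step)."""
    out = matrix.copy()
    phi_in = np.asarray(phi_in, float).reshape(matrix.n_in)
    out.fields *= np.exp(-1j * phi_in)[:, None, None]
    out.fields *= np.exp(-1j * np.asarray(phi_out, float))[None, :, :]
    return out
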