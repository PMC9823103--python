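"""Quality metrics: circular phase statistics, image correlation, PSF widths.

Phase comparisons are circular and gauge-aware: a recovered aberration is
defined only up to piston (global offset) and tilt (linear ramp, which the
model absorbs as a lateral shift of the object), so the recovery metric
maximises the coherence |⟨w e^{i(Δφ − a·w − c)}⟩| over piston and tilt.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, optimize
from scipy.special import j1
from skimage.registration import phase_cross_correlation

from .geometry import Grid

__all__ = [
    "phase_recovery_metric",
    "circular_rms",
    "image_correlation",
    "measure_fwhm",
    "airy_fwhm_amplitude",
    "shear_limited_fwhm",
]


def _tilt_coherence(diff_phasor: np.ndarray, grid: Grid,
                    weights: Optional[np.ndarray]) -> Tuple[float, np.ndarray]:
    """max over tilt (ay, ax) of |Σ w e^{iΔ} e^{-i(ay·y+ax·x)}| / Σ w."""
    w = np.ones_like(diff_phasor, dtype=float) if weights is None else np.asarray(weights, float)
    c = w * diff_phasor
    total = w.sum()
    if total == 0:
        return 0.0, np.zeros(2)
    # coarse tilt search: zero-padded FFT peak
    pad = 8
    ny, nx = c.shape
    buf = np.zeros((pad * ny, pad * nx), dtype=np.complex128)
    buf[:ny, :nx] = c
    spec = np.fft.fft2(buf)
    iy, ix = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
    fy = np.fft.fftfreq(pad * ny)[iy] / grid.pitch
    fx = np.fft.fftfreq(pad * nx)[ix] / grid.pitch
    a0 = 2 * np.pi * np.array([fy, fx])

    yy, xx = grid.mesh()

    def neg_mag(a):
        return -np.abs(np.sum(c * np.exp(-1j * (a[0] * yy + a[1] * xx))))

    res = optimize.minimize(neg_mag, a0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400})
    best = max(-res.fun, -neg_mag(a0))
    return float(best / total), res.x


def phase_recovery_metric(phi_est: np.ndarray, phi_true: np.ndarray,
                          grid: Grid, weights: Optional[np.ndarray] = None,
                          remove_tilt: bool = True) -> float:
    """|⟨e^{i(φ̂ − φ)}⟩| over the (weighted) support, after piston/tilt.

    1.0 means perfect recovery up to the model's gauge freedoms.
    """
    diff = np.exp(1j * (np.asarray(phi_est, float) - np.asarray(phi_true, float)))
    if not remove_tilt:
        w = np.ones_like(diff, float) if weights is None else weights
        return float(np.abs(np.sum(w * diff)) / np.sum(w))
    metric, _ = _tilt_coherence(diff, grid, weights)
    return metric


def circular_rms(phi_est: np.ndarray, phi_true: np.ndarray, grid: Grid,
                 weights: Optional[np.ndarray] = None,
                 remove_tilt: bool = True) -> float:
    """Circular RMS (radians) of the residual phase after piston/tilt:
    sqrt(−2 ln R) with R the coherence — equals the plain RMS for small
    residuals."""
    r = phase_recovery_metric(phi_est, phi_true, grid, weights, remove_tilt)
    r = min(max(r, 1e-300), 1.0)
    return float(np.sqrt(max(-2.0 * np.log(r), 0.0)))


def image_correlation(image: np.ndarray, reference: np.ndarray,
                      align: bool = True, upsample: int = 10) -> float:
    """Pearson correlation of two (magnitude) images, after registering
    the image to the reference by subpixel cross-correlation when
    ``align=True`` (the solver has a tilt degeneracy that shifts the
    reconstruction laterally)."""
    a = np.abs(np.asarray(image, dtype=np.complex128))
    b = np.abs(np.asarray(reference, dtype=np.complex128))
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if align:
        shift, _, _ = phase_cross_correlation(b, a, upsample_factor=upsample,
                                              normalization=None)
        a = np.abs(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(a), shift)))
    av = a - a.mean()
    bv = b - b.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def measure_fwhm(profile: np.ndarray, pitch: float) -> Tuple[float, bool]:
    """FWHM of a 1D non-negative profile by linear interpolation of the
    half-maximum crossings around the peak.  Returns (fwhm, defined)."""
    p = np.asarray(profile, float)
    i0 = int(np.argmax(p))
    half = p[i0] / 2.0
    # walk left
    left = None
    for i in range(i0, 0, -1):
        if p[i - 1] <= half <= p[i]:
            frac = (p[i] - half) / (p[i] - p[i - 1]) if p[i] != p[i - 1] else 0.0
            left = i - frac
            break
    right = None
    for i in range(i0, len(p) - 1):
        if p[i + 1] <= half <= p[i]:
            frac = (p[i] - half) / (p[i] - p[i + 1]) if p[i] != p[i + 1] else 0.0
            right = i + frac
            break
    if left is None or right is None:
        return float("inf"), False
    return float((right - left) * pitch), True


def airy_fwhm_amplitude(wavelength: float, na: float) -> float:
    """FWHM (μm) of the amplitude Airy pattern |2J₁(v)/v| of a circular
    aperture of numerical aperture ``na`` — the round-trip amplitude PSF of
    an aberration-free double-pass system whose illumination and detection
    share the same pupil."""
    f = lambda v: 2 * j1(v) / v - 0.5
    v_half = optimize.brentq(f, 1.0, 3.0)
    return 2.0 * v_half * wavelength / (2 * np.pi * na)


def shear_limited_fwhm(wavelength: float, z: float, scan_extent: float) -> float:
    """FWHM (μm) of the amplitude profile sinc(x·S/(λz)) — the round-trip
    PSF of the lattice model when the illumination lattice extent S is the
    limiting window."""
    # sin(pi t)/(pi t) = 1/2 at t = 0.6033551
    t = optimize.brentq(lambda t: np.sinc(t) - 0.5, 0.1, 0.9)
    return 2.0 * t * wavelength * z / scan_extent
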