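"""Ground-truth generators: random phase screens and test objects.

The phase screen stands in for the spatial phase retardation of the skull
at the plane conjugate to it; the test objects emulate the targets used to
validate the correction (resolution-chart bars, point scatterers, thin
myelin-like fibres).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .geometry import Grid

__all__ = ["ScreenSpec", "NoiseSpec", "make_phase_screen", "make_test_object"]


@dataclass(frozen=True)
class ScreenSpec:
    """Statistics of the aberrating phase screen.

    Defaults describe a strongly aberrating, fully speckle-forming skull
    layer: zero-mean Gaussian phase of 3 rad RMS correlated over 4 μm,
    which broadens the confocal PSF by well over an order of magnitude on
    the default geometry.  An explicit ``phase_map`` overrides the random
    synthesis.
    """

    rms_phase: float = 3.0
    correlation_length: float = 4.0
    seed: int = 0
    phase_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.rms_phase < 0:
            raise ValueError("rms_phase must be non-negative")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiple-scattering noise: circular complex Gaussian with a given
    power ratio relative to the ballistic (single-scattering) signal."""

    multiple_scattering_power_ratio: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiple_scattering_power_ratio < 0:
            raise ValueError("noise power ratio must be non-negative")


def make_phase_screen(spec: ScreenSpec, grid: Grid) -> np.ndarray:
    """Synthesize a smooth zero-mean random phase field on ``grid`` (rad).

    White Gaussian noise is low-pass filtered with a Gaussian kernel whose
    1/e half-width is the requested correlation length, then rescaled so
    the realized RMS matches ``spec.rms_phase`` (exactly, by construction).
    Bit-reproducible per seed.
    """
    if spec.phase_map is not None:
        phi = np.asarray(spec.phase_map, dtype=np.float64)
        if phi.shape != grid.shape:
            raise ValueError(f"explicit phase map shape {phi.shape} != grid {grid.shape}")
        return phi.copy()
    if spec.rms_phase == 0:
        return np.zeros(grid.shape)
    # Gaussian correlation exp(-r²/l²) corresponds to smoothing white noise
    # with a Gaussian of sigma = l/2 (autocorrelation of the kernel doubles
    # the variance scale).
    sigma_px = spec.correlation_length / (2.0 * grid.pitch)
    if spec.correlation_length < 2.0 * grid.pitch:
        raise ValueError(
            f"correlation_length {spec.correlation_length} below 2 px "
            f"({2 * grid.pitch}) undersamples the screen")
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(white, sigma_px, mode="wrap")
    smooth -= smooth.mean()
    rms = np.sqrt(np.mean(smooth**2))
    if rms == 0:
        return np.zeros(grid.shape)
    return smooth * (spec.rms_phase / rms)


def make_test_object(kind: str, grid: Grid, params: Optional[dict] = None
                     ) -> Tuple[np.ndarray, dict]:
    """Build a real, non-negative reflectance map O(r) in [0, 1].

    Kinds
    -----
    ``usaf_bars``
        Resolution-chart-like binary bar groups (duty cycle 0.5) in two
        orientations and several periods.  ``params``: ``period_px``
        (smallest bar period, default 4), ``n_groups`` (default 3).
    ``point_scatterers``
        ``n`` unit point reflectors; positions drawn per ``seed`` or given
        explicitly as ``positions`` (μm).  Ground-truth positions returned.
    ``fibers``
        Curvilinear strokes ~1 px wide emulating thin myelin segments;
        ``params``: ``n`` (default 6), ``seed``; centrelines returned.

    Returns ``(reflectance, truth)`` where ``truth`` records the ground
    truth (bar mask / positions / centrelines).
    """
    params = dict(params or {})
    ny, nx = grid.shape
    obj = np.zeros((ny, nx))
    truth: dict = {"kind": kind}

    if kind == "usaf_bars":
        period = int(params.pop("period_px", 4))
        n_groups = int(params.pop("n_groups", 3))
        margin = int(params.pop("margin_px", 0))
        _reject_unknown(params)
        if period < 2:
            raise ValueError("bar period must be at least 2 px")
        # lay groups of horizontal and vertical bars inside the margin
        my, mx = margin, margin
        hy, hx = ny - 2 * my, nx - 2 * mx
        if hy < n_groups + 1 or hx < 8:
            raise ValueError("margin leaves no room for the bar pattern")
        gy = hy // (n_groups + 1)
        for g in range(n_groups):
            p = period * (g + 1)
            y0 = my + gy // 2 + g * gy
            y1 = min(y0 + gy - 2, ny - my)
            # vertical bars (vary along x) on the left half
            xs = np.arange(mx + hx // 8, mx + hx // 2 - 2)
            mask = ((xs - xs[0]) % p) < (p // 2)
            obj[y0:y1, xs[mask]] = 1.0
            # horizontal bars (vary along y) on the right half
            ys = np.arange(y0, y1)
            mask = ((ys - ys[0]) % p) < (p // 2)
            obj[ys[mask], mx + hx // 2 + 2: nx - mx - hx // 8] = 1.0
        truth["mask"] = obj.copy()

    elif kind == "point_scatterers":
        n = int(params.pop("n", 1))
        seed = params.pop("seed", 0)
        positions = params.pop("positions", None)
        margin = int(params.pop("margin_px", 2))
        _reject_unknown(params)
        if positions is None:
            rng = np.random.default_rng(seed)
            iy = rng.integers(margin, ny - margin, size=n)
            ix = rng.integers(margin, nx - margin, size=n)
        else:
            pos = np.asarray(positions, dtype=float).reshape(-1, 2)
            iy = np.array([grid.index_of(tuple(p))[0] for p in pos])
            ix = np.array([grid.index_of(tuple(p))[1] for p in pos])
        obj[iy, ix] = 1.0
        y, x = grid.axes()
        truth["positions"] = np.column_stack([y[iy], x[ix]])

    elif kind == "fibers":
        n = int(params.pop("n", 6))
        seed = params.pop("seed", 0)
        _reject_unknown(params)
        rng = np.random.default_rng(seed)
        centerlines = []
        for _ in range(n):
            # random gentle arc across the field
            t = np.linspace(0, 1, 4 * max(ny, nx))
            y0, x0 = rng.uniform(0.1, 0.9, 2) * (ny, nx)
            theta = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(0.4, 0.9) * min(ny, nx)
            curv = rng.uniform(-2.0, 2.0) / max(ny, nx)
            s = (t - 0.5) * length
            yline = y0 + s * np.sin(theta) + curv * s**2 * np.cos(theta)
            xline = x0 + s * np.cos(theta) - curv * s**2 * np.sin(theta)
            iy = np.round(yline).astype(int)
            ix = np.round(xline).astype(int)
            keep = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
            obj[iy[keep], ix[keep]] = 1.0
            centerlines.append(np.column_stack([yline[keep], xline[keep]]))
        truth["centerlines"] = centerlines

    else:
        raise ValueError(f"unknown object kind {kind!r}")

    return obj, truth


def _reject_unknown(params: dict) -> None:
    if params:
        raise ValueError(f"unknown object parameters: {sorted(params)}")
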