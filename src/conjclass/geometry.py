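"""Acquisition geometry and sampling-grid helpers.

All coordinates are physical micrometres.  The origin sits on the optical
axis of the full field of illumination; a lattice index ``i`` maps to the
coordinate ``origin + i * pitch`` (0-based indices, pixel centres).  The
illumination lattice and the detection grid share one global pitch so that
``W = w_o + w_in`` always lands on a lattice point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "Grid",
    "validate_geometry",
    "GridMismatchError",
    "AliasingError",
]


class GridMismatchError(ValueError):
    """Raised when field maps or lattices do not share a common grid."""


class AliasingError(ValueError):
    """Raised when a propagation/conversion would alias the quadratic phase."""


@dataclass(frozen=True)
class Grid:
    """A regular 2D grid: ``coord = origin + index * pitch`` (y, x order)."""

    shape: Tuple[int, int]
    pitch: float
    origin: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("grid pitch must be positive")
        ny, nx = self.shape
        if ny < 1 or nx < 1:
            raise ValueError("grid shape must be at least 1x1")

    @classmethod
    def centered(cls, shape: Tuple[int, int], pitch: float) -> "Grid":
        """Grid whose centre pixel (``n // 2``) sits on the origin."""
        ny, nx = shape
        return cls(shape=(ny, nx), pitch=pitch,
                   origin=(-(ny // 2) * pitch, -(nx // 2) * pitch))

    @property
    def extent(self) -> Tuple[float, float]:
        return (self.shape[0] * self.pitch, self.shape[1] * self.pitch)

    def axes(self) -> Tuple[np.ndarray, np.ndarray]:
        y = self.origin[0] + self.pitch * np.arange(self.shape[0])
        x = self.origin[1] + self.pitch * np.arange(self.shape[1])
        return y, x

    def mesh(self) -> Tuple[np.ndarray, np.ndarray]:
        y, x = self.axes()
        return np.meshgrid(y, x, indexing="ij")

    def rsq(self) -> np.ndarray:
        yy, xx = self.mesh()
        return yy**2 + xx**2

    def index_of(self, point: Tuple[float, float], atol: float = 1e-6) -> Tuple[int, int]:
        """Lattice index of a physical point; the point must be on-lattice."""
        iy = (point[0] - self.origin[0]) / self.pitch
        ix = (point[1] - self.origin[1]) / self.pitch
        jy, jx = int(round(iy)), int(round(ix))
        if abs(iy - jy) > atol or abs(ix - jx) > atol:
            raise GridMismatchError(f"point {point} is off-lattice (pitch {self.pitch})")
        return jy, jx

    def contains_index(self, idx: Tuple[int, int]) -> bool:
        return 0 <= idx[0] < self.shape[0] and 0 <= idx[1] < self.shape[1]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical parameters of a reflection-matrix acquisition.

    Parameters
    ----------
    wavelength:
        Vacuum wavelength of the source, micrometres.
    numerical_aperture:
        NA of the objective (dimensionless).
    sample_pixel_pitch:
        Camera pixel pitch referred to the sample plane, micrometres.
    scan_step:
        Spacing of the focused-illumination raster, micrometres.  Must be an
        integer multiple of ``sample_pixel_pitch`` so every scan position
        falls on the detection lattice.
    scan_shape:
        Number of illumination points per axis, (ny, nx).
    detection_extent:
        Side length of the per-illumination camera window at the sample
        plane, micrometres.
    conjugate_distance:
        Distance z from the sample plane to the aberrating layer,
        micrometres (positive when a conjugate-basis operation is used).
    medium_index:
        Refractive index of the immersion/tissue medium.
    """

    wavelength: float = 1.3
    numerical_aperture: float = 1.05
    sample_pixel_pitch: float = 0.325
    scan_step: float = 0.65
    scan_shape: Tuple[int, int] = (32, 32)
    detection_extent: float = 25.0
    conjugate_distance: float = 100.0
    medium_index: float = 1.0

    @property
    def wavenumber(self) -> float:
        """k = 2π/λ in the medium (rad/μm)."""
        return 2.0 * np.pi * self.medium_index / self.wavelength

    @property
    def wavelength_medium(self) -> float:
        return self.wavelength / self.medium_index

    @property
    def detection_shape(self) -> Tuple[int, int]:
        n = int(round(self.detection_extent / self.sample_pixel_pitch))
        return (n, n)

    @property
    def step_ratio(self) -> int:
        """scan_step / pixel pitch as an exact integer."""
        r = self.scan_step / self.sample_pixel_pitch
        ri = int(round(r))
        if abs(r - ri) > 1e-9 or ri < 1:
            raise GridMismatchError(
                f"scan_step {self.scan_step} is not an integer multiple of the "
                f"pixel pitch {self.sample_pixel_pitch}")
        return ri

    def detection_grid(self) -> Grid:
        return Grid.centered(self.detection_shape, self.sample_pixel_pitch)

    def scan_grid(self) -> Grid:
        return Grid.centered(self.scan_shape, self.scan_step)

    def scan_positions(self) -> np.ndarray:
        """(n_in, 2) array of illumination positions (y, x), row-major."""
        gy, gx = self.scan_grid().axes()
        yy, xx = np.meshgrid(gy, gx, indexing="ij")
        return np.column_stack([yy.ravel(), xx.ravel()])

    def with_(self, **kw) -> "AcquisitionGeometry":
        return replace(self, **kw)


def quadratic_phase_step_at_edge(geometry: AcquisitionGeometry, grid: Grid) -> float:
    """Largest per-pixel increment of (k/2z)|w|² anywhere on ``grid`` (rad).

    Evaluated analytically: the increment between neighbours at the outer
    corner is (k/2z)(|w+Δ|²−|w|²) ≈ (k/z)|w|Δ + (k/2z)Δ², per axis.
    """
    z = geometry.conjugate_distance
    if z <= 0:
        return np.inf
    k = geometry.wavenumber
    y, x = grid.axes()
    wmax = max(np.abs(y).max(), np.abs(x).max())
    d = grid.pitch
    return (k / z) * wmax * d + (k / (2 * z)) * d**2


def validate_geometry(geometry: AcquisitionGeometry,
                      conjugate: bool = False) -> List[str]:
    """Return the list of violated invariants (empty list = valid).

    With ``conjugate=True`` the conjugate-distance invariants are enforced,
    including the anti-aliasing condition on the quadratic conjugate-plane
    phase (per-pixel phase step must stay below π at the grid edge).
    """
    report: List[str] = []
    g = geometry
    if g.wavelength <= 0:
        report.append("wavelength must be positive")
    if g.numerical_aperture <= 0:
        report.append("numerical_aperture must be positive")
    if g.sample_pixel_pitch <= 0:
        report.append("sample_pixel_pitch must be positive")
    if g.medium_index <= 0:
        report.append("medium_index must be positive")
    try:
        g.step_ratio
    except GridMismatchError as exc:
        report.append(str(exc))
    if g.detection_extent < 4 * g.scan_step:
        report.append("detection_extent must be at least 4 x scan_step")
    if any(n < 1 for n in g.scan_shape):
        report.append("scan_shape must be positive")
    if conjugate:
        if g.conjugate_distance <= 0:
            report.append("conjugate_distance must be positive for conjugate-basis operations")
        else:
            # The W lattice spans detection window plus scan extent.
            det = g.detection_grid()
            ny, nx = det.shape
            sy = g.scan_shape[0] * g.step_ratio
            sx = g.scan_shape[1] * g.step_ratio
            wgrid = Grid.centered((ny + sy, nx + sx), g.sample_pixel_pitch)
            step = quadratic_phase_step_at_edge(g, wgrid)
            if step > np.pi:
                report.append(
                    f"conjugate-plane quadratic phase aliases: per-pixel step "
                    f"{step:.2f} rad > pi at the W-lattice edge (z={g.conjugate_distance})")
    return report
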