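"""Reflection-matrix containers.

A reflection matrix is the stack of complex backscattered field maps, one
per focused-illumination position.  Columns are indexed by the illumination
position (``r_in`` in the sample basis, ``w_in`` in the layer-conjugate
basis, ``k_in`` in the pupil basis); each column is a 2D complex field over
the detection coordinate of the same basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import AcquisitionGeometry, Grid, GridMismatchError

__all__ = [
    "FieldMap",
    "ReflectionMatrix",
    "AberrationEstimate",
    "ObjectReconstruction",
    "assemble_matrix",
    "BASES",
]

BASES = ("sample", "conjugate", "pupil")


@dataclass
class FieldMap:
    """A complex field on a regular 2D grid with physical metadata."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("FieldMap data must be 2D")
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.data.view(np.float64))):
            raise ValueError("FieldMap contains non-finite values")

    @property
    def pitch(self) -> float:
        return self.grid.pitch

    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))


@dataclass
class ReflectionMatrix:
    """Stack of per-illumination field maps on a common pixel grid.

    Parameters
    ----------
    fields:
        Complex array ``(n_in, ny, nx)``; column ``i`` is the detected field
        for illumination ``keys[i]``.
    keys:
        ``(n_in, 2)`` illumination positions ``(y, x)``; μm in the sample and
        conjugate bases, rad/μm in the pupil basis.  The keys must form a
        regular lattice.
    grid:
        Detection grid shared by all columns.  For a descanned matrix the
        grid is relative to each illumination point (each map centred on its
        own ``r_in``); otherwise it is the global grid.
    basis:
        One of ``sample | conjugate | pupil``.
    descanned:
        True when each map is still centred on its own illumination point.
        Every solver and basis conversion requires ``descanned=False``.
    """

    fields: np.ndarray
    keys: np.ndarray
    grid: Grid
    geometry: AcquisitionGeometry
    basis: str = "sample"
    descanned: bool = False
    key_pitch: Optional[float] = None  # spacing of the key lattice

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=np.complex128)
        self.keys = np.asarray(self.keys, dtype=np.float64)
        if self.fields.ndim != 3:
            raise ValueError("fields must be (n_in, ny, nx)")
        if self.keys.shape != (self.fields.shape[0], 2):
            raise ValueError("keys must be (n_in, 2)")
        if self.fields.shape[1:] != self.grid.shape:
            raise GridMismatchError(
                f"field shape {self.fields.shape[1:]} != grid {self.grid.shape}")
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.key_pitch is None:
            self.key_pitch = _infer_key_pitch(self.keys)

    @property
    def n_in(self) -> int:
        return self.fields.shape[0]

    def column(self, i: int) -> FieldMap:
        return FieldMap(self.fields[i], self.grid)

    def key_index(self, key: Tuple[float, float], atol: float = 1e-6) -> int:
        d = np.abs(self.keys - np.asarray(key)).sum(axis=1)
        i = int(np.argmin(d))
        if d[i] > atol:
            raise KeyError(f"illumination key {key} not present")
        return i

    def copy(self) -> "ReflectionMatrix":
        return ReflectionMatrix(self.fields.copy(), self.keys.copy(), self.grid,
                                self.geometry, self.basis, self.descanned,
                                self.key_pitch)

    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.fields.ravel()))

    def require(self, basis: Optional[str] = None,
                descanned: Optional[bool] = None) -> "ReflectionMatrix":
        if basis is not None and self.basis != basis:
            raise ValueError(f"operation requires {basis}-basis matrix, got {self.basis}")
        if descanned is not None and self.descanned != descanned:
            state = "descanned" if descanned else "recentred (descanned=False)"
            raise ValueError(f"operation requires a {state} matrix")
        return self


def _infer_key_pitch(keys: np.ndarray) -> float:
    """Spacing of the (regular) key lattice; 0.0 for a single key."""
    pitches = []
    for axis in (0, 1):
        vals = np.unique(np.round(keys[:, axis], 9))
        if len(vals) > 1:
            d = np.diff(vals)
            if not np.allclose(d, d[0], atol=1e-6):
                raise GridMismatchError("illumination keys are not a regular lattice")
            pitches.append(float(d[0]))
    if not pitches:
        return 0.0
    if len(pitches) == 2 and not np.isclose(pitches[0], pitches[1], atol=1e-9):
        raise GridMismatchError("key lattice pitch differs between axes")
    return pitches[0]


def assemble_matrix(field_maps: Sequence[FieldMap],
                    keys: Sequence[Tuple[float, float]],
                    geometry: AcquisitionGeometry,
                    descanned: bool = False) -> ReflectionMatrix:
    """Pack per-illumination field maps into a sample-basis ReflectionMatrix.

    All maps must share pitch and shape and the keys must form a complete
    regular lattice with no duplicates.
    """
    if len(field_maps) != len(keys):
        raise ValueError("one key per field map required")
    if len(field_maps) == 0:
        raise ValueError("empty matrix")
    ref = field_maps[0].grid
    for fm in field_maps[1:]:
        if fm.grid.shape != ref.shape or not np.isclose(fm.grid.pitch, ref.pitch):
            raise GridMismatchError("field maps do not share pitch and shape")
    karr = np.asarray(keys, dtype=np.float64).reshape(len(keys), 2)
    uniq = {tuple(np.round(k, 9)) for k in karr}
    if len(uniq) != len(karr):
        raise KeyError("duplicate illumination keys")
    fields = np.stack([fm.data for fm in field_maps])
    return ReflectionMatrix(fields, karr, ref, geometry,
                            basis="sample", descanned=descanned)


def disassemble_matrix(matrix: ReflectionMatrix) -> Tuple[List[FieldMap], np.ndarray]:
    """Inverse of :func:`assemble_matrix`."""
    maps = [matrix.column(i) for i in range(matrix.n_in)]
    return maps, matrix.keys.copy()


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    out = np.mod(np.asarray(phi, dtype=np.float64) + np.pi, 2 * np.pi) - np.pi
    # np.mod maps exact π to −π; fold back so the interval is half-open at −π
    if np.ndim(out) == 0:
        return out if out != -np.pi else np.float64(np.pi)
    out[out == -np.pi] = np.pi
    return out


@dataclass
class AberrationEstimate:
    """Accumulated input/output correction phases on the conjugate grid.

    ``phi_in`` lives on the illumination (w_in) lattice, ``phi_out`` on the
    detection (w_o) grid; both wrapped to (−π, π] with the gauge pixel (the
    lattice point nearest the optical axis) pinned to exactly 0.  The
    quadratic/screen split is filled by ``decompose_aberration``.
    """

    phi_in: np.ndarray
    phi_out: np.ndarray
    in_grid: Grid
    out_grid: Grid
    update_rms_in: List[float] = field(default_factory=list)
    update_rms_out: List[float] = field(default_factory=list)
    spectrum_energy: List[float] = field(default_factory=list)
    converged: bool = False
    diverged: bool = False
    phi_quad_in: Optional[np.ndarray] = None
    phi_screen_in: Optional[np.ndarray] = None
    phi_quad_out: Optional[np.ndarray] = None
    phi_screen_out: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.phi_in = wrap_phase(self.phi_in)
        self.phi_out = wrap_phase(self.phi_out)
        for phi, grid, name in ((self.phi_in, self.in_grid, "phi_in"),
                                (self.phi_out, self.out_grid, "phi_out")):
            gy, gx = _gauge_index(grid)
            if abs(phi[gy, gx]) > 1e-12:
                raise ValueError(f"{name} gauge pixel is not zero")
        hist = np.asarray(self.update_rms_in + self.update_rms_out, dtype=float)
        if hist.size and (not np.all(np.isfinite(hist)) or np.any(hist < 0)):
            raise ValueError("update-magnitude history must be finite and non-negative")


def _gauge_index(grid: Grid) -> Tuple[int, int]:
    """Index of the lattice point nearest the optical axis (w = 0)."""
    y, x = grid.axes()
    return int(np.argmin(np.abs(y))), int(np.argmin(np.abs(x)))


@dataclass
class ObjectReconstruction:
    """Coherently accumulated object spectrum and the reconstructed object.

    ``spectrum`` is the accumulated Õ_M on the W lattice (count-normalised:
    per-pixel mean over present columns scaled by N).  ``object_field`` is
    O_M(r) on ``object_grid``; ``reflectance`` is O(r) with the geometric
    quadratic phase exp{i(k/z)|r|²} removed; ``intensity`` is |O|².
    """

    spectrum: np.ndarray
    counts: np.ndarray
    w_grid: Grid
    n_accumulated: int
    object_field: Optional[np.ndarray] = None
    reflectance: Optional[np.ndarray] = None
    intensity: Optional[np.ndarray] = None
    object_grid: Optional[Grid] = None

    def spectrum_energy(self) -> float:
        return float(np.sum(np.abs(self.spectrum) ** 2))

    def peak_spectrum_intensity(self) -> float:
        return float(np.max(np.abs(self.spectrum) ** 2))
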