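"""Separable non-uniform DFT between a spatial grid and a q-lattice.

The conjugate-basis model evaluates the object spectrum at spatial
frequencies q = k W / z on the (Minkowski-sum) W lattice, which in general
is not the FFT lattice of the object grid.  Both directions are computed as
exact separable matrix products (a "chirp DFT"), so the simulator and the
image reconstruction agree with the continuous-model formulas to machine
precision on the lattice.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .geometry import Grid

__all__ = ["spectrum_from_object", "object_from_spectrum", "q_axes_for_w_grid"]


def q_axes_for_w_grid(w_grid: Grid, k: float, z: float) -> Tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency axes q = k w / z (rad/μm) for a conjugate W grid."""
    wy, wx = w_grid.axes()
    return k * wy / z, k * wx / z


def spectrum_from_object(obj: np.ndarray, obj_grid: Grid,
                         qy: np.ndarray, qx: np.ndarray) -> np.ndarray:
    """Õ(q) = Σ_r O(r) e^{-i q·r} Δr²  evaluated on the (qy × qx) lattice."""
    y, x = obj_grid.axes()
    Ay = np.exp(-1j * np.outer(qy, y)) * obj_grid.pitch
    Ax = np.exp(-1j * np.outer(qx, x)) * obj_grid.pitch
    return Ay @ np.asarray(obj, dtype=np.complex128) @ Ax.T


def object_from_spectrum(spec: np.ndarray, qy: np.ndarray, qx: np.ndarray,
                         out_grid: Grid) -> np.ndarray:
    """O(r) = (1/2π)² Σ_q Õ(q) e^{+i q·r} Δq²  on ``out_grid``.

    Inverse of :func:`spectrum_from_object` in the continuum limit; with a
    finite q window it returns the band-limited reconstruction.
    """
    y, x = out_grid.axes()
    dqy = qy[1] - qy[0] if len(qy) > 1 else 1.0
    dqx = qx[1] - qx[0] if len(qx) > 1 else 1.0
    By = np.exp(1j * np.outer(y, qy)) * (dqy / (2 * np.pi))
    Bx = np.exp(1j * np.outer(x, qx)) * (dqx / (2 * np.pi))
    return By @ np.asarray(spec, dtype=np.complex128) @ Bx.T
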