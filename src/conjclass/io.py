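"""Container read/write (HDF5) and image export (32-bit float TIFF)."""

from __future__ import annotations

from typing import Dict, Optional

import h5py
import numpy as np
import tifffile

from .geometry import AcquisitionGeometry, Grid
from .matrix import ReflectionMatrix

__all__ = ["read_matrix", "write_matrix", "export_tiff", "read_tiff",
           "CONTAINER_VERSION", "ContainerVersionError", "ContainerIntegrityError"]

CONTAINER_VERSION = "conjclass-rm-v1"

_GEOMETRY_ATTRS = ("wavelength", "numerical_aperture", "sample_pixel_pitch",
                   "scan_step", "scan_shape", "detection_extent",
                   "conjugate_distance", "medium_index")


class ContainerVersionError(RuntimeError):
    pass


class ContainerIntegrityError(RuntimeError):
    pass


def write_matrix(matrix: ReflectionMatrix, path, truth: Optional[Dict] = None,
                 seeds: Optional[Dict] = None) -> str:
    """Write a ReflectionMatrix (and optional ground truth) to HDF5.

    Layout: group ``/matrix`` with datasets ``fields`` (complex,
    [n_in, ny, nx], chunked per illumination position) and ``keys``
    ([n_in, 2]), geometry/basis attributes, and the container version tag.
    """
    path = str(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("matrix")
        g.create_dataset("fields", data=matrix.fields,
                         chunks=(1,) + matrix.grid.shape)
        g.create_dataset("keys", data=matrix.keys)
        g.attrs["version"] = CONTAINER_VERSION
        g.attrs["basis"] = matrix.basis
        g.attrs["descanned"] = bool(matrix.descanned)
        g.attrs["key_pitch"] = matrix.key_pitch
        g.attrs["grid_pitch"] = matrix.grid.pitch
        g.attrs["grid_origin"] = matrix.grid.origin
        geo = matrix.geometry
        for name in _GEOMETRY_ATTRS:
            g.attrs[f"geometry_{name}"] = getattr(geo, name)
        if truth:
            t = f.create_group("truth")
            for key, val in truth.items():
                if isinstance(val, np.ndarray):
                    t.create_dataset(key, data=val)
                elif isinstance(val, (int, float, str, bool)):
                    t.attrs[key] = val
        if seeds:
            s = f.create_group("seeds")
            for key, val in seeds.items():
                if val is not None:
                    s.attrs[key] = val
    return path


def read_matrix(path) -> ReflectionMatrix:
    """Read a ReflectionMatrix written by :func:`write_matrix`."""
    with h5py.File(str(path), "r") as f:
        if "matrix" not in f:
            raise ContainerIntegrityError("missing /matrix group")
        g = f["matrix"]
        version = g.attrs.get("version")
        if version != CONTAINER_VERSION:
            raise ContainerVersionError(
                f"container version {version!r} is not {CONTAINER_VERSION!r}; "
                f"re-export or upgrade the file")
        missing = [a for a in ("fields", "keys") if a not in g]
        missing += [f"geometry_{n}" for n in _GEOMETRY_ATTRS
                    if f"geometry_{n}" not in g.attrs]
        for a in ("basis", "descanned", "grid_pitch", "grid_origin"):
            if a not in g.attrs:
                missing.append(a)
        if missing:
            raise ContainerIntegrityError(f"missing fields: {sorted(missing)}")
        fields = g["fields"][...]
        keys = g["keys"][...]
        geo_kwargs = {n: g.attrs[f"geometry_{n}"] for n in _GEOMETRY_ATTRS}
        geo_kwargs["scan_shape"] = tuple(int(v) for v in np.atleast_1d(geo_kwargs["scan_shape"]))
        geometry = AcquisitionGeometry(**{k: (float(v) if k != "scan_shape" else v)
                                          for k, v in geo_kwargs.items()})
        grid = Grid(fields.shape[1:], float(g.attrs["grid_pitch"]),
                    tuple(float(v) for v in g.attrs["grid_origin"]))
        return ReflectionMatrix(fields, keys, grid, geometry,
                                basis=str(g.attrs["basis"]),
                                descanned=bool(g.attrs["descanned"]),
                                key_pitch=float(g.attrs["key_pitch"]))


def export_tiff(image: np.ndarray, path, pixel_size: float,
                allow_nan: bool = False, metadata: Optional[Dict] = None) -> str:
    """Write a 32-bit float TIFF with pixel-size metadata (μm)."""
    img = np.asarray(image, dtype=np.float32)
    if not allow_nan and not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN/inf pixels (pass allow_nan=True to force)")
    path = str(path)
    res = 1.0 / pixel_size  # pixels per micrometre
    meta = {"axes": "YX", "PixelSizeUm": float(pixel_size)}
    if metadata:
        meta.update(metadata)
    tifffile.imwrite(path, img, resolution=(res, res),
                     resolutionunit="NONE", metadata=meta)
    return path


def read_tiff(path) -> tuple[np.ndarray, float]:
    """Read a TIFF written by :func:`export_tiff`; returns (image, pixel size)."""
    with tifffile.TiffFile(str(path)) as tf:
        img = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        pixel = float(meta.get("PixelSizeUm", 0.0))
    return img, pixel
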