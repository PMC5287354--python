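"""Density maps and tilt series, with MRC2014 file I/O.

A :class:`DensityMap` is a 3D scalar grid with an isotropic voxel size in
Ångström and an origin vector in Å. Arrays are indexed ``data[ix, iy, iz]``
so a voxel's index triple is its Cartesian position in voxel units; the MRC
file written for such a map has x as the fast (column) axis, which is the
common convention for tomography software.

Tilt series are stored as MRC image stacks (one section per tilt) with the
tilt angles in a plain-text ``.tlt`` sidecar, one angle in degrees per line,
and optional per-tilt defoci in a two-column ``(angle, defocus_A)`` sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

from .errors import FormatError, ShapeError, ValidationError

__all__ = [
    "DensityMap",
    "TiltSeries",
    "read_map",
    "write_map",
    "read_tilt_series",
    "write_tilt_series",
]


@dataclasses.dataclass
class DensityMap:
    """3D scalar grid with voxel size (Å) and origin (Å)."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ShapeError(f"all grid dimensions must be >= 1, got {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValidationError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "DensityMap":
        return DensityMap(self.data.copy(), self.voxel_size, self.origin.copy())

    def with_data(self, data: np.ndarray) -> "DensityMap":
        """Same geometry, new grid values."""
        return DensityMap(np.asarray(data), self.voxel_size, self.origin.copy())


@dataclasses.dataclass
class TiltSeries:
    """Ordered stack of projection images with acquisition geometry.

    ``images`` has shape ``(n_tilts, nx, ny)`` with the same in-plane axis
    convention as :class:`DensityMap`; the tilt axis at zero in-plane
    rotation is the image y-axis.
    """

    images: np.ndarray
    angles: np.ndarray
    pixel_size: float
    tilt_axis_angle: float = 0.0
    defoci: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ShapeError("images must be a (n_tilts, nx, ny) stack")
        if len(self.angles) != self.images.shape[0]:
            raise ShapeError("one tilt angle required per image")
        if self.defoci is not None:
            self.defoci = np.asarray(self.defoci, dtype=float)
            if len(self.defoci) != len(self.angles):
                raise ShapeError("one defocus required per image")

    def __len__(self) -> int:
        return self.images.shape[0]

    def copy(self) -> "TiltSeries":
        return TiltSeries(
            self.images.copy(), self.angles.copy(), self.pixel_size,
            self.tilt_axis_angle, None if self.defoci is None else self.defoci.copy(),
        )


# MRC2014 header words (1-based) for the origin record.
_ORIGIN_WORDS = (50, 51, 52)


def write_map(path, density: DensityMap) -> None:
    """Write a volume as 32-bit float MRC2014 (mode 2)."""
    data = np.asarray(density.data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValidationError("refusing to write non-finite density values")
    grid = gemmi.FloatGrid(*data.shape)
    np.asarray(grid.array)[...] = data
    nx, ny, nz = data.shape
    v = float(density.voxel_size)
    grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip(_ORIGIN_WORDS, density.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    """Read an MRC volume written by :func:`write_map` or compatible tools."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"not a readable MRC volume: {path}: {exc}") from exc
    data = np.ascontiguousarray(np.asarray(ccp4.grid.array), dtype=np.float32)
    if data.ndim != 3 or 1 in data.shape:
        raise ShapeError(f"expected a 3D volume in {path}, got shape {data.shape}")
    spacing = np.asarray(ccp4.grid.spacing)
    if spacing.max() - spacing.min() > 1e-4 * spacing.max():
        raise FormatError(f"anisotropic voxel size {spacing} unsupported")
    origin = np.array([ccp4.header_float(w) for w in _ORIGIN_WORDS])
    return DensityMap(data, float(spacing.mean()), origin)


def write_tilt_series(path, ts: TiltSeries) -> None:
    """Write a tilt series as an MRC stack plus ``.tlt`` angle sidecar."""
    # stack sections along the last (z) axis so section i is image i
    vol = np.ascontiguousarray(np.moveaxis(ts.images, 0, -1), dtype=np.float32)
    write_map(path, DensityMap(vol, ts.pixel_size))
    path = Path(path)
    tlt = path.with_suffix(".tlt")
    np.savetxt(tlt, ts.angles, fmt="%.3f")
    if ts.defoci is not None:
        np.savetxt(path.with_suffix(".defocus"),
                   np.column_stack([ts.angles, ts.defoci]), fmt="%.3f %.1f")


def read_tilt_series(path) -> TiltSeries:
    path = Path(path)
    vol = read_map(path)
    images = np.moveaxis(vol.data, -1, 0)
    angles = np.loadtxt(path.with_suffix(".tlt"), ndmin=1)
    if len(angles) != images.shape[0]:
        raise ShapeError("angle file does not match image count")
    defocus_path = path.with_suffix(".defocus")
    defoci = None
    if defocus_path.exists():
        table = np.loadtxt(defocus_path, ndmin=2)
        defoci = table[:, 1]
    return TiltSeries(images, angles, vol.voxel_size, defoci=defoci)
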