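"""Forward projection, noise and weighted back-projection.

The imaging model is a parallel-beam line integral: at tilt angle ``t`` the
beam direction is the z-axis rotated by ``t`` about the tilt axis (the
image y-axis when ``tilt_axis_angle`` is zero). Projections are computed by
rigidly resampling the scene onto a beam-aligned grid (trilinear) and
summing along the beam, so the sum over each image conserves the total
scene mass up to interpolation error.

Reconstruction is weighted back-projection: each image is ramp-filtered
(|f| weighting) along the in-plane direction perpendicular to the tilt
axis, then smeared back along its rays. The global scale of the output is
arbitrary, as usual for WBP.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ShapeError
from .geometry import box_centre
from .maps import DensityMap, TiltSeries

__all__ = ["TiltScheme", "project_tilt_series", "add_noise", "reconstruct_wbp"]


@dataclasses.dataclass
class TiltScheme:
    """Acquisition geometry: tilt angles (degrees), in-plane tilt-axis
    orientation and optional per-tilt defocus (Å)."""

    angles: np.ndarray
    tilt_axis_angle: float = 0.0
    per_tilt_defocus: np.ndarray | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) == 0:
            raise ParameterError("tilt scheme must contain at least one angle")
        if np.any(np.abs(self.angles) > 90):
            raise ParameterError("tilt angles must satisfy |angle| <= 90")
        diffs = np.diff(self.angles)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ParameterError("tilt angles must be strictly monotone")
        if self.per_tilt_defocus is not None:
            self.per_tilt_defocus = np.asarray(self.per_tilt_defocus, dtype=float)
            if len(self.per_tilt_defocus) != len(self.angles):
                raise ShapeError("per-tilt defocus must match the number of angles")

    @classmethod
    def symmetric(cls, max_tilt: float = 60.0, step: float = 3.0, tilt_axis_angle: float = 0.0):
        """The conventional ±max_tilt scheme in fixed increments."""
        n = int(round(2 * max_tilt / step)) + 1
        return cls(np.linspace(-max_tilt, max_tilt, n), tilt_axis_angle)


def _beam_rotation(tilt_deg: float, axis_deg: float) -> np.ndarray:
    """Rotation taking beam-frame coordinates to scene coordinates."""
    t, g = np.radians(tilt_deg), np.radians(axis_deg)
    ry = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])
    rz = np.array([[np.cos(g), -np.sin(g), 0], [np.sin(g), np.cos(g), 0], [0, 0, 1]])
    return rz @ ry @ rz.T


def project_tilt_series(scene: DensityMap, scheme: TiltScheme) -> TiltSeries:
    """Parallel-beam projection of the scene for every tilt angle."""
    data = scene.data.astype(np.float32)
    nx, ny, nz = data.shape
    if abs(scheme.tilt_axis_angle) > 1e-9:
        depth = int(np.ceil(np.sqrt(nx * nx + ny * ny + nz * nz))) + 2
    else:
        depth = int(np.ceil(np.hypot(nx, nz))) + 2
    c_in = box_centre(data.shape)
    out_shape = (nx, ny, depth)
    c_out = box_centre(out_shape)
    images = np.empty((len(scheme.angles), nx, ny), dtype=np.float32)
    for i, tilt in enumerate(scheme.angles):
        rot = _beam_rotation(tilt, scheme.tilt_axis_angle)
        offset = c_in - rot @ c_out
        beam_grid = ndimage.affine_transform(
            data, rot, offset=offset, output_shape=out_shape, order=1,
            mode="constant", cval=0.0,
        )
        images[i] = beam_grid.sum(axis=2)
    return TiltSeries(images, scheme.angles.copy(), scene.voxel_size,
                      scheme.tilt_axis_angle,
                      None if scheme.per_tilt_defocus is None else scheme.per_tilt_defocus.copy())


def add_noise(ts: TiltSeries, snr: float, seed: int) -> TiltSeries:
    """Additive white Gaussian noise with variance ``var(signal) / snr``.

    ``snr = inf`` returns an identical copy. The signal variance is taken
    over the whole stack so every tilt receives the same noise level.
    """
    if not snr > 0:
        raise ParameterError("snr must be > 0")
    out = ts.copy()
    if np.isinf(snr):
        return out
    rng = np.random.default_rng(seed)
    sigma = float(np.std(ts.images)) / np.sqrt(snr)
    out.images = ts.images + rng.normal(0.0, sigma, ts.images.shape).astype(np.float32)
    return out


def _ramp_filter(images: np.ndarray) -> np.ndarray:
    """Ram-Lak |f| filtering along the in-plane axis perpendicular to the
    tilt axis (image x)."""
    n = images.shape[1]
    freq = np.fft.rfftfreq(n)
    spec = np.fft.rfft(images, axis=1)
    spec *= freq[None, :, None]
    return np.fft.irfft(spec, n=n, axis=1)


def reconstruct_wbp(ts: TiltSeries, depth: int | None = None) -> DensityMap:
    """Weighted back-projection of a tilt series into a volume.

    ``depth`` is the z-extent of the output (defaults to the image x size).
    Only a tilt axis along the image y-axis is supported.
    """
    if abs(ts.tilt_axis_angle) > 1e-9:
        raise ParameterError("reconstruction requires the tilt axis along y")
    if ts.images.ndim != 3:
        raise ShapeError("tilt series images must form a 3D stack")
    n_tilt, nx, ny = ts.images.shape
    nz = int(depth) if depth is not None else nx
    filtered = _ramp_filter(ts.images.astype(np.float64))
    vol = np.zeros((nx, ny, nz), dtype=np.float64)
    cx, cz, cu = (nx - 1) / 2.0, (nz - 1) / 2.0, (nx - 1) / 2.0
    xc = np.arange(nx) - cx
    zc = np.arange(nz) - cz
    for i, tilt in enumerate(ts.angles):
        t = np.radians(tilt)
        # u-coordinate of each (x, z) column in the beam-aligned image frame
        u = xc[:, None] * np.cos(t) - zc[None, :] * np.sin(t) + cu
        iu = np.floor(u).astype(int)
        frac = u - iu
        valid = (iu >= 0) & (iu < nx - 1)
        iu_c = np.clip(iu, 0, nx - 2)
        img = filtered[i]
        lo = img[iu_c.ravel(), :].reshape(nx, nz, ny)
        hi = img[(iu_c + 1).ravel(), :].reshape(nx, nz, ny)
        contrib = lo * (1.0 - frac[..., None]) + hi * frac[..., None]
        contrib *= valid[..., None]
        vol += np.moveaxis(contrib, 2, 1)
    vol *= np.pi / (2.0 * n_tilt)
    return DensityMap(vol.astype(np.float32), ts.pixel_size)
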