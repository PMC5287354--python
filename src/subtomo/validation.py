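"""Map validation: FSC with several masking regimes, resolution readout,
comparison against an ideal reference, helical-lattice spectral diagnostics
and back-plotting of averages into tomograms.

Fourier shell correlation is computed in shells one Fourier voxel wide with
no shell smoothing. Resolution is reported at the *first* downward crossing
of the threshold (0.5 and 0.143 are the conventional cuts) because noisy
curves can re-cross at high frequency; when the curve never crosses, the
Nyquist limit is returned with a ``crossed=False`` flag. Tight masks are
known to inflate the correlation of pure noise between half-maps — the
package's null-statistics tests reproduce this caution.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ShapeError
from .geometry import box_centre, euler_to_matrix
from .maps import DensityMap

__all__ = [
    "MaskSpec",
    "make_mask",
    "FSCCurve",
    "compute_fsc",
    "ResolutionResult",
    "resolution_at",
    "fsc_to_ideal",
    "lowpass_map",
    "gaussian_lowpass_to_nyquist",
    "rotational_power_spectrum",
    "dominant_angular_order",
    "layer_line_profile",
    "peak_axial_spacing",
    "backplot",
    "count_surface_maxima",
    "write_fsc_curve",
]

MASK_KINDS = ("none", "threshold_soft", "cylinder_hard", "cylinder_soft")


@dataclasses.dataclass
class MaskSpec:
    """Recipe for an FSC mask."""

    kind: str = "none"
    threshold: float | None = None
    radius: float | None = None  # Å, cylinder kinds
    soft_edge: float = 0.0  # Å

    def __post_init__(self):
        if self.kind not in MASK_KINDS:
            raise ParameterError(f"mask kind must be one of {MASK_KINDS}")
        if self.soft_edge < 0:
            raise ParameterError("soft_edge must be >= 0")
        if self.kind.startswith("cylinder") and not (self.radius and self.radius > 0):
            raise ParameterError("cylinder masks need radius > 0")


def _cosine_falloff(distance: np.ndarray, soft_edge: float) -> np.ndarray:
    if soft_edge <= 0:
        return (distance <= 0).astype(np.float32)
    x = np.clip(distance / soft_edge, 0.0, 1.0)
    return (0.5 + 0.5 * np.cos(np.pi * x)).astype(np.float32)


def make_mask(spec: MaskSpec, shape, voxel_size: float,
              reference: DensityMap | None = None) -> np.ndarray:
    """Build a [0, 1] mask volume; cylinder axes run along z."""
    shape = tuple(int(n) for n in shape)
    if spec.kind == "none":
        return np.ones(shape, dtype=np.float32)
    if spec.kind in ("cylinder_hard", "cylinder_soft"):
        c = box_centre(shape)
        x = (np.arange(shape[0]) - c[0]) * voxel_size
        y = (np.arange(shape[1]) - c[1]) * voxel_size
        r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
        if spec.kind == "cylinder_hard":
            plane = (r <= spec.radius).astype(np.float32)
        else:
            plane = _cosine_falloff(r - spec.radius, spec.soft_edge)
            plane[r <= spec.radius] = 1.0
        return np.repeat(plane[:, :, None], shape[2], axis=2)
    # threshold_soft: binarise the reference and extend with a soft edge
    if reference is None:
        raise ParameterError("threshold_soft mask requires a reference map")
    binary = reference.data >= spec.threshold
    if not binary.any():
        raise ParameterError("threshold leaves an empty mask")
    dist = ndimage.distance_transform_edt(~binary) * voxel_size
    out = _cosine_falloff(dist, spec.soft_edge)
    out[binary] = 1.0
    return out


@dataclasses.dataclass
class FSCCurve:
    """Per-shell spatial frequency (1/Å) and correlation."""

    freq: np.ndarray
    corr: np.ndarray
    mask_kind: str = "none"

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        if len(self.freq) != len(self.corr):
            raise ShapeError("freq and corr must have equal length")
        if np.any(np.diff(self.freq) <= 0):
            raise ParameterError("freq must be strictly increasing")


def _shell_index(shape, voxel_size):
    n = shape[0]
    if len(set(shape)) != 1:
        raise ShapeError("FSC requires a cubic box")
    freqs = [np.fft.fftfreq(n, d=voxel_size)] * 3
    r = np.sqrt(freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
                + freqs[2][None, None, :] ** 2)
    df = 1.0 / (n * voxel_size)
    idx = np.round(r / df).astype(int)
    n_shell = n // 2 + 1
    return np.minimum(idx, n_shell), n_shell, df


def compute_fsc(map_a: DensityMap, map_b: DensityMap,
                mask: np.ndarray | None = None, mask_kind: str = "none") -> FSCCurve:
    """Fourier shell correlation of two maps (optionally masked).

    Shells are one Fourier voxel wide; shell 0 is the DC term and the last
    shell sits at the Nyquist frequency.
    """
    if map_a.shape != map_b.shape:
        raise ShapeError("maps must share a shape")
    if abs(map_a.voxel_size - map_b.voxel_size) > 1e-6 * map_a.voxel_size:
        raise ParameterError("maps must share a voxel size")
    a = map_a.data.astype(np.float64)
    b = map_b.data.astype(np.float64)
    if mask is not None:
        a = a * mask
        b = b * mask
    idx, n_shell, df = _shell_index(a.shape, map_a.voxel_size)
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    idx_flat = idx.ravel()
    cross = np.bincount(idx_flat, weights=(fa * np.conj(fb)).real.ravel(), minlength=n_shell + 1)
    pa = np.bincount(idx_flat, weights=np.abs(fa).ravel() ** 2, minlength=n_shell + 1)
    pb = np.bincount(idx_flat, weights=np.abs(fb).ravel() ** 2, minlength=n_shell + 1)
    cross, pa, pb = cross[:n_shell], pa[:n_shell], pb[:n_shell]
    denom = np.sqrt(pa * pb)
    corr = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)
    freq = np.arange(n_shell) * df
    return FSCCurve(freq, corr, mask_kind)


@dataclasses.dataclass
class ResolutionResult:
    resolution: float  # Å
    frequency: float  # 1/Å
    crossed: bool


def resolution_at(curve: FSCCurve, threshold: float) -> ResolutionResult:
    """Resolution at the first downward threshold crossing (linear
    interpolation between shells); Nyquist with ``crossed=False`` if the
    curve never drops below the threshold."""
    if not 0 < threshold < 1:
        raise ParameterError("threshold must lie in (0, 1)")
    corr, freq = curve.corr, curve.freq
    for i in range(1, len(corr)):
        if corr[i - 1] >= threshold > corr[i]:
            frac = (corr[i - 1] - threshold) / (corr[i - 1] - corr[i])
            f = freq[i - 1] + frac * (freq[i] - freq[i - 1])
            return ResolutionResult(1.0 / f, f, True)
    f_nyq = freq[-1]
    return ResolutionResult(1.0 / f_nyq if f_nyq > 0 else np.inf, f_nyq, False)


def fsc_to_ideal(average: DensityMap, ideal: DensityMap) -> FSCCurve:
    """Unmasked FSC between an experimental average and a noiseless
    reference already matched in sampling and box size."""
    return compute_fsc(average, ideal, mask=None, mask_kind="none")


def lowpass_map(density: DensityMap, resolution: float, edge_shells: float = 2.0) -> DensityMap:
    """Cosine-edge low-pass filter; the pass band ends exactly at
    ``1/resolution`` so power beyond the cut is removed."""
    if resolution <= 0:
        raise ParameterError("resolution must be > 0")
    shape = density.shape
    freqs = [np.fft.fftfreq(n, d=density.voxel_size) for n in shape]
    r = np.sqrt(freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
                + freqs[2][None, None, :] ** 2)
    fc = 1.0 / resolution
    width = edge_shells / (shape[0] * density.voxel_size)
    width = min(width, fc)
    x = np.clip((fc - r) / width, 0.0, 1.0)
    taper = 0.5 - 0.5 * np.cos(np.pi * x)
    out = np.fft.ifftn(np.fft.fftn(density.data) * taper).real
    return density.with_data(out.astype(np.float32))


def gaussian_lowpass_to_nyquist(density: DensityMap) -> DensityMap:
    """Gaussian blur with 1/e half-width at the Nyquist frequency, the
    conventional way to band-match an ideal model to an experimental map."""
    sigma_f = 0.5 / density.voxel_size  # Nyquist in 1/Å
    sigma_r = 1.0 / (2.0 * np.pi * sigma_f / np.sqrt(2.0)) / density.voxel_size
    return density.with_data(ndimage.gaussian_filter(density.data.astype(np.float32), sigma_r))


def rotational_power_spectrum(density: DensityMap, radius_band, n_theta: int = 256,
                              z_frac: float = 0.5):
    """Angular Fourier power of the cylindrically unwrapped density.

    The density is sampled on rings of radii spanning ``radius_band``
    (Å, helix axis along z) over the central ``z_frac`` of the box, the
    angular FFT taken per ring and the power averaged over rings (area
    weighted) and z. Returns ``(orders, power)``.
    """
    rmin, rmax = radius_band
    voxel = density.voxel_size
    shape = density.shape
    c = box_centre(shape)
    if rmax <= rmin or rmax > min(shape[0], shape[1]) / 2.0 * voxel:
        raise ParameterError("radius band outside the map")
    radii = np.arange(rmin, rmax + 1e-9, voxel)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    nz = shape[2]
    z_lo = int(nz * (0.5 - z_frac / 2.0))
    z_hi = max(z_lo + 1, int(nz * (0.5 + z_frac / 2.0)))
    zs = np.arange(z_lo, z_hi)
    rr, tt, zz = np.meshgrid(radii / voxel, theta, zs, indexing="ij")
    coords = np.stack([c[0] + rr * np.cos(tt), c[1] + rr * np.sin(tt), zz])
    vals = ndimage.map_coordinates(density.data.astype(np.float64),
                                   coords.reshape(3, -1), order=1).reshape(rr.shape)
    spec = np.fft.rfft(vals, axis=1)
    power = np.abs(spec) ** 2
    weights = (radii / radii.sum())[:, None, None]
    profile = (power * weights).sum(axis=(0, 2)) / len(zs)
    orders = np.arange(profile.shape[0])
    return orders, profile


def dominant_angular_order(orders, power, min_order: int = 1, max_order: int | None = None) -> int:
    """Angular order with maximal power, ignoring the rotationally
    invariant order-0 term."""
    orders = np.asarray(orders)
    power = np.asarray(power)
    sel = orders >= min_order
    if max_order is not None:
        sel &= orders <= max_order
    return int(orders[sel][np.argmax(power[sel])])


def layer_line_profile(density: DensityMap):
    """Axial spectral power: |F|^2 integrated over in-plane frequency as a
    function of axial frequency (helix axis along z). Returns
    ``(freq_z 1/Å, power)`` for the non-negative axial frequencies."""
    power = np.abs(np.fft.fftn(density.data.astype(np.float64))) ** 2
    prof_full = power.sum(axis=(0, 1))
    nz = density.shape[2]
    n_half = nz // 2 + 1
    prof = prof_full[:n_half].copy()
    for k in range(1, nz - n_half + 1):
        prof[k] += prof_full[nz - k]
    freq = np.arange(n_half) / (nz * density.voxel_size)
    return freq, prof


def peak_axial_spacing(freq, power, min_freq: float = 0.0) -> float:
    """Repeat distance (Å) at the dominant layer line, with parabolic
    sub-shell refinement of the peak frequency.

    A layer line is a *local* maximum of the axial power profile; the
    strongest one above ``min_freq`` is reported. Requiring a local
    maximum excludes the smooth, monotonically falling box-scale envelope
    that dominates the lowest shells of a small-particle average."""
    freq = np.asarray(freq)
    power = np.asarray(power)
    sel = np.flatnonzero(freq > min_freq)
    local = [i for i in sel
             if 0 < i < len(power) - 1 and power[i] > power[i - 1] and power[i] >= power[i + 1]]
    if local:
        i = max(local, key=lambda j: power[j])
    else:
        i = sel[np.argmax(power[sel])]
    f = freq[i]
    if 0 < i < len(freq) - 1:
        lo, mid, hi = power[i - 1], power[i], power[i + 1]
        denom = lo - 2 * mid + hi
        if abs(denom) > 0:
            f += np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5) * (freq[1] - freq[0])
    return float(1.0 / f)


def backplot(shape, average: DensityMap, particles, mode: str = "max") -> DensityMap:
    """Paint the average into an empty volume at every particle pose.

    ``mode='sum'`` accumulates overlapping copies; the default ``'max'``
    takes the voxelwise maximum, which avoids double-counting density where
    picked boxes overlap along a filament. Particles whose support falls
    outside the volume are clipped.
    """
    if mode not in ("sum", "max"):
        raise ParameterError("mode must be 'sum' or 'max'")
    shape = tuple(int(n) for n in shape)
    voxel = average.voxel_size
    canvas = np.zeros(shape, dtype=np.float32)
    avg = average.data.astype(np.float32)
    c_avg = box_centre(avg.shape)
    reach = int(np.ceil(np.linalg.norm(avg.shape) / 2.0)) + 1
    for centre, euler, shift in zip(particles.centres, particles.eulers, particles.shifts):
        pos = (centre / voxel) + (np.asarray(shift) / voxel)
        lo = np.maximum(np.floor(pos - reach).astype(int), 0)
        hi = np.minimum(np.ceil(pos + reach).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        rot = euler_to_matrix(euler)
        rinv = rot.T
        offset = c_avg - rinv @ (pos - lo)
        block = ndimage.affine_transform(avg, rinv, offset=offset,
                                         output_shape=tuple(hi - lo), order=1,
                                         mode="constant", cval=0.0)
        view = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if mode == "sum":
            view += block
        else:
            np.maximum(view, block, out=view)
    return DensityMap(canvas, voxel)


def count_surface_maxima(density: DensityMap, radius: float, level_frac: float = 0.5,
                         min_separation_deg: float = 15.0, n_grid: int = 180) -> int:
    """Count distinct density maxima on a sphere of the given radius (Å).

    The sphere is sampled on an angular grid, points above
    ``level_frac * max`` are clustered greedily by angular distance, and
    the number of clusters returned — e.g. the vertex-marker sites of a
    symmetrised capsid."""
    c = box_centre(density.shape)
    theta = np.linspace(0.0, np.pi, n_grid // 2 + 1)[1:-1]
    phi = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)])
    coords = c[:, None, None] + dirs * (radius / density.voxel_size)
    vals = ndimage.map_coordinates(density.data.astype(np.float64),
                                   coords.reshape(3, -1), order=1).reshape(tt.shape)
    level = level_frac * vals.max()
    sel = vals > level
    pts = dirs[:, sel].T
    scores = vals[sel]
    order = np.argsort(scores)[::-1]
    centres: list[np.ndarray] = []
    cos_min = np.cos(np.radians(min_separation_deg))
    for i in order:
        d = pts[i]
        if all(float(d @ q) < cos_min for q in centres):
            centres.append(d)
    return len(centres)


def radial_density_profile(density: DensityMap, z_frac: float = 0.3):
    """Rotationally and axially averaged density versus cylinder radius
    (helix axis along z; the axial average spans the central ``z_frac``)."""
    nx, ny, nz = density.shape
    c = box_centre(density.shape)
    x = (np.arange(nx) - c[0]) * density.voxel_size
    y = (np.arange(ny) - c[1]) * density.voxel_size
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    z_lo = int(nz * (0.5 - z_frac / 2.0))
    z_hi = max(z_lo + 1, int(nz * (0.5 + z_frac / 2.0)))
    plane = density.data[:, :, z_lo:z_hi].mean(axis=2)
    edges = np.arange(0.0, r.max(), density.voxel_size)
    idx = np.digitize(r.ravel(), edges)
    sums = np.bincount(idx, weights=plane.ravel(), minlength=len(edges) + 2)
    counts = np.maximum(np.bincount(idx, minlength=len(edges) + 2), 1)
    return edges, (sums / counts)[1:len(edges) + 1]


def outer_half_max_diameter(radii, profile) -> float:
    """Twice the radius of the outer half-maximum crossing of a radial
    profile (linear interpolation between samples)."""
    profile = np.asarray(profile, dtype=float)
    i_pk = int(np.argmax(profile))
    half = profile[i_pk] / 2.0
    i = i_pk
    while i + 1 < len(profile) and profile[i] > half:
        i += 1
    frac = (profile[i - 1] - half) / max(profile[i - 1] - profile[i], 1e-30)
    r_half = radii[i - 1] + frac * (radii[1] - radii[0])
    return float(2.0 * r_half)


def write_fsc_curve(path, curve: FSCCurve, thresholds=(0.5, 0.143)) -> None:
    """Two-column TSV (frequency 1/Å, correlation) plus a JSON sidecar with
    threshold crossings and the mask kind."""
    path = Path(path)
    np.savetxt(path, np.column_stack([curve.freq, curve.corr]),
               fmt="%.6f\t%.6f", header="freq_invA\tfsc", comments="")
    side = {"mask_kind": curve.mask_kind, "crossings": {}}
    for thr in thresholds:
        res = resolution_at(curve, thr)
        side["crossings"][str(thr)] = {
            "resolution_A": res.resolution, "frequency_invA": res.frequency,
            "crossed": res.crossed,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))
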