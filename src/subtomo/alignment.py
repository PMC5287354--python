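"""Missing-wedge-aware sub-volume alignment, averaging and refinement.

The aligner performs an exhaustive grid search over the three ZYZ Euler
angles around a starting pose. For each candidate rotation the reference is
resampled (trilinear), and the translation is read off the peak of the
normalised cross-correlation computed over Fourier components *outside the
missing wedge* — the constrained cross-correlation of tomographic practice.
Because a translation only changes Fourier phases, the normalisation is
translation-invariant and a single inverse FFT yields the whole correlation
map; the peak is then refined to sub-voxel precision by parabolic
interpolation.

Averaging inverse-transforms every sub-volume into the reference frame and
accumulates in Fourier space with per-voxel wedge-occupancy weighting (the
sum of rotated wedge masks), so datasets whose particles sample many
orientations fill each other's missing wedges instead of averaging bias in.

Gold-standard bookkeeping: iterative refinement keeps the A and B half-sets
strictly separate — each half aligns only against the average built from
its own particles — and records which particle ids contributed to every
reference it built.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import ParameterError, ShapeError, ValidationError
from .geometry import box_centre, euler_to_matrix, invert_pose, matrix_to_euler, transform_map
from .maps import DensityMap
from .particles import ParticleSet

logger = logging.getLogger(__name__)

__all__ = [
    "Pose",
    "WedgeMask",
    "fourier_wedge_mask",
    "soft_sphere_mask",
    "extract_subvolumes",
    "align_subvolume",
    "average_aligned",
    "refine_iteratively",
    "RefineResult",
    "rescale_poses",
    "centres_to_voxels",
    "align_reference_to_particle",
]


@dataclasses.dataclass
class Pose:
    """A rigid placement of the reference into a particle: rotate by the
    ZYZ Euler angles (degrees), then translate by the shift (Å)."""

    euler: np.ndarray
    shift: np.ndarray
    ccc: float = np.nan
    at_bound: bool = False

    def __post_init__(self):
        self.euler = np.asarray(self.euler, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if np.isfinite(self.ccc) and not -1.0 - 1e-6 <= self.ccc <= 1.0 + 1e-6:
            raise ValidationError(f"ccc {self.ccc} outside [-1, 1]")

    @property
    def rotation(self) -> np.ndarray:
        return euler_to_matrix(self.euler)


@dataclasses.dataclass
class WedgeMask:
    """Angular description of the measured tilt range."""

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_axis_angle: float = 0.0

    def __post_init__(self):
        if not self.tilt_min < self.tilt_max:
            raise ParameterError("tilt_min must be < tilt_max")


def fourier_wedge_mask(shape, wedge: WedgeMask, rotation: np.ndarray | None = None,
                       rfft: bool = True, exclude_dc: bool = False) -> np.ndarray:
    """Boolean mask of Fourier components observed through the tilt range.

    A spatial frequency k is measured if some tilt's projection plane
    contains it, i.e. if the tilt angle solving ``k · beam(t) = 0`` lies in
    ``[tilt_min, tilt_max]``. ``rotation`` maps the mask into the frame of
    a particle rotated by that matrix (mask(k) = wedge(R k)).
    """
    nx, ny, nz = shape
    kx = np.fft.fftfreq(nx)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kz = (np.fft.rfftfreq(nz) if rfft else np.fft.fftfreq(nz))[None, None, :]
    if rotation is not None:
        r = np.asarray(rotation, dtype=float)
        tx = r[0, 0] * kx + r[0, 1] * ky + r[0, 2] * kz
        ty = r[1, 0] * kx + r[1, 1] * ky + r[1, 2] * kz
        tz = r[2, 0] * kx + r[2, 1] * ky + r[2, 2] * kz
    else:
        tx, ty, tz = kx, ky, kz
    g = np.radians(wedge.tilt_axis_angle)
    in_plane = tx * np.cos(g) + ty * np.sin(g)
    t = np.degrees(np.arctan2(-tz, in_plane))
    t = (t + 90.0) % 180.0 - 90.0
    mask = (t >= wedge.tilt_min) & (t <= wedge.tilt_max)
    mask = np.broadcast_to(mask, np.broadcast_shapes(tx.shape, ty.shape, tz.shape)).copy()
    if exclude_dc:
        mask[0, 0, 0] = False
    else:
        mask[0, 0, 0] = True
    return mask


def _hermitian_weights(shape) -> np.ndarray:
    """Multiplicity of each rfft bin in the full Fourier grid."""
    nz = shape[2]
    nzr = nz // 2 + 1
    w = np.full(nzr, 2.0)
    w[0] = 1.0
    if nz % 2 == 0:
        w[-1] = 1.0
    return w[None, None, :]


def soft_sphere_mask(shape, radius_frac: float = 0.42, soft_frac: float = 0.08) -> np.ndarray:
    """Cosine-edged spherical mask used to suppress box-edge wrap-around
    during correlation. Radii are fractions of the box size."""
    shape = tuple(int(n) for n in shape)
    c = box_centre(shape)
    n = min(shape)
    ax = [np.arange(shape[i]) - c[i] for i in range(3)]
    r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2)
    r0, w = radius_frac * n, max(soft_frac * n, 1e-6)
    out = np.clip((r0 + w - r) / w, 0.0, 1.0)
    return (0.5 - 0.5 * np.cos(np.pi * out)).astype(np.float32)


def extract_subvolumes(tomogram: DensityMap, particles: ParticleSet, box: int):
    """Cut one ``box``³ sub-volume per particle, centred on its centre with
    trilinear sampling; out-of-bounds voxels take the tomogram mean.

    Returns ``(stack, kept)`` where ``kept`` flags particles whose centre
    lay within half a box of the volume (others are skipped with a
    warning).
    """
    from scipy import ndimage

    box = int(box)
    if box % 2:
        raise ParameterError("box size must be even")
    data = tomogram.data.astype(np.float32)
    fill = float(data.mean())
    dims = np.asarray(data.shape)
    centre_local = box_centre((box, box, box))
    grid = np.stack(np.meshgrid(*[np.arange(box)] * 3, indexing="ij")).reshape(3, -1)
    kept = np.zeros(len(particles), dtype=bool)
    stack = []
    centres_vox = (particles.centres - tomogram.origin) / tomogram.voxel_size
    for i, c in enumerate(centres_vox):
        if np.any(c < -box / 2) or np.any(c > dims - 1 + box / 2):
            logger.warning("particle %s centre %s outside tomogram; skipped",
                           particles.df['id'].iat[i], np.round(c, 1))
            continue
        coords = grid + (c - centre_local)[:, None]
        sub = ndimage.map_coordinates(data, coords, order=1, cval=fill,
                                      mode="constant").reshape(box, box, box)
        stack.append(sub)
        kept[i] = True
    stack = np.stack(stack) if stack else np.empty((0, box, box, box), dtype=np.float32)
    return stack, kept


def _angle_grid(ang_range, ang_step):
    """Per-axis delta grids; scalars apply to all three Euler angles."""
    ranges = np.broadcast_to(np.asarray(ang_range, dtype=float), (3,))
    steps = np.broadcast_to(np.asarray(ang_step, dtype=float), (3,))
    axes = []
    for r, s in zip(ranges, steps):
        if r <= 0:
            axes.append(np.array([0.0]))
        else:
            if s <= 0:
                raise ParameterError("ang_step must be > 0 when ang_range > 0")
            n = int(np.floor(r / s + 1e-9))
            axes.append(np.arange(-n, n + 1) * s)
    return axes


def _parabolic_offset(lo: float, mid: float, hi: float) -> float:
    denom = lo - 2.0 * mid + hi
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))


def _candidate_rotations(start_euler, ang_range, ang_step):
    r_start = euler_to_matrix(start_euler)
    dphi, dtheta, dpsi = _angle_grid(ang_range, ang_step)
    for a in dphi:
        for b in dtheta:
            for c in dpsi:
                r = r_start @ euler_to_matrix((a, b, c))
                yield matrix_to_euler(r)


def align_subvolume(subvol, reference, wedge: WedgeMask, ang_range, ang_step,
                    shift_limit: float, voxel_size: float | None = None,
                    start_euler=(0.0, 0.0, 0.0), real_mask: np.ndarray | None = None,
                    freq_limit: float | None = None, ref_cache: dict | None = None) -> Pose:
    """Constrained cross-correlation alignment of one sub-volume.

    Searches rotations on the grid ``start ∘ (Δphi, Δtheta, Δpsi)`` with the
    given range(s)/step(s) in degrees (scalars or length-3 sequences), and
    translations up to ``shift_limit`` Å from zero (per axis). Returns the
    best pose; ``at_bound`` flags a translation peak at the search boundary.

    ``freq_limit`` (Å) restricts the correlation to spatial frequencies
    coarser than the given resolution, the usual low-pass discipline that
    keeps noise from driving the search. ``ref_cache`` (a plain dict) may
    be shared across calls that use the same reference, wedge, masks and
    frequency limit to reuse rotated-reference transforms.
    """
    sub, vs1 = _as_array(subvol)
    ref, vs2 = _as_array(reference)
    voxel_size = voxel_size or vs1 or vs2
    if voxel_size is None:
        raise ParameterError("voxel_size required when passing bare arrays")
    if sub.shape != ref.shape:
        raise ShapeError(f"sub-volume {sub.shape} and reference {ref.shape} differ")
    shape = sub.shape
    mask3 = fourier_wedge_mask(shape, wedge, rfft=True, exclude_dc=True)
    if freq_limit is not None:
        mask3 &= _radial_freq(shape, voxel_size) <= 1.0 / freq_limit
    weights = _hermitian_weights(shape) * mask3
    sub_p = _prepare_real(sub, real_mask)
    f_sub = np.fft.rfftn(sub_p)
    n_sub = np.sqrt(np.sum(weights * np.abs(f_sub) ** 2))
    if n_sub == 0:
        raise ValidationError("sub-volume has no power outside the wedge")
    ref_p = _prepare_real(ref, real_mask)
    n_tot = float(np.prod(shape))
    shift_limit_vox = shift_limit / voxel_size
    best = None
    if ref_cache is None:
        ref_cache = {}
    for euler in _candidate_rotations(start_euler, ang_range, ang_step):
        key = tuple(np.round(euler, 2))
        entry = ref_cache.get(key)
        if entry is None:
            rot_ref = transform_map(ref_p, euler_to_matrix(euler))
            f_ref = np.fft.rfftn(rot_ref)
            n_ref = np.sqrt(np.sum(weights * np.abs(f_ref) ** 2))
            g = (np.conj(f_ref) * mask3 / max(n_ref, 1e-30)).astype(np.complex64)
            entry = ref_cache[key] = g
        cross = np.fft.irfftn(f_sub * entry, s=shape, axes=(0, 1, 2)) * (n_tot / n_sub)
        peak = _masked_peak(cross, shift_limit_vox)
        if peak is None:
            continue
        score, shift_vox, at_bound = peak
        if best is None or score > best[0]:
            best = (score, np.asarray(euler, dtype=float), shift_vox, at_bound)
    if best is None:
        raise ParameterError("no translation satisfies the shift limit")
    score, euler, shift_vox, at_bound = best
    return Pose(euler, shift_vox * voxel_size, float(np.clip(score, -1.0, 1.0)), at_bound)


def _radial_freq(shape, voxel_size: float) -> np.ndarray:
    kx = np.fft.fftfreq(shape[0], d=voxel_size)[:, None, None]
    ky = np.fft.fftfreq(shape[1], d=voxel_size)[None, :, None]
    kz = np.fft.rfftfreq(shape[2], d=voxel_size)[None, None, :]
    return np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)


def _as_array(vol):
    if isinstance(vol, DensityMap):
        return vol.data.astype(np.float32), vol.voxel_size
    return np.asarray(vol, dtype=np.float32), None


def _prepare_real(vol: np.ndarray, real_mask: np.ndarray | None) -> np.ndarray:
    out = vol - vol.mean()
    if real_mask is not None:
        out = out * real_mask
    return out


def _masked_peak(cross: np.ndarray, limit_vox: float):
    """Peak of a circular correlation map within ``limit_vox`` of zero
    shift, with per-axis parabolic sub-voxel refinement."""
    shape = cross.shape
    half = [min(int(np.floor(limit_vox)), n // 2 - 1) for n in shape]
    if any(h < 0 for h in half):
        return None
    windows = [np.r_[np.arange(0, h + 1), np.arange(-h, 0) % n] if h > 0 else np.array([0])
               for h, n in zip(half, shape)]
    sub = cross[np.ix_(*windows)]
    idx = np.unravel_index(np.argmax(sub), sub.shape)
    centre_idx = [int(windows[a][idx[a]]) for a in range(3)]
    shift = np.array([i if i <= n // 2 else i - n for i, n in zip(centre_idx, shape)], dtype=float)
    # parabolic refinement using wrapped neighbours on the full map
    refined = shift.copy()
    score = float(cross[tuple(centre_idx)])
    for a in range(3):
        if half[a] == 0:
            continue
        lo_i = list(centre_idx)
        hi_i = list(centre_idx)
        lo_i[a] = (centre_idx[a] - 1) % shape[a]
        hi_i[a] = (centre_idx[a] + 1) % shape[a]
        refined[a] += _parabolic_offset(float(cross[tuple(lo_i)]), score, float(cross[tuple(hi_i)]))
    at_bound = bool(np.any(np.abs(shift) >= np.maximum(np.array(half, dtype=float) - 0.5, 0.0)))
    return score, refined, at_bound


def average_aligned(stack, poses, wedge: WedgeMask, voxel_size: float) -> np.ndarray:
    """Wedge-weighted Fourier-space average of aligned sub-volumes.

    Each sub-volume is inverse-transformed to the reference frame and its
    Fourier components accumulated where its (rotated) wedge mask observes
    them; the accumulator is divided by the per-voxel wedge occupancy.
    """
    stack = np.asarray(stack, dtype=np.float32)
    if len(stack) == 0:
        raise ValidationError("cannot average zero particles")
    if len(stack) != len(poses):
        raise ShapeError("one pose required per sub-volume")
    shape = stack.shape[1:]
    num = np.zeros((shape[0], shape[1], shape[2] // 2 + 1), dtype=np.complex128)
    den = np.zeros(num.shape, dtype=np.float64)
    for vol, pose in zip(stack, poses):
        rot = pose.rotation
        shift_vox = pose.shift / voxel_size
        rinv, tinv = invert_pose(rot, shift_vox)
        aligned = transform_map(vol - vol.mean(), rinv, tinv)
        mask = fourier_wedge_mask(shape, wedge, rotation=rot, rfft=True)
        num += np.fft.rfftn(aligned) * mask
        den += mask
    avg = np.fft.irfftn(np.where(den > 0, num / np.maximum(den, 1e-30), 0.0), s=shape, axes=(0, 1, 2))
    return avg.astype(np.float32)


def wedge_occupancy(poses, wedge: WedgeMask, shape) -> np.ndarray:
    """Per-voxel count of particles observing each Fourier component."""
    den = np.zeros((shape[0], shape[1], shape[2] // 2 + 1), dtype=np.float64)
    for pose in poses:
        den += fourier_wedge_mask(shape, wedge, rotation=pose.rotation, rfft=True)
    return den


@dataclasses.dataclass
class RefineResult:
    particles: ParticleSet
    combined: DensityMap
    half_maps: dict
    history: list
    audit: list


def _poses_from(particles: ParticleSet, rows) -> list:
    eulers = particles.eulers[rows]
    shifts = particles.shifts[rows]
    ccc = particles.ccc[rows]
    return [Pose(e, s, c if np.isfinite(c) else np.nan) for e, s, c in zip(eulers, shifts, ccc)]


def refine_iteratively(tomogram: DensityMap, particles: ParticleSet,
                       reference: DensityMap | None, schedule, wedge: WedgeMask,
                       box: int, real_mask: np.ndarray | str | None = "sphere",
                       freq_limit: float | None = None,
                       reference_symmetry=None) -> RefineResult:
    """Iterative alignment with reference updating, independently per
    half-set.

    ``schedule`` is a sequence of ``(ang_range, ang_step, shift_limit)``
    entries (angles in degrees — scalars or per-axis triples — shift limit
    in Å). Each iteration aligns every particle to its half-set's current
    reference and re-averages; the starting reference (when ``reference``
    is None) is the unaligned average of the picked particles of that half,
    which avoids external reference bias. Refinement stops early if the
    mean ccc drops on two consecutive iterations.

    ``reference_symmetry`` (a :class:`~subtomo.symmetry.SymmetryGroup`)
    symmetrises every reference before it is aligned against — for helical
    specimens this makes all correlation maxima lattice-consistent, which
    is what allows the monomer register to converge. ``freq_limit`` (Å)
    low-pass-limits the correlation.
    """
    if len(schedule) == 0:
        raise ParameterError("schedule must contain at least one iteration")
    stack, kept = extract_subvolumes(tomogram, particles, box)
    particles = particles.select(kept)
    voxel = tomogram.voxel_size
    if isinstance(real_mask, str) and real_mask == "sphere":
        real_mask = soft_sphere_mask((box, box, box))

    def _symmetrise(arr: np.ndarray) -> np.ndarray:
        if reference_symmetry is None:
            return arr
        from .symmetry import symmetrise_map
        return symmetrise_map(DensityMap(arr, voxel), reference_symmetry).data

    halves = sorted(set(particles.half) & {"A", "B"}) or ["combined"]
    groups = {h: np.flatnonzero(particles.half == h) for h in halves}
    refs: dict[str, np.ndarray] = {}
    for h, rows in groups.items():
        if reference is not None:
            refs[h] = _symmetrise(reference.data.astype(np.float32))
        else:
            refs[h] = _symmetrise(
                average_aligned(stack[rows], _poses_from(particles, rows), wedge, voxel))
    history: list[dict] = []
    audit: list[dict] = []
    eulers = particles.eulers.copy()
    shifts = particles.shifts.copy()
    ccc = particles.ccc.copy()
    drops = 0
    for it, (ang_range, ang_step, shift_limit) in enumerate(schedule):
        for h, rows in groups.items():
            audit.append({"iteration": it, "half": h,
                          "reference_particle_ids": particles.df["id"].to_numpy()[rows].tolist()})
            cache: dict = {}
            ref_h = refs[h]
            for i in rows:
                pose = align_subvolume(stack[i], ref_h, wedge, ang_range, ang_step,
                                       shift_limit, voxel_size=voxel,
                                       start_euler=eulers[i], real_mask=real_mask,
                                       freq_limit=freq_limit, ref_cache=cache)
                eulers[i] = pose.euler
                shifts[i] = pose.shift
                ccc[i] = pose.ccc
        particles = particles.with_poses(eulers, shifts, ccc)
        for h, rows in groups.items():
            refs[h] = _symmetrise(
                average_aligned(stack[rows], _poses_from(particles, rows), wedge, voxel))
        mean_ccc = float(np.nanmean(ccc))
        history.append({"iteration": it, "mean_ccc": mean_ccc,
                        "ang_range": ang_range, "ang_step": ang_step,
                        "shift_limit": shift_limit})
        if len(history) >= 2 and mean_ccc < history[-2]["mean_ccc"] - 1e-3:
            drops += 1
            if drops >= 2:
                logger.warning("mean ccc dropped twice in a row; stopping at iteration %d", it)
                break
        else:
            drops = 0
    if set(groups) == {"A", "B"}:
        # Reference-free refinement fixes each half's structure only up to
        # a global rotation about the helix axis and an axial shift (a
        # gauge). Register half B onto half A before accumulating the
        # combined map; the halves themselves were never mixed during
        # refinement.
        gauge = _register_half_gauge(refs["B"], refs["A"], voxel, freq_limit)
        g_rot = gauge.rotation
        g_shift_vox = gauge.shift / voxel
        rows_b = groups["B"]
        for i in rows_b:
            r_i = euler_to_matrix(eulers[i])
            shifts[i] = shifts[i] + (r_i @ g_shift_vox) * voxel
            eulers[i] = matrix_to_euler(r_i @ g_rot)
        particles = particles.with_poses(eulers, shifts, ccc)
        audit.append({"iteration": "gauge", "half": "B",
                      "gauge_euler": gauge.euler.tolist(),
                      "gauge_shift_A": gauge.shift.tolist()})
    combined = average_aligned(stack, _poses_from(particles, np.arange(len(particles))),
                               wedge, voxel)
    half_maps = {h: DensityMap(refs[h], voxel) for h in halves}
    return RefineResult(particles, DensityMap(combined, voxel), half_maps, history, audit)


def _register_half_gauge(ref_b: np.ndarray, ref_a: np.ndarray, voxel: float,
                         freq_limit: float | None) -> Pose:
    """Screw-axis registration of one half reference onto the other:
    ``ref_b ≈ place(ref_a, gauge)``. Searched over spin about z and a
    translation, which are the degeneracies of reference-free helical
    refinement."""
    no_wedge = WedgeMask(-90.0, 89.999)
    return align_subvolume(ref_b, ref_a, no_wedge, (0.0, 0.0, 14.0), (1.0, 1.0, 1.0),
                           shift_limit=28.0, voxel_size=voxel, freq_limit=freq_limit,
                           real_mask=soft_sphere_mask(ref_b.shape))


_VALID_BINS = (1, 2, 4)


def rescale_poses(particles: ParticleSet, bin_from: int, bin_to: int) -> ParticleSet:
    """Hand poses from one binning level to another.

    Centres and shifts are stored in Å in the unbinned frame, so they are
    invariant under rebinning; only their voxel-unit representation changes
    (by ``bin_from / bin_to``, see :func:`centres_to_voxels`). Euler angles
    are unchanged. Validates the binning levels and returns a copy.
    """
    if bin_from not in _VALID_BINS or bin_to not in _VALID_BINS:
        raise ParameterError(f"binning levels must be in {_VALID_BINS}")
    return particles.copy()


def centres_to_voxels(particles: ParticleSet, unbinned_voxel_size: float, binning: int) -> np.ndarray:
    """Particle centres in voxel units of a binned tomogram."""
    if binning not in _VALID_BINS:
        raise ParameterError(f"binning levels must be in {_VALID_BINS}")
    return particles.centres / (unbinned_voxel_size * binning)


def _theta_grid(step: float) -> np.ndarray:
    n = max(int(round(180.0 / step)), 1)
    return np.linspace(0.0, 180.0, n + 1)


def global_orientation_grid(step: float):
    """Quasi-exhaustive ZYZ grid over SO(3), de-duplicated at the poles."""
    out = []
    phis = np.arange(0.0, 360.0, step)
    psis = np.arange(0.0, 360.0, step)
    for theta in _theta_grid(step):
        if theta < 1e-9 or theta > 180 - 1e-9:
            for psi in psis:
                out.append((0.0, theta, psi))
        else:
            for phi in phis:
                for psi in psis:
                    out.append((phi, theta, psi))
    return out


def align_reference_to_particle(subvol: DensityMap, reference: DensityMap, lowpass: float,
                                wedge: WedgeMask, coarse_step: float = 24.0,
                                refine_schedule=((15.0, 5.0), (4.0, 1.5)),
                                shift_limit: float | None = None,
                                real_mask: np.ndarray | str | None = "sphere") -> list:
    """Global orientation search of a known reference onto one particle.

    The reference and particle are low-pass filtered to ``lowpass`` Å, a
    coarse grid over the whole rotation group is scored by constrained
    cross-correlation, and the best orientations are refined locally with
    shrinking angular ranges. Returns the best poses sorted by ccc; two
    poses are returned when the runner-up peak scores within 1% of the
    best, otherwise one.
    """
    from .validation import lowpass_map

    if abs(subvol.voxel_size - reference.voxel_size) > 1e-6 * subvol.voxel_size:
        raise ParameterError("resample the reference to the particle voxel size first")
    sub_f = lowpass_map(subvol, lowpass)
    ref_f = lowpass_map(reference, lowpass)
    voxel = subvol.voxel_size
    if shift_limit is None:
        shift_limit = subvol.shape[0] * voxel / 8.0
    if isinstance(real_mask, str) and real_mask == "sphere":
        real_mask = soft_sphere_mask(subvol.shape)
    cache: dict = {}
    scored = []
    for euler in global_orientation_grid(coarse_step):
        pose = align_subvolume(sub_f, ref_f, wedge, 0.0, 1.0, shift_limit,
                               voxel_size=voxel, start_euler=euler,
                               real_mask=real_mask, ref_cache=cache)
        scored.append(pose)
    scored.sort(key=lambda p: p.ccc, reverse=True)
    # refine a handful of distinct coarse candidates
    seeds = _distinct_poses(scored, min_angle=1.5 * coarse_step, max_n=4)
    finals = []
    for seed in seeds:
        pose = seed
        for rng, step in refine_schedule:
            pose = align_subvolume(sub_f, ref_f, wedge, rng, step, shift_limit,
                                   voxel_size=voxel, start_euler=pose.euler,
                                   real_mask=real_mask, ref_cache={})
        finals.append(pose)
    finals.sort(key=lambda p: p.ccc, reverse=True)
    finals = _distinct_poses(finals, min_angle=5.0, max_n=len(finals))
    if len(finals) > 1 and finals[1].ccc >= 0.99 * finals[0].ccc:
        return finals[:2]
    return finals[:1]


def _distinct_poses(poses, min_angle: float, max_n: int):
    from .geometry import geodesic_angle

    out = []
    for p in poses:
        if all(geodesic_angle(p.rotation, q.rotation) >= min_angle for q in out):
            out.append(p)
        if len(out) >= max_n:
            break
    return out
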