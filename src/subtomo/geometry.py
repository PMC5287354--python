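"""Rotations, Euler-angle conventions and real-space map transforms.

Conventions used throughout the package
---------------------------------------
* Euler angles are intrinsic ZYZ, in degrees, written ``(phi, theta, psi)``.
  The rotation matrix is ``R = Rz(phi) @ Ry(theta) @ Rz(psi)`` and acts on
  column vectors; ``R @ [0, 0, 1]`` is the direction the particle z-axis is
  mapped to.
* Volumes are numpy arrays indexed ``data[ix, iy, iz]`` so that the index
  vector of a voxel is its Cartesian coordinate in voxel units.
* A *pose* places a reference into a particle frame: rotate by ``R`` about
  the box centre, then translate by the shift (rotation before translation).
* All rotations are applied about the geometric box centre ``(n - 1) / 2``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "direction_to_euler",
    "geodesic_angle",
    "transform_map",
    "invert_pose",
    "box_centre",
]


def euler_to_matrix(euler_deg) -> np.ndarray:
    """3x3 rotation matrix from intrinsic ZYZ Euler angles in degrees."""
    return Rotation.from_euler("ZYZ", np.asarray(euler_deg, dtype=float), degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> np.ndarray:
    """Intrinsic ZYZ Euler angles (degrees) of a rotation matrix.

    At the gimbal-locked poles (theta = 0 or 180) the split between phi and
    psi is degenerate; psi is set to zero there.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        return Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)


def direction_to_euler(direction) -> np.ndarray:
    """Euler angles mapping the unit z-vector onto ``direction``.

    The in-plane spin (psi) is left at zero; it is degenerate for this
    mapping and is refined later by alignment.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    d = d / n
    theta = np.degrees(np.arccos(np.clip(d[2], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(d[1], d[0])) if theta > 1e-12 else 0.0
    return np.array([phi, theta, 0.0])


def geodesic_angle(r1: np.ndarray, r2: np.ndarray) -> float:
    """Angle (degrees) of the relative rotation between two matrices."""
    return float(np.degrees((Rotation.from_matrix(r1) * Rotation.from_matrix(r2).inv()).magnitude()))


def box_centre(shape) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0


def transform_map(
    data: np.ndarray,
    rotation: np.ndarray,
    shift_vox=(0.0, 0.0, 0.0),
    order: int = 1,
    cval: float = 0.0,
    output_shape=None,
    centre_in=None,
    centre_out=None,
) -> np.ndarray:
    """Rigid transform of a volume: rotate about the box centre, then shift.

    Returns ``out`` with ``out(x) = data(R^-1 (x - c_out - t) + c_in)`` —
    i.e. the density is rotated by ``rotation`` and translated by
    ``shift_vox`` (voxels). Trilinear interpolation by default.
    """
    data = np.asarray(data)
    rotation = np.asarray(rotation, dtype=float)
    shift_vox = np.asarray(shift_vox, dtype=float)
    if output_shape is None:
        output_shape = data.shape
    c_in = box_centre(data.shape) if centre_in is None else np.asarray(centre_in, float)
    c_out = box_centre(output_shape) if centre_out is None else np.asarray(centre_out, float)
    rinv = rotation.T
    offset = c_in - rinv @ (c_out + shift_vox)
    return ndimage.affine_transform(
        data, rinv, offset=offset, output_shape=tuple(output_shape), order=order,
        mode="constant", cval=cval, prefilter=(order > 1),
    )


def invert_pose(rotation: np.ndarray, shift):
    """Inverse of the rigid map ``x -> R x + t`` as ``(R', t')``."""
    rotation = np.asarray(rotation, dtype=float)
    shift = np.asarray(shift, dtype=float)
    return rotation.T, -rotation.T @ shift
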