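"""Point-group and helical symmetry operators and map symmetrisation.

Helical operators follow the n-start lattice description: operator ``k`` of
an ``n``-fold helical family rotates by ``360 k / n`` degrees about the
z-axis with an axial rise of ``k * (start * spacing / n)`` Å, so for the
13-protofilament, 40 Å repeat, 3-start microtubule lattice operator 1
rotates by 27.69° and rises by 120/13 ≈ 9.23 Å.

The icosahedral group is the 60-element proper rotation group I (532) in
the convention with 2-fold axes along the coordinate axes; it is generated
here by closure from a 5-fold about an icosahedron vertex and the 2-fold
about z.

Symmetrisation averages the map over all operators in real space with
trilinear interpolation, rotations taken about the box centre. The helix
seam of real microtubules is deliberately ignored: symmetrisation is exact
n-fold.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .geometry import transform_map
from .maps import DensityMap
from .phantoms import icosahedron_vertices

__all__ = [
    "SymmetryGroup",
    "cyclic_operators",
    "helical_operators",
    "icosahedral_operators",
    "symmetrise_map",
    "symmetrise_single_particle",
    "parse_group",
]


@dataclasses.dataclass
class SymmetryGroup:
    """A list of (rotation matrix, axial rise Å) operator pairs."""

    rotations: np.ndarray  # (n, 3, 3)
    rises: np.ndarray  # (n,)
    kind: str

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.rises = np.asarray(self.rises, dtype=float)
        if self.kind not in ("cyclic", "helical", "icosahedral"):
            raise ParameterError(f"unknown symmetry kind {self.kind!r}")
        if self.kind in ("cyclic", "icosahedral") and np.any(self.rises != 0):
            raise ParameterError(f"{self.kind} operators must have zero rise")
        if self.kind == "icosahedral" and len(self.rotations) != 60:
            raise ParameterError("icosahedral group must have 60 operators")
        if not any(np.allclose(r, np.eye(3)) and abs(z) < 1e-9
                   for r, z in zip(self.rotations, self.rises)):
            raise ParameterError("symmetry group must contain the identity")

    def __len__(self) -> int:
        return len(self.rotations)


def cyclic_operators(n: int) -> SymmetryGroup:
    """The n rotations of the cyclic group C_n about z."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rots = Rotation.from_euler("z", (360.0 * np.arange(n) / n)[:, None], degrees=True).as_matrix()
    return SymmetryGroup(rots.reshape(n, 3, 3), np.zeros(n), "cyclic")


def helical_operators(n: int, monomer_spacing: float, start: int) -> SymmetryGroup:
    """Screw operators of an n-fold, ``start``-start helical lattice."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rots = Rotation.from_euler("z", (360.0 * np.arange(n) / n)[:, None], degrees=True).as_matrix()
    rises = np.arange(n) * (start * monomer_spacing / n)
    kind = "helical" if n > 1 else "cyclic"
    if n == 1:
        return SymmetryGroup(rots.reshape(1, 3, 3), np.zeros(1), "cyclic")
    return SymmetryGroup(rots.reshape(n, 3, 3), rises, kind)


def _closure(generators) -> np.ndarray:
    """Finite group closure over rotation matrices (quaternion dedup)."""
    def key(r):
        q = np.round(Rotation.from_matrix(r).as_quat(), 6)
        nz = np.nonzero(q)[0]
        if q[nz[-1]] < 0:
            q = -q
        return tuple(q + 0.0)

    elements = {key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    while frontier:
        new = []
        for a in frontier:
            for g in generators:
                b = g @ a
                k = key(b)
                if k not in elements:
                    elements[k] = b
                    new.append(b)
        frontier = new
        if len(elements) > 1000:
            raise ParameterError("generators do not close into a small group")
    return np.stack(list(elements.values()))


_ICOS_CACHE: np.ndarray | None = None


def icosahedral_operators() -> SymmetryGroup:
    """The 60 proper rotations of the icosahedral group (532 convention,
    2-fold axes on the coordinate axes)."""
    global _ICOS_CACHE
    if _ICOS_CACHE is None:
        vertex = icosahedron_vertices()[np.argmax(icosahedron_vertices()[:, 2])]
        r5 = Rotation.from_rotvec(vertex * math.radians(72.0)).as_matrix()
        r2 = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        _ICOS_CACHE = _closure([r5, r2])
    rots = _ICOS_CACHE
    return SymmetryGroup(rots, np.zeros(len(rots)), "icosahedral")


def symmetrise_map(density: DensityMap, group: SymmetryGroup) -> DensityMap:
    """Real-space average of the map over every operator.

    The symmetry axis is assumed to lie along the map z-axis (the caller
    orients the map; poses from alignment are applied first via
    :func:`symmetrise_single_particle`).
    """
    acc = np.zeros(density.shape, dtype=np.float64)
    for rot, rise in zip(group.rotations, group.rises):
        shift = np.array([0.0, 0.0, rise / density.voxel_size])
        acc += transform_map(density.data.astype(np.float32), rot, shift)
    return density.with_data((acc / len(group)).astype(np.float32))


def symmetrise_single_particle(subvol: DensityMap, pose, group: SymmetryGroup) -> DensityMap:
    """Transform a sub-volume into the reference frame by the inverse of
    its pose, then symmetrise. With an unrefined (wrong) pose the output
    carries no coherent structure."""
    from .geometry import euler_to_matrix, invert_pose

    rot = euler_to_matrix(pose.euler if hasattr(pose, "euler") else pose)
    shift_vox = (np.asarray(pose.shift) / subvol.voxel_size) if hasattr(pose, "shift") else np.zeros(3)
    rinv, tinv = invert_pose(rot, shift_vox)
    aligned = subvol.with_data(transform_map(subvol.data.astype(np.float32), rinv, tinv))
    return symmetrise_map(aligned, group)


def parse_group(text: str):
    """Parse a CLI group descriptor: ``c<n>``, ``helical:<n>,<spacing>,<start>``
    or ``icos``."""
    text = text.strip().lower()
    if text == "icos":
        return icosahedral_operators()
    if text.startswith("c") and text[1:].isdigit():
        return cyclic_operators(int(text[1:]))
    if text.startswith("helical:"):
        n, spacing, start = text[len("helical:"):].split(",")
        return helical_operators(int(n), float(spacing), int(start))
    raise ParameterError(f"cannot parse symmetry descriptor {text!r}")
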