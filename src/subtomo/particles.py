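"""Particle tables: centres, poses, scores and half-set labels.

The on-disk format is a tab-separated table with a header row and the
columns ``id, x, y, z, phi, theta, psi, sx, sy, sz, ccc, half``:

* ``x, y, z`` — particle centre in Å in the unbinned tomogram frame,
* ``phi, theta, psi`` — intrinsic ZYZ Euler angles in degrees,
* ``sx, sy, sz`` — residual translation in Å applied after rotation,
* ``ccc`` — constrained cross-correlation score in [-1, 1] (NaN before
  any alignment has been run),
* ``half`` — gold-standard half-set label, one of ``A``, ``B``,
  ``combined``.

Unknown extra columns are carried through reading and writing untouched.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = ["ParticleSet", "read_particles", "write_particles", "REQUIRED_COLUMNS", "HALF_LABELS"]

REQUIRED_COLUMNS = ["id", "x", "y", "z", "phi", "theta", "psi", "sx", "sy", "sz", "ccc", "half"]
HALF_LABELS = ("A", "B", "combined")


@dataclasses.dataclass
class ParticleSet:
    """A validated table of particle records (thin pandas wrapper)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"particle table is missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("particle ids must be unique")
        ccc = self.df["ccc"].to_numpy(dtype=float)
        finite = ccc[np.isfinite(ccc)]
        if finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ValidationError("ccc values must lie in [-1, 1]")
        bad = set(self.df["half"].astype(str)) - set(HALF_LABELS)
        if bad:
            raise ValidationError(f"unknown half-set labels: {sorted(bad)}")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_arrays(cls, centres, eulers=None, shifts=None, ccc=None, half="combined", ids=None):
        centres = np.atleast_2d(np.asarray(centres, dtype=float))
        n = len(centres)
        eulers = np.zeros((n, 3)) if eulers is None else np.atleast_2d(np.asarray(eulers, float))
        shifts = np.zeros((n, 3)) if shifts is None else np.atleast_2d(np.asarray(shifts, float))
        ccc = np.full(n, np.nan) if ccc is None else np.asarray(ccc, dtype=float)
        ids = np.arange(n) if ids is None else np.asarray(ids)
        half_col = [half] * n if isinstance(half, str) else list(half)
        return cls(pd.DataFrame({
            "id": ids,
            "x": centres[:, 0], "y": centres[:, 1], "z": centres[:, 2],
            "phi": eulers[:, 0], "theta": eulers[:, 1], "psi": eulers[:, 2],
            "sx": shifts[:, 0], "sy": shifts[:, 1], "sz": shifts[:, 2],
            "ccc": ccc, "half": half_col,
        }))

    @classmethod
    def empty(cls) -> "ParticleSet":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in REQUIRED_COLUMNS}))

    # -- array views -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def centres(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def eulers(self) -> np.ndarray:
        return self.df[["phi", "theta", "psi"]].to_numpy(dtype=float)

    @property
    def shifts(self) -> np.ndarray:
        return self.df[["sx", "sy", "sz"]].to_numpy(dtype=float)

    @property
    def ccc(self) -> np.ndarray:
        return self.df["ccc"].to_numpy(dtype=float)

    @property
    def half(self) -> np.ndarray:
        return self.df["half"].to_numpy(dtype=object)

    def copy(self) -> "ParticleSet":
        return ParticleSet(self.df.copy())

    def select(self, mask) -> "ParticleSet":
        return ParticleSet(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def with_poses(self, eulers=None, shifts=None, ccc=None) -> "ParticleSet":
        df = self.df.copy()
        if eulers is not None:
            df[["phi", "theta", "psi"]] = np.asarray(eulers, dtype=float)
        if shifts is not None:
            df[["sx", "sy", "sz"]] = np.asarray(shifts, dtype=float)
        if ccc is not None:
            df["ccc"] = np.asarray(ccc, dtype=float)
        return ParticleSet(df)


def write_particles(path, particles: ParticleSet) -> None:
    particles.df.to_csv(path, sep="\t", index=False)


def read_particles(path) -> ParticleSet:
    path = Path(path)
    text = path.read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", float_precision="round_trip")
    if len(df) and "half" in df.columns:
        df["half"] = df["half"].astype(str)
    return ParticleSet(df)
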