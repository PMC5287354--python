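"""Oriented particle sampling along filament traces and particle bookkeeping.

Implements the particle housekeeping of a filament sub-tomogram averaging
run: even sampling at a fixed arc-length interval along user-supplied
traces with each particle's z-axis oriented along the local filament
direction, greedy duplicate exclusion by cross-correlation score,
CCC thresholding, and random gold-standard half-set splitting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError, ValidationError
from .geometry import direction_to_euler
from .particles import ParticleSet

__all__ = [
    "FilamentTrace",
    "read_traces",
    "write_traces",
    "sample_filament",
    "sample_filaments",
    "remove_duplicates",
    "filter_by_ccc",
    "split_halves",
]


@dataclasses.dataclass
class FilamentTrace:
    """Ordered polyline (Å) marking a filament axis."""

    points: np.ndarray
    id: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 1:
            raise ValidationError("trace needs at least one point")
        if len(self.points) > 1:
            seg = np.diff(self.points, axis=0)
            if np.any(np.linalg.norm(seg, axis=1) == 0):
                raise ValidationError("consecutive trace points must be distinct")

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def read_traces(path) -> list[FilamentTrace]:
    """Read traces from a TSV with columns trace_id, x, y, z (Å)."""
    df = pd.read_csv(Path(path), sep="\t")
    required = {"trace_id", "x", "y", "z"}
    if not required <= set(df.columns):
        raise SchemaError(f"trace table needs columns {sorted(required)}")
    traces = []
    for tid, group in df.groupby("trace_id", sort=True):
        traces.append(FilamentTrace(group[["x", "y", "z"]].to_numpy(dtype=float), id=int(tid)))
    return traces


def write_traces(path, traces) -> None:
    rows = []
    for tr in traces:
        for p in tr.points:
            rows.append((tr.id, *p))
    pd.DataFrame(rows, columns=["trace_id", "x", "y", "z"]).to_csv(path, sep="\t", index=False)


def sample_filament(trace: FilamentTrace, interval: float, id_offset: int = 0) -> ParticleSet:
    """Particles at arc-length positions 0, interval, 2*interval, ... along
    the trace, each oriented with its z-axis parallel to the local segment
    direction and in-plane spin initialised to zero."""
    if not interval > 0:
        raise ParameterError("sampling interval must be > 0")
    pts = trace.points
    if len(pts) == 1:
        return ParticleSet.from_arrays(pts[:1], ids=[id_offset])
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = int(np.floor(total / interval + 1e-9)) + 1
    centres, eulers = [], []
    for k in range(n):
        s = min(k * interval, total)
        j = int(np.searchsorted(cum[1:], s, side="left"))
        j = min(j, len(seg) - 1)
        frac = (s - cum[j]) / seg_len[j]
        centres.append(pts[j] + frac * seg[j])
        eulers.append(direction_to_euler(seg[j]))
    return ParticleSet.from_arrays(np.asarray(centres), np.asarray(eulers),
                                   ids=np.arange(n) + id_offset)


def sample_filaments(traces, interval: float) -> ParticleSet:
    """Sample every trace, carrying a ``trace_id`` column for provenance."""
    frames = []
    offset = 0
    for tr in traces:
        ps = sample_filament(tr, interval, id_offset=offset)
        df = ps.df.copy()
        df["trace_id"] = tr.id
        frames.append(df)
        offset += len(ps)
    if not frames:
        return ParticleSet.empty()
    return ParticleSet(pd.concat(frames, ignore_index=True))


def remove_duplicates(particles: ParticleSet, min_dist: float) -> ParticleSet:
    """Greedy duplicate exclusion in descending ccc order.

    A particle is kept iff no already-kept particle lies within
    ``min_dist`` of its (shift-corrected) centre; among equal scores the
    lower id wins. The output preserves input row order.
    """
    ccc = particles.ccc
    if len(particles) and not np.all(np.isfinite(ccc)):
        raise ValidationError("all particles need a ccc score for duplicate removal")
    pos = particles.centres + particles.shifts
    ids = particles.df["id"].to_numpy()
    order = np.lexsort((ids, -ccc))
    keep = np.zeros(len(particles), dtype=bool)
    kept_pos: list[np.ndarray] = []
    for i in order:
        p = pos[i]
        if all(np.linalg.norm(p - q) >= min_dist for q in kept_pos):
            keep[i] = True
            kept_pos.append(p)
    return particles.select(keep)


def filter_by_ccc(particles: ParticleSet, threshold: float, keep_equal: bool = True) -> ParticleSet:
    """Retain particles scoring at or above the threshold.

    ``keep_equal`` controls whether exactly-threshold scores survive
    (the default mirrors excluding only scores strictly below the cut)."""
    ccc = particles.ccc
    keep = ccc >= threshold if keep_equal else ccc > threshold
    return particles.select(keep)


def split_halves(particles: ParticleSet, seed: int) -> ParticleSet:
    """Random gold-standard split: ceil(n/2) particles labelled A, the rest
    B, from a seeded permutation. Labels persist in the table."""
    n = len(particles)
    if n < 2:
        raise ValidationError("need at least 2 particles to split into halves")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    n_a = int(np.ceil(n / 2))
    labels[perm[:n_a]] = "A"
    labels[perm[n_a:]] = "B"
    df = particles.df.copy()
    df["half"] = labels
    return ParticleSet(df)
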