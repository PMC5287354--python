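"""Configuration-driven pipeline runner.

A run is described by a mapping (usually loaded from YAML)::

    seed: 1
    stages:
      - stage: simulate
        snr: 0.3
      - stage: pick
        interval: 40.0
      - stage: split
      - stage: align
        box: 48
      - stage: fsc

Each stage consumes named artefacts produced by earlier stages (tomograms,
tilt series, particle tables, maps) and writes its outputs into the run
directory; a machine-readable JSON-lines log records every stage with its
parameters and the SHA-256 checksum of each output file. Stochastic stages
draw their randomness from the run seed, so a (config, seed) pair
reproduces a run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import alignment, picking, validation, workflows
from .ctf import CTFParams, phase_flip_tilt_series
from .errors import DependencyError, ParameterError
from .maps import read_map, read_tilt_series, write_map, write_tilt_series
from .particles import read_particles, write_particles
from .symmetry import parse_group, symmetrise_map

__all__ = ["run_pipeline", "load_config", "PipelineContext"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParameterError("pipeline config must be a mapping")
    return cfg


@dataclasses.dataclass
class PipelineContext:
    run_dir: Path
    seed: int
    artefacts: dict = dataclasses.field(default_factory=dict)

    def need(self, key: str):
        if key not in self.artefacts:
            raise DependencyError(f"stage requires missing upstream artefact {key!r}")
        return self.artefacts[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(ctx: PipelineContext, params: dict) -> list:
    ctf = params.pop("ctf", None)
    data = workflows.simulate_microtubule_dataset(
        seed=ctx.seed, ctf=CTFParams(**ctf) if ctf else None, **params)
    ctx.artefacts.update(tomogram=data.tomogram, scene=data.scene, traces=data.traces,
                         truth=data.truth, tilt_series=data.tilt_series, wedge=data.wedge,
                         phantom_params=data.params)
    outs = []
    for name, vol in (("tomogram.mrc", data.tomogram), ("scene.mrc", data.scene)):
        write_map(ctx.run_dir / name, vol)
        outs.append(ctx.run_dir / name)
    write_tilt_series(ctx.run_dir / "tilt_series.mrc", data.tilt_series)
    outs += [ctx.run_dir / "tilt_series.mrc", ctx.run_dir / "tilt_series.tlt"]
    picking.write_traces(ctx.run_dir / "traces.tsv", data.traces)
    write_particles(ctx.run_dir / "truth.tsv", data.truth)
    outs += [ctx.run_dir / "traces.tsv", ctx.run_dir / "truth.tsv"]
    return outs


def _stage_pick(ctx: PipelineContext, params: dict) -> list:
    traces = ctx.need("traces")
    interval = params.get("interval", 40.0)
    picks = picking.sample_filaments(traces, interval)
    ctx.artefacts["particles"] = picks
    out = ctx.run_dir / "picks.tsv"
    write_particles(out, picks)
    return [out]


def _stage_split(ctx: PipelineContext, params: dict) -> list:
    parts = picking.split_halves(ctx.need("particles"), seed=ctx.seed + 1)
    ctx.artefacts["particles"] = parts
    out = ctx.run_dir / "picks_split.tsv"
    write_particles(out, parts)
    return [out]


def _stage_align(ctx: PipelineContext, params: dict) -> list:
    tomogram = ctx.need("tomogram")
    parts = ctx.need("particles")
    wedge = ctx.need("wedge")
    schedule = params.get("schedule", workflows.DEFAULT_SCHEDULE)
    sym = params.get("reference_symmetry")
    result = alignment.refine_iteratively(
        tomogram, parts, None, schedule, wedge, box=params.get("box", 48),
        freq_limit=params.get("freq_limit", workflows.ALIGN_FREQ_LIMIT),
        reference_symmetry=parse_group(sym) if sym else None)
    ctx.artefacts.update(particles=result.particles, combined=result.combined,
                         half_maps=result.half_maps)
    outs = []
    write_particles(ctx.run_dir / "refined.tsv", result.particles)
    outs.append(ctx.run_dir / "refined.tsv")
    write_map(ctx.run_dir / "combined.mrc", result.combined)
    outs.append(ctx.run_dir / "combined.mrc")
    for h, vol in result.half_maps.items():
        write_map(ctx.run_dir / f"half_{h}.mrc", vol)
        outs.append(ctx.run_dir / f"half_{h}.mrc")
    (ctx.run_dir / "refine_history.json").write_text(
        json.dumps({"history": result.history, "audit": result.audit}, indent=2))
    outs.append(ctx.run_dir / "refine_history.json")
    return outs


def _stage_filter(ctx: PipelineContext, params: dict) -> list:
    parts = ctx.need("particles")
    parts = picking.filter_by_ccc(parts, params.get("ccc_threshold", 0.2))
    parts = picking.remove_duplicates(parts, params.get("min_dist", 40.0))
    ctx.artefacts["particles"] = parts
    out = ctx.run_dir / "filtered.tsv"
    write_particles(out, parts)
    return [out]


def _stage_average(ctx: PipelineContext, params: dict) -> list:
    tomogram = ctx.need("tomogram")
    parts = ctx.need("particles")
    wedge = ctx.need("wedge")
    box = params.get("box", 48)
    stack, kept = alignment.extract_subvolumes(tomogram, parts, box)
    parts = parts.select(kept)
    poses = alignment._poses_from(parts, np.arange(len(parts)))
    avg = alignment.average_aligned(stack, poses, wedge, tomogram.voxel_size)
    from .maps import DensityMap
    ctx.artefacts["average"] = DensityMap(avg, tomogram.voxel_size)
    out = ctx.run_dir / "average.mrc"
    write_map(out, ctx.artefacts["average"])
    return [out]


def _stage_symmetrize(ctx: PipelineContext, params: dict) -> list:
    group = parse_group(params.get("group", "helical:13,40,3"))
    source = params.get("input", "average")
    sym = symmetrise_map(ctx.need(source), group)
    ctx.artefacts["symmetrised"] = sym
    out = ctx.run_dir / "symmetrised.mrc"
    write_map(out, sym)
    return [out]


def _stage_fsc(ctx: PipelineContext, params: dict) -> list:
    halves = ctx.need("half_maps")
    if set(halves) != {"A", "B"}:
        raise DependencyError("fsc stage requires both half maps")
    spec = validation.MaskSpec(**params.get("mask", {"kind": "none"}))
    shape = halves["A"].shape
    mask = validation.make_mask(spec, shape, halves["A"].voxel_size,
                                reference=ctx.artefacts.get("combined"))
    curve = validation.compute_fsc(halves["A"], halves["B"], mask, spec.kind)
    ctx.artefacts["fsc"] = curve
    out = ctx.run_dir / "fsc.tsv"
    validation.write_fsc_curve(out, curve)
    return [out, out.with_suffix(".tsv.json")]


def _stage_ctf_flip(ctx: PipelineContext, params: dict) -> list:
    ts = ctx.need("tilt_series")
    flipped = phase_flip_tilt_series(ts, CTFParams(**params.get("ctf", {})),
                                     strips=params.get("strips", False))
    ctx.artefacts["tilt_series"] = flipped
    out = ctx.run_dir / "tilt_series_flipped.mrc"
    write_tilt_series(out, flipped)
    return [out, out.with_suffix(".tlt")]


def _stage_backplot(ctx: PipelineContext, params: dict) -> list:
    avg = ctx.need(params.get("input", "average"))
    parts = ctx.need("particles")
    shape = ctx.need("tomogram").shape
    plot = validation.backplot(shape, avg, parts, mode=params.get("mode", "max"))
    ctx.artefacts["backplot"] = plot
    out = ctx.run_dir / "backplot.mrc"
    write_map(out, plot)
    return [out]


_STAGES = {
    "simulate": _stage_simulate,
    "pick": _stage_pick,
    "split": _stage_split,
    "align": _stage_align,
    "filter": _stage_filter,
    "average": _stage_average,
    "symmetrize": _stage_symmetrize,
    "fsc": _stage_fsc,
    "ctf-flip": _stage_ctf_flip,
    "backplot": _stage_backplot,
}


def run_pipeline(config: dict, run_dir, seed: int | None = None) -> Path:
    """Execute the configured stage sequence; returns the run directory.

    The JSON-lines log ``run_log.jsonl`` records one entry per stage with
    its resolved parameters and output checksums.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    ctx = PipelineContext(run_dir, seed)
    log_path = run_dir / "run_log.jsonl"
    with open(log_path, "w") as log:
        log.write(json.dumps({"event": "start", "seed": seed,
                              "n_stages": len(config.get("stages", []))}) + "\n")
        for entry in config.get("stages", []):
            entry = dict(entry)
            name = entry.pop("stage", None)
            if name not in _STAGES:
                raise ParameterError(f"unknown stage {name!r}")
            t0 = time.time()
            outputs = _STAGES[name](ctx, entry)
            log.write(json.dumps({
                "stage": name, "params": entry,
                "outputs": {str(p.relative_to(run_dir)): _sha256(p) for p in outputs},
                "elapsed_s": round(time.time() - t0, 3),
            }) + "\n")
            log.flush()
    return run_dir


def load_artefacts(ctx: PipelineContext, paths: dict) -> None:
    """Pre-populate a context from files (used by the CLI subcommands)."""
    for key, path in paths.items():
        path = Path(path)
        if key in ("tomogram", "scene", "average", "combined"):
            ctx.artefacts[key] = read_map(path)
        elif key == "particles":
            ctx.artefacts[key] = read_particles(path)
        elif key == "traces":
            ctx.artefacts[key] = picking.read_traces(path)
        elif key == "tilt_series":
            ctx.artefacts[key] = read_tilt_series(path)
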