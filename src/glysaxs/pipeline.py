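"""End-to-end workflow: ensembles → windows → envelope → excess SAXS → verdict.

Mirrors the SAXS-MD analysis loop: obtain folded/unfolded ensembles,
select conformationally pure windows by end-to-end distance, build the
solvation envelope, compute buffer-subtracted ensemble intensities,
analyze the experimental curve (Guinier/Kratky/rod), fit each conformer
model to the experiment, and report which conformation fits.

Every effective parameter is logged and serialized into a run manifest
so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .core import ScatteringCurve, Trajectory
from .conformation import classify_windows, end_to_end_series, rg_series
from .curve_analysis import (agu_count, compare_models, guinier_fit, kratky_peak,
                             read_curve, rod_length_from_rg, write_curve)
from .envelope import build_envelope
from .io import read_trajectory_pdb
from .scattering import excess_intensity
from .synthetic_data import (BULK_WATER_DENSITY, FC_RANGE, UFC_RANGE, SyntheticSpec,
                             generate_hairpin_trajectory, generate_solvent_trajectory,
                             solvate_trajectory, synthesize_experimental_curve)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("glysaxs.pipeline")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Full configuration of one analysis run (all defaults are the study values)."""

    # ensembles: synthetic generation or multi-model PDB inputs
    synthetic: bool = True
    seed: int = 1
    n_frames: int = 1000
    n_residues_per_strand: int = 3
    torsion_jitter: float = 8.0
    frame_interval: float = 1.0  # ps
    box_edge: float = 40.0
    trajectory_paths: dict[str, str] = field(default_factory=dict)  # label -> PDB
    # experiment: a measured curve, or one synthesized from a named model
    experiment_path: str | None = None
    experiment_q_unit: str = "angstrom"
    synthetic_experiment_from: str | None = "folded"
    experiment_relative_sigma: float = 0.05
    # window selection
    fc_range: tuple[float, float] = FC_RANGE
    ufc_range: tuple[float, float] = UFC_RANGE
    min_window_frames: int = 1000
    # envelope & solvation
    envelope_distance: float = 7.0  # Å
    voxel: float = 0.5  # Å
    hydration: bool = True
    water_density: float = BULK_WATER_DENSITY
    contact: float = 1.8  # Å
    n_solvent_frames: int | None = None  # default: same as window length
    # scattering
    q_min: float = 0.01
    q_max: float = 0.5
    q_points: int = 100
    q_spacing: str = "log"
    n_directions: int = 400
    # curve analysis
    guinier_q2_range: tuple[float, float] = (0.008, 0.06)
    rod_radius: float = 3.0
    report_band: tuple[float, float] = (0.16, 0.4)
    # output
    outdir: str = "glysaxs_run"

    def q_grid(self) -> np.ndarray:
        from .scattering import default_q_grid
        return default_q_grid(self.q_min, self.q_max, self.q_points, self.q_spacing)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _subseed(seed: int, tag: int) -> int:
    return int(np.random.default_rng([seed, tag]).integers(2**31))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("ensembles")
def _obtain_ensembles(config: RunConfig) -> dict[str, Trajectory]:
    if config.synthetic:
        out = {}
        for i, state in enumerate(("folded", "unfolded")):
            spec = SyntheticSpec(
                seed=_subseed(config.seed, i), n_frames=config.n_frames,
                state=state, n_residues_per_strand=config.n_residues_per_strand,
                frame_interval=config.frame_interval,
                torsion_jitter=config.torsion_jitter, box_edge=config.box_edge)
            out[state] = generate_hairpin_trajectory(spec)
        return out
    if not config.trajectory_paths:
        raise ValueError("no trajectory_paths given and synthetic=False")
    return {label: read_trajectory_pdb(p, config.frame_interval)
            for label, p in config.trajectory_paths.items()}


@_stage("windows")
def _select_windows(config: RunConfig, ensembles: dict[str, Trajectory]
                    ) -> dict[str, dict[str, Any]]:
    out = {}
    for label, traj in ensembles.items():
        d = end_to_end_series(traj)
        windows = classify_windows(d, config.fc_range, config.ufc_range,
                                   config.min_window_frames, config.frame_interval)
        if not windows:
            raise ValueError(
                f"ensemble '{label}': no window of >= {config.min_window_frames} "
                "frames inside either distance range")
        win = max(windows, key=lambda w: w.n_frames)
        out[label] = {
            "window": win,
            "trajectory": traj[win.start:win.end],
            "distances": d,
            "rg_mean": float(np.mean(rg_series(traj[win.start:win.end]))),
        }
        log.info("ensemble %s: window %s [%d, %d) of %d frames, mean Rg %.2f A",
                 label, win.label, win.start, win.end, win.n_frames,
                 out[label]["rg_mean"])
    return out


@_stage("scattering")
def _compute_models(config: RunConfig, selections: dict[str, dict[str, Any]]
                    ) -> dict[str, ScatteringCurve]:
    q = config.q_grid()
    models = {}
    for i, (label, sel) in enumerate(selections.items()):
        window_traj: Trajectory = sel["trajectory"]
        envelope = build_envelope(window_traj, config.envelope_distance, config.voxel)
        log.info("ensemble %s: envelope volume %.0f A^3 at %.1f A",
                 label, envelope.volume, config.envelope_distance)
        if config.hydration:
            solute_frames = solvate_trajectory(
                window_traj, envelope, config.water_density, config.contact,
                seed=_subseed(config.seed, 100 + i))
            n_solv = config.n_solvent_frames or len(window_traj)
            solvent_frames = generate_solvent_trajectory(
                envelope, n_solv, config.water_density,
                seed=_subseed(config.seed, 200 + i), box_edge=config.box_edge,
                frame_interval=config.frame_interval)
            curve = excess_intensity(solute_frames, solvent_frames, envelope,
                                     q, config.n_directions)
        else:
            curve = excess_intensity(window_traj, None, envelope,
                                     q, config.n_directions)
        curve.metadata["label"] = label
        models[label] = curve
    return models


@_stage("experiment")
def _obtain_experiment(config: RunConfig, models: dict[str, ScatteringCurve]
                       ) -> ScatteringCurve | None:
    if config.experiment_path:
        return read_curve(config.experiment_path, config.experiment_q_unit)
    if config.synthetic_experiment_from:
        src = config.synthetic_experiment_from
        if src not in models:
            raise ValueError(f"synthetic_experiment_from={src!r} is not a model label")
        return synthesize_experimental_curve(
            models[src], noise_seed=_subseed(config.seed, 300),
            relative_sigma=config.experiment_relative_sigma)
    return None


@_stage("curve_analysis")
def _analyze_experiment(config: RunConfig, experiment: ScatteringCurve) -> dict[str, Any]:
    out: dict[str, Any] = {}
    try:
        g = guinier_fit(experiment, config.guinier_q2_range)
        out["guinier"] = {"rg": g.rg, "i0": g.i0, "qmax_rg": g.qmax_rg,
                          "valid": g.valid, "n_points": g.n_points}
        rod = rod_length_from_rg(g.rg, config.rod_radius)
        n_agu = agu_count(rod.length)
        out["rod_model"] = {"radius": rod.radius, "length": rod.length,
                            "length_rounded": rod.length_rounded,
                            "agu_count": n_agu.count, "agu_ratio": n_agu.ratio}
    except ValueError as exc:
        out["guinier_error"] = str(exc)
    out["kratky_peak"] = kratky_peak(experiment)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow and write curves, tables and a manifest.

    Returns the run report (also written to ``<outdir>/report.json``).
    Any stage failure raises :class:`PipelineError` naming the stage;
    partial outputs are retained next to a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        ensembles = _obtain_ensembles(config)
        selections = _select_windows(config, ensembles)
        models = _compute_models(config, selections)
        experiment = _obtain_experiment(config, models)

        report: dict[str, Any] = {
            "windows": {
                label: {"label": sel["window"].label,
                        "start": sel["window"].start, "end": sel["window"].end,
                        "n_frames": sel["window"].n_frames,
                        "duration_ps": sel["window"].duration,
                        "criterion": list(sel["window"].criterion),
                        "rg_mean": sel["rg_mean"]}
                for label, sel in selections.items()},
        }
        for label, curve in models.items():
            write_curve(curve, outdir / f"model_{label}.dat")

        if experiment is not None:
            write_curve(experiment, outdir / "experiment.dat")
            report["experiment_analysis"] = _analyze_experiment(config, experiment)
            verdict, fits = compare_models(models, experiment, config.report_band)
            report["fits"] = {
                label: {"scale": f.scale, "constant": f.constant, "chi2": f.chi2,
                        "chi2_reduced": f.chi2_reduced, "n_points": f.n_points,
                        "band_chi2_reduced": f.band_chi2_reduced}
                for label, f in fits.items()}
            report["verdict"] = verdict
            log.info("verdict: %s (chi2 %s)", verdict,
                     {k: round(v["chi2"], 3) for k, v in report["fits"].items()})
        else:
            report["verdict"] = None
            log.info("model-only mode: no experimental curve, no verdict")

        manifest = {
            "config": config.to_dict(),
            "versions": {"glysaxs": __version__, "numpy": np.__version__},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception:
        (outdir / "FAILED").write_text("run aborted; see logs\n")
        raise
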