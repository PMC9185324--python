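"""Run configuration, orchestration and outputs.

A :class:`SimulationConfig` fully parameterises one brushing run (geometry,
materials, kinematics, engine controls); defaults reproduce the reference
setup: 42-tuft acrylic brush (3 x 14 grid, 8 particles per tuft, two
clamped), enamel two-plate + groove tooth model, one two-stroke scrub cycle
of L = 56 mm.  ``run_brushing`` executes one cycle, ``run_sweep`` the
brushing-speed x brushing-depth study, ``run_validation`` the cantilever
bench.  Everything is deterministic; any result is reproducible
bit-identically from the manifest echoed next to it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import Engine, EngineParams
from .geometry import BrushAssembly, MotionProfile, ToothModel, build_brush, build_teeth
from .materials import ACRYLIC, ENAMEL
from .validation import deflection_error_curve
from .wear import WearMap, WearParams, summarize_wear, wear_map_to_csv

log = logging.getLogger("brushwear")

BRISTLE_RADIUS = 0.9e-3  # r of the tuft beam, m


@dataclass
class SimulationConfig:
    """Full parameterisation of one brushing run (SI units)."""

    # kinematics
    speed: float = 0.10  # V, m/s
    depth: float = BRISTLE_RADIUS  # d_z, m (r by default)
    stroke: float = 56.0e-3  # L, total two-stroke distance, m
    # brush geometry
    n_rows: int = 3
    n_cols: int = 14
    head_length: float = 27.5e-3
    head_width: float = 10.2e-3
    beam_length: float = 10.8e-3
    particle_diameter: float = 1.8e-3
    n_particles: int = 8
    n_clamped: int = 2
    # tooth geometry
    groove_width: float = 2.4e-3
    groove_depth: float = 3.0e-3
    measured_span: float = 28.0e-3
    plate_height: float = 16.0e-3
    apron_length: float = 36.0e-3
    # contact / engine
    restitution: float = 0.3
    friction: float = 0.18
    gamma_bg: float = 10.0
    gravity: bool = False
    torsion: bool = False
    pair_contacts: bool = True
    dt_safety: float = 0.1
    dt: Optional[float] = None
    # wear + outputs
    wear_cell: float = 0.5e-3
    archard_k: float = 1.0
    log_stride: int = 200

    def __post_init__(self) -> None:
        if not (self.speed > 0 and self.stroke > 0):
            raise ValueError("speed and stroke must be > 0")
        if not 0 < self.depth <= self.particle_diameter / 2.0:
            raise ValueError("depth must be in (0, r]")
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be > 0")

    # -- serialisation ---------------------------------------------------------
    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def manifest(self, extra: dict = None) -> dict:
        m = {"package": "brushwear", "version": __version__, "config": self.resolved()}
        if extra:
            m.update(extra)
        m["config_hash"] = hashlib.sha256(
            json.dumps(m["config"], sort_keys=True).encode()
        ).hexdigest()[:16]
        return m

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    # -- builders --------------------------------------------------------------
    def build(self) -> tuple[BrushAssembly, ToothModel, MotionProfile]:
        assembly = build_brush(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            head_length=self.head_length,
            head_width=self.head_width,
            beam_length=self.beam_length,
            particle_diameter=self.particle_diameter,
            n_particles=self.n_particles,
            n_clamped=self.n_clamped,
            material=ACRYLIC,
        )
        teeth = build_teeth(
            groove_width=self.groove_width,
            groove_depth=self.groove_depth,
            measured_span=self.measured_span,
            plate_height=self.plate_height,
            apron_length=self.apron_length,
        )
        motion = MotionProfile(speed=self.speed, depth=self.depth, stroke=self.stroke)
        return assembly, teeth, motion

    def engine_params(self) -> EngineParams:
        return EngineParams(
            restitution=self.restitution,
            friction=self.friction,
            gamma_bg=self.gamma_bg,
            gravity=self.gravity,
            torsion=self.torsion,
            pair_contacts=self.pair_contacts,
            dt_safety=self.dt_safety,
            wear_cell=self.wear_cell,
            archard_k=self.archard_k,
            log_stride=self.log_stride,
        )


@dataclass
class RunResults:
    """Outputs of one brushing run."""

    config: SimulationConfig
    manifest: dict
    wear: WearMap
    summary: dict
    forces: pd.DataFrame  # decimated per-tip force log
    snapshots: pd.DataFrame  # per-tip records at the two groove crossings

    def save(self, outdir, vtk: bool = False) -> None:
        """Write forces/wear/summary/manifest as plain-text files; every
        file's directory carries the manifest (with its config hash)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(self.manifest, sort_keys=True))
        self.forces.to_csv(outdir / "forces.csv", index=False)
        self.snapshots.to_csv(outdir / "snapshots.csv", index=False)
        wear_map_to_csv(self.wear, outdir / "wear_map.csv")
        summary = dict(self.summary)
        summary["manifest_hash"] = self.manifest["config_hash"]
        (outdir / "summary.yaml").write_text(yaml.safe_dump(_pyfloats(summary), sort_keys=True))
        if vtk:
            from .io_vtk import write_wear_vtk

            write_wear_vtk(outdir / "wear_map.vtk", self.wear)


def _pyfloats(obj):
    if isinstance(obj, dict):
        return {k: _pyfloats(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_brushing(config: SimulationConfig = None, progress: bool = True) -> RunResults:
    """Execute one full two-stroke brushing cycle.

    Records decimated per-tip contact forces, instantaneous + 5 ms
    rolling-max per-tip snapshots at the interproximal crossings (stroke
    fractions 1/5 and 4/5), and the Archard wear map, continuously.
    """
    config = config or SimulationConfig()
    assembly, teeth, motion = config.build()
    n_steps = int(math.ceil(motion.duration / _dt_of(config, assembly)))
    eng = Engine.from_assembly(
        assembly,
        teeth,
        motion,
        params=config.engine_params(),
        dt=config.dt,
        max_log_rows=n_steps // config.log_stride + 4,
    )
    total = motion.duration
    n_slices = 10
    for k in range(n_slices):
        eng.run_until(total * (k + 1) / n_slices)
        if progress:
            log.info(
                "brushing %3d%%: t=%.3f s, KE=%.3e J, max groove tip force %.3g N",
                (k + 1) * 100 // n_slices,
                eng.t,
                eng.stats[2],
                float(np.max(eng.tip_groove_max, initial=0.0)),
            )
    return _collect_results(config, assembly, teeth, motion, eng)


def _dt_of(config: SimulationConfig, assembly: BrushAssembly) -> float:
    if config.dt is not None:
        return config.dt
    from .engine import critical_timestep

    return critical_timestep(assembly, ENAMEL, depth=config.depth, safety=config.dt_safety)


def _collect_results(config, assembly, teeth, motion, eng: Engine) -> RunResults:
    params = WearParams(archard_constant=config.archard_k, hardness=ENAMEL.hardness)
    wmap = WearMap(teeth, params=params, cell_size=config.wear_cell)
    wmap.work = eng.work_grid
    wmap.grid = (params.archard_constant / params.hardness) * eng.work_grid
    wmap.dropped_work = float(eng.dropped[0])

    frames = eng.log_frames()
    frac = np.minimum(eng.par[21] * frames["t"] / motion.stroke, 1.0)  # V t / L
    tol = config.log_stride * eng.dt * motion.speed / motion.stroke + 1e-9
    forces = pd.DataFrame(
        {
            "t": frames["t"],
            "head_displacement": frames["s"],
            "stroke_fraction": frac,
            "kinetic_energy": frames["ke"],
            "interproximal_crossing": (np.abs(frac - 0.2) <= tol) | (np.abs(frac - 0.8) <= tol),
            "mean_tip_fn": frames["tip_fn"].mean(axis=1),
            "mean_tip_ft": frames["tip_ft"].mean(axis=1),
            "max_tip_fn": frames["tip_fn"].max(axis=1) if frames["tip_fn"].size else frames["t"],
            "max_tip_ft": frames["tip_ft"].max(axis=1) if frames["tip_ft"].size else frames["t"],
        }
    )

    snap_rows = []
    labels = ["L/5", "4L/5"]
    for sidx in range(2):
        if eng.snap_done[sidx] == 0:
            continue
        for k in range(len(eng.tip_idx)):
            snap_rows.append(
                {
                    "crossing": labels[sidx],
                    "tuft": k,
                    "tip_x": eng.snap_tip_x[sidx, k],
                    "tip_y": eng.snap_tip_y[sidx, k],
                    "force": eng.snap_tip_f[sidx, k],
                    "normal_force": eng.snap_tip_fn[sidx, k],
                    "tangential_force": eng.snap_tip_ft[sidx, k],
                    "rolling_max_force": eng.snap_win_max[sidx, k],
                }
            )
    snapshots = pd.DataFrame(
        snap_rows,
        columns=[
            "crossing",
            "tuft",
            "tip_x",
            "tip_y",
            "force",
            "normal_force",
            "tangential_force",
            "rolling_max_force",
        ],
    )

    wear_summary = summarize_wear(wmap)
    in_contact = eng.snap_count.sum()
    mean_snap = (
        float((eng.snap_mean * eng.snap_count).sum() / in_contact) if in_contact > 0 else 0.0
    )
    summary = {
        "speed": config.speed,
        "depth": config.depth,
        "stroke": config.stroke,
        "dt": eng.dt,
        "n_steps": eng.step_count,
        "duration": motion.duration,
        "max_groove_tip_force": float(np.max(eng.tip_groove_max, initial=0.0)),
        "max_crossing_tip_force": float(np.max(eng.snap_win_max, initial=0.0)),
        "max_crossing_groove_tip_force": float(np.max(eng.snap_groove_max, initial=0.0)),
        "mean_crossing_tip_force": mean_snap,
        "mean_crossing_tip_force_L5": float(eng.snap_mean[0]),
        "mean_crossing_tip_force_4L5": float(eng.snap_mean[1]),
        "tips_in_contact_L5": int(eng.snap_count[0]),
        "tips_in_contact_4L5": int(eng.snap_count[1]),
        **{f"wear_{k}": v for k, v in wear_summary.items()},
    }
    manifest = eng_manifest(config, eng)
    return RunResults(config, manifest, wmap, _pyfloats(summary), forces, snapshots)


def eng_manifest(config: SimulationConfig, eng: Engine) -> dict:
    return config.manifest(extra={"dt": float(eng.dt), "n_steps": int(eng.step_count)})


def run_sweep(
    base: SimulationConfig = None,
    depths=None,
    speeds=None,
    progress: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """The brushing-speed x brushing-depth study.

    Defaults reproduce the two reference slices: depth in {r, r/2, r/4} at
    V = 0.1 m/s, and speed in {0.05, 0.10, 0.15} m/s at d_z = r (five
    distinct conditions).  Returns ``(results, table)`` where ``table`` has
    one row per condition.  Per-run failures are isolated: the sweep
    continues and the table records the error.
    """
    base = base or SimulationConfig()
    r = base.particle_diameter / 2.0
    if depths is None:
        depths = [r, r / 2.0, r / 4.0]
    if speeds is None:
        speeds = [0.05, 0.10, 0.15]
    conditions = [(0.10, d) for d in depths] + [(v, r) for v in speeds]
    seen, ordered = set(), []
    for cond in conditions:
        key = (round(cond[0], 12), round(cond[1], 15))
        if key not in seen:
            seen.add(key)
            ordered.append(cond)
    results, rows = {}, []
    for v, d in ordered:
        cfg = dataclasses.replace(base, speed=v, depth=d)
        try:
            res = run_brushing(cfg, progress=progress)
        except Exception as exc:  # isolate per-run failures
            log.error("run (V=%.2f, d_z=%.2e) failed: %s", v, d, exc)
            rows.append({"speed": v, "depth": d, "error": str(exc)})
            continue
        results[(v, d)] = res
        rows.append(
            {
                "speed": v,
                "depth": d,
                "total_wear": res.summary["wear_total"],
                "groove_fraction": res.summary["wear_groove_fraction"],
                "groove_density_ratio": res.summary["wear_groove_density_ratio"],
                "symmetry_score": res.summary["wear_symmetry_score"],
                "max_groove_tip_force": res.summary["max_groove_tip_force"],
                "max_crossing_groove_tip_force": res.summary["max_crossing_groove_tip_force"],
                "mean_crossing_tip_force": res.summary["mean_crossing_tip_force"],
            }
        )
    return results, pd.DataFrame(rows)


def run_validation(loads=None, target_pct: float = 3.3, gate_pct: float = 5.0) -> dict:
    """Cantilever bench over a 0-30 N sweep.

    Returns the per-load error table plus pass/fail against the target
    (3.3%) and hard gate (5%) at the maximum load.
    """
    if loads is None:
        loads = np.arange(2.5, 30.01, 2.5)
    table = deflection_error_curve(loads)
    err_max_load = float(table.loc[table["load"].idxmax(), "pct_error"])
    return {
        "table": table,
        "max_load": float(table["load"].max()),
        "error_at_max_load": err_max_load,
        "meets_target": bool(err_max_load <= target_pct),
        "meets_gate": bool(err_max_load <= gate_pct),
    }
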