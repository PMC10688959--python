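"""Sequential fitting pipeline: functional joint centers -> scale
initialization -> inverse kinematics -> bilevel MAP refinement -> (with GRF)
jerk smoothing -> linear COM/mass fit -> iterative angular fit -> final
residual-minimizing optimization."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import io as bio
from .dynamics_fit import (
    apply_com_to_root,
    fit_angular,
    fit_com,
    residual_metrics,
    smooth_jerk,
    DEFAULT_JERK_WEIGHT,
)
from .final_opt import DynamicSolution, FinalFitConfig, final_fit
from .kinematics_init import fit_joint_constraints, ik_solve, initialize_scales
from .marker_fit import (
    BilevelConfig,
    KinematicSolution,
    Priors,
    bilevel_fit,
    marker_error_metrics,
)
from .skeleton import Skeleton, com_positions_trajectory

log = logging.getLogger("biomechfit")


@dataclass
class PipelineConfig:
    skeleton: str = ""
    markers: str = ""
    grf: Optional[str] = None
    outdir: str = "out"
    kinematics_only: bool = False
    dump_intermediate: bool = False
    seed: int = 0
    jerk_weight: float = DEFAULT_JERK_WEIGHT
    init_frames: int = 20
    joint_fit_frames: int = 120
    bilevel: BilevelConfig = field(default_factory=BilevelConfig)
    final: FinalFitConfig = field(default_factory=FinalFitConfig)
    priors: Priors = field(default_factory=Priors)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if k == "priors":
                cfg.priors = Priors(**v)
            elif k == "bilevel":
                cfg.bilevel = BilevelConfig(**v)
            elif k == "final":
                cfg.final = FinalFitConfig(**v)
            elif hasattr(cfg, k):
                setattr(cfg, k, v)
            else:
                raise ValueError(f"unknown config key {k!r}")
        return cfg


@dataclass
class StageRecord:
    name: str
    seconds: float
    info: Dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineResult:
    kinematic: KinematicSolution
    dynamic: Optional[DynamicSolution]
    skeleton: Skeleton            # scaled + registered (+ masses if dynamic)
    stages: List[StageRecord]

    @property
    def solution(self):
        return self.dynamic if self.dynamic is not None else self.kinematic

    def report_dict(self) -> dict:
        # wall times are logged, not reported: reports must be bit-identical
        # across runs with the same inputs
        d = {"stages": [{"name": s.name, **s.info} for s in self.stages]}
        d["kinematic"] = self.kinematic.report_dict()
        if self.dynamic is not None:
            d["dynamic"] = self.dynamic.report_dict()
        return d


def fit_trial(
    skel: Skeleton,
    trial: bio.MarkerTrial,
    grf: Optional[bio.GrfTrial] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full sequential pipeline on in-memory data."""
    cfg = config or PipelineConfig()
    priors = cfg.priors
    stages: List[StageRecord] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        out = fn()
        rec = StageRecord(name, time.perf_counter() - t0)
        stages.append(rec)
        log.info("stage %-16s %6.2fs", name, rec.seconds)
        return out, rec

    constraints, _ = stage("joint_centers", lambda: fit_joint_constraints(
        skel, trial, max_frames=cfg.joint_fit_frames))
    if cfg.dump_intermediate and cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        dump = {
            name: {
                "kind": c.kind,
                "centers": c.centers.tolist(),
                **({"axes": c.axes.tolist()} if c.axes is not None else {}),
            }
            for name, c in constraints.items()
        }
        with open(os.path.join(cfg.outdir, "joint_fits.json"), "w") as fh:
            json.dump(dump, fh)
    scales0, _ = stage("scale_init", lambda: initialize_scales(
        skel, trial, constraints, n_frames=cfg.init_frames))
    work0 = skel.with_scales(scales0)
    q0, _ = stage("ik_init", lambda: ik_solve(work0, trial))
    init = KinematicSolution(q0, scales0, skel.marker_offsets())
    kin, rec = stage("bilevel_fit", lambda: bilevel_fit(
        skel, init, trial, priors, cfg.bilevel))
    rec.info.update(marker_rmse=kin.marker_rmse, objective=kin.objective)

    fitted = skel.with_scales(kin.scales)
    fitted.set_marker_offsets(kin.marker_offsets)

    if grf is None or cfg.kinematics_only:
        return PipelineResult(kin, None, fitted, stages)

    dt = trial.dt
    grf_rs = grf.resampled(trial.times) if abs(grf.frame_rate - trial.frame_rate) > 1e-9 \
        else grf
    q_s, _ = stage("smooth_jerk", lambda: smooth_jerk(kin.q, dt, cfg.jerk_weight))
    assignment, _ = stage("foot_assignment", lambda: bio.assign_plates_to_feet(
        fitted, q_s, grf_rs))
    f_total = sum(p.force for p in grf_rs.plates)

    def run_com():
        z_hat = com_positions_trajectory(fitted, q_s)
        return fit_com(z_hat, f_total, dt, fitted.gravity,
                       fallback_mass=fitted.total_mass)
    com, rec = stage("com_fit", run_com)
    rec.info.update(mass=com.mass, com_rmse=com.fit_rmse)
    fitted.segment_masses = np.array(
        [s.nominal_mass_fraction for s in fitted.segments]) * com.mass
    q_c = apply_com_to_root(fitted, q_s, com.Z)

    ang, rec = stage("angular_fit", lambda: fit_angular(
        fitted, q_c, grf_rs, assignment, dt, com_fit=com,
        tol=cfg.final.angular_tol, max_iter=cfg.final.angular_max_iter))
    rec.info.update(iterations=ang.iterations, converged=float(ang.converged))

    dyn, rec = stage("final_fit", lambda: final_fit(
        skel, kin, ang.q, com, trial, grf_rs, assignment, priors, cfg.final))
    rec.info.update(residual_force_pct=dyn.residuals.force_normalized_pct,
                    residual_torque_pct=dyn.residuals.torque_normalized_pct,
                    total_mass=dyn.total_mass, marker_rmse=dyn.marker_rmse)
    fitted.segment_masses = dyn.segment_masses
    return PipelineResult(kin, dyn, fitted, stages)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs, fit, write all outputs."""
    skel = Skeleton.load(config.skeleton)
    trial = bio.read_trc(config.markers)
    grf = bio.read_grf_mot(config.grf) if (config.grf and not config.kinematics_only) \
        else None
    result = fit_trial(skel, trial, grf, config)

    os.makedirs(config.outdir, exist_ok=True)
    out_skel = result.skeleton
    out_skel.save(os.path.join(config.outdir, "skeleton_fitted.json"))
    rot = out_skel.rotational_dofs()
    names = out_skel.coordinate_names()
    sol = result.solution
    bio.write_motion_mot(sol.q, names, trial.frame_rate,
                         os.path.join(config.outdir, "angles.mot"), rotational=rot)
    if result.dynamic is not None:
        bio.write_motion_mot(result.dynamic.joint_torques,
                             [f"{n}_moment" for n in names], trial.frame_rate,
                             os.path.join(config.outdir, "torques.mot"))
    bio.write_report(result, os.path.join(config.outdir, "report.json"))
    return result


def compare_solutions(dir_a: str, dir_b: str) -> dict:
    """Per-metric deltas between two pipeline output directories, including
    per-coordinate angle RMSE over the shared coordinate names."""
    import warnings

    rep_a = bio.read_report(os.path.join(dir_a, "report.json"))
    rep_b = bio.read_report(os.path.join(dir_b, "report.json"))
    out: Dict[str, object] = {"metric_deltas": {}}
    for section in ("kinematic", "dynamic"):
        a, b = rep_a.get(section), rep_b.get(section)
        if not (isinstance(a, dict) and isinstance(b, dict)):
            continue
        for key in sorted(set(a) & set(b)):
            va, vb = a[key], b[key]
            if isinstance(va, (int, float)) and isinstance(vb, (int, float)):
                out["metric_deltas"][f"{section}.{key}"] = float(vb) - float(va)
    names_a, qa, _ = bio.read_motion_mot(os.path.join(dir_a, "angles.mot"))
    names_b, qb, _ = bio.read_motion_mot(os.path.join(dir_b, "angles.mot"))
    shared = [n for n in names_a if n in names_b]
    if len(shared) < len(names_a) or len(shared) < len(names_b):
        warnings.warn("coordinate lists differ; comparing the intersection")
    T = min(len(qa), len(qb))
    per_coord = {}
    for n in shared:
        ca = qa[:T, names_a.index(n)]
        cb = qb[:T, names_b.index(n)]
        per_coord[n] = float(np.sqrt(np.mean((ca - cb) ** 2)))
    out["per_coordinate_rmse"] = per_coord
    return out
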