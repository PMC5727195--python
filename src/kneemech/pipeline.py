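"""End-to-end orchestration: fixtures -> IK -> recruitment -> load export ->
finite elements, with provenance metadata on every artifact."""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fem, fixtures, loads
from .geometry import build_fea_frame
from .kinematics import cardan_knee_angles, solve_inverse_kinematics
from .recruitment import (RecruitmentSolution, assemble_coefficients,
                          assemble_load_vector, joint_reaction_force,
                          scale_group_strength, solve_recruitment)


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the printed model constants."""

    out_dir: str = "kneemech_out"
    seed: int = 0
    stance_duration: float = 0.65
    body_mass: float = 61.2
    fdk_tolerance: float = 0.3
    contact_modulus: float = 9.3e9
    reference_stance_time: float = 0.65
    strength_factors: tuple[float, ...] = (0.5, 0.75, 1.0)
    fe_stance_steps: int = 12
    fe_axial_scale: float = 0.25  # fraction of the exported axial load the
    # desk-scale FE fixture carries (its contact patch is a fraction of a
    # full joint surface)
    stages: tuple[str, ...] = ("fixtures", "ik", "recruit", "sweep", "export", "fe")

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# per-frame recruitment over a trial
# ---------------------------------------------------------------------------


def solve_gait_recruitment(trial: fixtures.GaitTrial, muscles=None):
    """Hinge-knee inverse dynamics + recruitment at every frame."""
    muscles = muscles if muscles is not None else trial.muscles
    out = []
    x_prev = None
    for f in range(trial.n_frames):
        prob = assemble_coefficients(trial.model, trial.kin, f, muscles)
        prob.d = assemble_load_vector(trial.model, trial.kin, f, trial.externals[f])
        sol = solve_recruitment(prob, x0=x_prev)
        x_prev = sol.f
        out.append((prob, sol))
    return out


def knee_axial_force(trial: fixtures.GaitTrial, results) -> np.ndarray:
    """Compressive tibiofemoral reaction along the shank axis per frame [N]."""
    out = np.empty(len(results))
    for f, (prob, sol) in enumerate(results):
        lam = joint_reaction_force(prob, sol, "shank")
        z_shank = trial.kin.poses[f]["shank"].rotation[:, 2]  # up the tibia
        out[f] = -float(lam @ z_shank)
    return out


def strength_sweep(trial: fixtures.GaitTrial, factors=(0.5, 0.75, 1.0)) -> dict:
    """Peak knee axial force vs knee flexor/extensor strength factor."""
    sweep = {}
    for fac in factors:
        muscles = scale_group_strength(trial.muscles, "knee-flexor", fac)
        muscles = scale_group_strength(muscles, "knee-extensor", fac)
        results = solve_gait_recruitment(trial, muscles)
        series = knee_axial_force(trial, results)
        sweep[fac] = {"series": series, "peak": float(series.max()),
                      "results": results}
    return sweep


# ---------------------------------------------------------------------------
# load export
# ---------------------------------------------------------------------------

_MED_EPI = np.array([0.0, 0.045, -fixtures.THIGH_LEN])
_LAT_EPI = np.array([0.0, -0.045, -fixtures.THIGH_LEN])


def anatomical_frames_local(model) -> dict:
    """FEA coordinate systems at the reference (imaging) pose, expressed in
    each bone's local coordinates; they then move rigidly with the bone."""
    import kneemech.geometry as G
    from kneemech.kinematics import RigidTransform

    poses0 = model.forward_kinematics(np.zeros(model.nq))
    out = {}
    for seg, med, lat, hip in (
            ("thigh", _MED_EPI, _LAT_EPI, np.zeros(3)),
            ("shank", np.array([0.0, 0.045, 0.0]), np.array([0.0, -0.045, 0.0]),
             None)):
        pose = poses0[seg]
        hip_w = poses0["thigh"].translation
        fr = G.build_fea_frame(pose.apply(med), pose.apply(lat), hip_w)
        inv = pose.inverse()
        out[seg] = (inv.apply(fr.origin), inv.rotation @ fr.axes)
    return out


def _frame_world(pose, local) -> "object":
    from kneemech.geometry import AnatomicalFrame
    origin_l, axes_l = local
    return AnatomicalFrame(pose.apply(origin_l), pose.rotation @ axes_l)


def export_equivalent_loads(trial: fixtures.GaitTrial, results) -> loads.EquivalentLoadSeries:
    """Equivalent femoral loads about the femoral reference point in the
    tibia FEA basis, plus the Cardan flexion angle, over the trial."""
    T = trial.n_frames
    ff = np.zeros((T, 3))
    fm = np.zeros((T, 3))
    flex = np.zeros(T)
    frames_local = anatomical_frames_local(trial.model)
    for f in range(T):
        poses = trial.kin.poses[f]
        femur_frame = _frame_world(poses["thigh"], frames_local["thigh"])
        tibia_frame = _frame_world(poses["shank"], frames_local["shank"])
        ref_point = femur_frame.origin  # femoral reference point
        prob, sol = results[f]
        F, M = loads.equivalent_femur_load(trial.model, trial.kin, f, prob, sol,
                                           "thigh", "shank", ref_point, tibia_frame,
                                           externals=trial.externals[f])
        ff[f], fm[f] = F, M
        flex[f] = cardan_knee_angles(femur_frame, tibia_frame)[0]
    zeros = np.zeros((T, 3))
    return loads.EquivalentLoadSeries(trial.truth.time, ff, fm, zeros, zeros, flex)


def fe_wrench_from_series(series: loads.EquivalentLoadSeries, scale: float = 1.0):
    """Map the exported knee-frame wrench onto the FE fixture axes.

    Knee frame: x medial-lateral, y longitudinal (axial), z anterior.
    FE fixture: x medial-lateral, y anterior-posterior, z axial (up).
    The axial component presses the indenter down (-z); in-plane force
    components and moments are passed through with the axis permutation.
    """
    def wrench(pct):
        w = series.wrench_at_pct(pct) * scale
        fx, fy, fz = w[0], w[1], w[2]
        mx, my, mz = w[3], w[4], w[5]
        return np.array([fx, fz, -abs(fy), mz, -my, mx])
    return wrench


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the staged pipeline, writing artifacts under ``out_dir``.

    Returns a summary dict (also written as JSON) with the key quantities
    of each stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    summary: dict = {"config_hash": config.hash(), "seed": config.seed,
                     "version": __version__, "stages": {}}

    spec = fixtures.SyntheticGaitSpec(stance_duration=config.stance_duration,
                                      body_mass=config.body_mass, seed=config.seed)
    trial = fixtures.generate_gait_record(spec)
    if "fixtures" in config.stages:
        trial.record.to_csv(out / "markers.csv")
        trial.grf.to_csv(out / "grf.csv", index=False)
        summary["stages"]["fixtures"] = {"n_frames": trial.n_frames}

    traj = trial.truth
    if "ik" in config.stages:
        traj = solve_inverse_kinematics(trial.record, trial.model)
        err = float(np.abs(traj.q - trial.truth.q).max())
        pd.DataFrame(traj.q).to_csv(out / "ik_q.csv", index=False)
        summary["stages"]["ik"] = {"max_coordinate_error": err,
                                   "max_marker_rms": float(traj.residual_rms.max())}

    results = None
    if "recruit" in config.stages:
        results = solve_gait_recruitment(trial)
        axial = knee_axial_force(trial, results)
        resid = max(s.equilibrium_residual for _, s in results)
        pd.DataFrame({
            "time": trial.truth.time, "knee_axial_force": axial,
            **{m.name: [s.f_muscle[i] for _, s in results]
               for i, m in enumerate(trial.muscles)},
        }).to_csv(out / "recruitment.csv", index=False)
        summary["stages"]["recruit"] = {
            "peak_knee_axial_force": float(axial.max()),
            "peak_knee_axial_force_bw": float(axial.max() / (config.body_mass * 9.81)),
            "max_equilibrium_residual": float(resid)}

    if "sweep" in config.stages:
        sweep = strength_sweep(trial, config.strength_factors)
        rows = [{"factor": k, "peak_axial_force": v["peak"]} for k, v in sweep.items()]
        pd.DataFrame(rows).to_csv(out / "strength_sweep.csv", index=False)
        summary["stages"]["sweep"] = {str(k): v["peak"] for k, v in sweep.items()}

    series = None
    if "export" in config.stages:
        if results is None:
            results = solve_gait_recruitment(trial)
        series = export_equivalent_loads(trial, results)
        series.to_csv(out / "equivalent_loads.csv")
        summary["stages"]["export"] = {
            "peak_axial_equivalent_load": float(np.abs(series.femur_force[:, 1]).max())}

    if "fe" in config.stages:
        if series is None:
            if results is None:
                results = solve_gait_recruitment(trial)
            series = export_equivalent_loads(trial, results)
        knee_fe = fixtures.simplified_knee_fe(seed=config.seed)
        protocol = fem.LoadProtocol(stance_steps=config.fe_stance_steps,
                                    stance_duration=config.stance_duration)
        wrench = fe_wrench_from_series(series, config.fe_axial_scale)
        history = fem.run_stance_simulation(knee_fe.model, wrench, protocol)
        post = fem.postprocess(history, knee_fe.mesh)
        pd.DataFrame(post).to_csv(out / "fe_summary.csv", index=False)
        peak = max(post["peak_pressure"])
        summary["stages"]["fe"] = {
            "peak_contact_pressure_mpa": peak / 1e6,
            "peak_contact_area_mm2": max(post["contact_area"]) * 1e6}

    summary["elapsed_s"] = _time.time() - t0
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
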