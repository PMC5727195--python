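"""MS -> FE hand-off: equivalent femoral/patellar loads and trial selection.

A free-body diagram of the femur sums muscle forces, the hip reaction,
gravity and inertia — but omits the tibiofemoral and patellofemoral
reactions.  The resulting wrench, reduced about the femoral reference point
and expressed in the tibia FEA basis, together with the tibiofemoral
flexion angle, is everything the finite-element stage consumes.  At
equilibrium Newton closure holds: equivalent wrench + omitted joint
reaction wrench = 0, which the tests re-verify by independent summation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AnatomicalFrame
from .kinematics import SegmentKinematics, SegmentModel, skew
from .recruitment import (ExternalLoad, Muscle, RecruitmentProblem,
                          RecruitmentSolution)

GRAVITY = np.array([0.0, 0.0, -9.81])


# ---------------------------------------------------------------------------
# domain type
# ---------------------------------------------------------------------------


@dataclass
class EquivalentLoadSeries:
    """Equivalent femoral/patellar wrenches over stance, tibia-FEA basis,
    about the femoral reference point."""

    time: np.ndarray
    femur_force: np.ndarray  # (T, 3) [N]
    femur_moment: np.ndarray  # (T, 3) [N m]
    patella_force: np.ndarray
    patella_moment: np.ndarray
    flexion: np.ndarray  # (T,) [rad]
    frame_tag: str = "tibia FEA coordinate system"
    reference_point_tag: str = "femoral reference point"

    def __post_init__(self):
        T = len(self.time)
        for name in ("femur_force", "femur_moment", "patella_force",
                     "patella_moment", "flexion"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != T:
                raise ValueError(f"{name} does not share the series time base")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @property
    def pct_stance(self) -> np.ndarray:
        t = self.time
        return 100.0 * (t - t[0]) / (t[-1] - t[0])

    def wrench_at_pct(self, pct: float) -> np.ndarray:
        """Interpolated femoral (force, moment) 6-vector at % stance."""
        p = self.pct_stance
        out = np.empty(6)
        for k in range(3):
            out[k] = np.interp(pct, p, self.femur_force[:, k])
            out[3 + k] = np.interp(pct, p, self.femur_moment[:, k])
        return out

    def to_csv(self, path) -> None:
        header = {"frame": self.frame_tag, "reference_point": self.reference_point_tag,
                  "units": {"force": "N", "moment": "N m", "time": "s",
                            "flexion": "rad"}}
        df = pd.DataFrame({
            "time": self.time, "pct_stance": self.pct_stance,
            **{f"femur_f{ax}": self.femur_force[:, k] for k, ax in enumerate("xyz")},
            **{f"femur_m{ax}": self.femur_moment[:, k] for k, ax in enumerate("xyz")},
            **{f"patella_f{ax}": self.patella_force[:, k] for k, ax in enumerate("xyz")},
            **{f"patella_m{ax}": self.patella_moment[:, k] for k, ax in enumerate("xyz")},
            "flexion": self.flexion,
        })
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "EquivalentLoadSeries":
        with open(path) as fh:
            first = fh.readline()
            header = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
            df = pd.read_csv(fh)
        get3 = lambda stem: df[[f"{stem}x", f"{stem}y", f"{stem}z"]].to_numpy()
        return cls(df["time"].to_numpy(), get3("femur_f"), get3("femur_m"),
                   get3("patella_f"), get3("patella_m"), df["flexion"].to_numpy(),
                   frame_tag=header.get("frame", "tibia FEA coordinate system"),
                   reference_point_tag=header.get("reference_point",
                                                  "femoral reference point"))


# ---------------------------------------------------------------------------
# free-body summation
# ---------------------------------------------------------------------------


def muscle_point_forces(model: SegmentModel, poses, muscle: Muscle,
                        tension: float) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """World attachment forces a tensioned muscle applies to each segment."""
    pts = [poses[s].apply(p) for s, p in muscle.path]
    out = []
    for k, (seg, _) in enumerate(muscle.path):
        fdir = np.zeros(3)
        if k > 0:
            u = pts[k - 1] - pts[k]
            fdir += u / np.linalg.norm(u)
        if k < len(pts) - 1:
            u = pts[k + 1] - pts[k]
            fdir += u / np.linalg.norm(u)
        out.append((seg, pts[k], tension * fdir))
    return out


def _segment_world_wrench(model, kin: SegmentKinematics, frame: int, seg_name: str,
                          about: np.ndarray, gravity=GRAVITY) -> np.ndarray:
    """Gravity + inertia wrench (world) of one segment about ``about``."""
    s = model.segment(seg_name)
    R = kin.poses[frame][seg_name].rotation
    com = kin.com_world[seg_name][frame]
    f = s.mass * gravity - s.mass * kin.acc_com_world[seg_name][frame]
    w = kin.omega_body[seg_name][frame]
    dw = kin.domega_body[seg_name][frame]
    m_body = -(s.inertia @ dw + skew(w) @ s.inertia @ w)
    m = R @ m_body + np.cross(com - about, f)
    return np.concatenate([f, m])


def equivalent_segment_load(model: SegmentModel, kin: SegmentKinematics, frame: int,
                            problem: RecruitmentProblem, solution: RecruitmentSolution,
                            segment: str, exclude_joints: tuple[str, ...],
                            reference_point: np.ndarray, basis: np.ndarray,
                            externals: list[ExternalLoad] = (),
                            gravity=GRAVITY) -> tuple[np.ndarray, np.ndarray]:
    """Free-body wrench of ``segment`` excluding the named joint reactions.

    ``exclude_joints`` lists child-segment names whose reactions onto this
    segment are omitted (e.g. the shank for the tibiofemoral joint).  The
    wrench is reduced about ``reference_point`` (world) and its components
    returned in the columns of ``basis`` (tibia FEA axes).
    """
    poses = kin.poses[frame]
    about = np.asarray(reference_point, dtype=float)
    total = _segment_world_wrench(model, kin, frame, segment, about, gravity)

    for m, t in zip(problem.muscles, solution.f_muscle):
        if t == 0.0 or all(s != segment for s, _ in m.path):
            continue
        for seg, pt, f in muscle_point_forces(model, poses, m, t):
            if seg != segment:
                continue
            total[:3] += f
            total[3:] += np.cross(pt - about, f)

    for rd, fval in zip(problem.reactions, solution.f_reaction):
        child = rd.joint_segment
        parent = model.segment(child).parent
        if segment not in (child, parent) or child in exclude_joints:
            continue
        sign = 1.0 if segment == child else -1.0
        jc = poses[child].translation
        if rd.kind == "force":
            f = sign * fval * rd.direction
            total[:3] += f
            total[3:] += np.cross(jc - about, f)
        else:
            total[3:] += sign * fval * rd.direction

    for ext in externals:
        if ext.segment != segment:
            continue
        total[:3] += ext.force
        total[3:] += np.cross(ext.point - about, ext.force) + ext.moment

    B = np.asarray(basis, dtype=float)
    return B.T @ total[:3], B.T @ total[3:]


def equivalent_femur_load(model, kin, frame, problem, solution,
                          femur_segment: str, knee_child: str,
                          reference_point: np.ndarray, tibia_frame: AnatomicalFrame,
                          externals=(), gravity=GRAVITY):
    """Equivalent femoral load: everything on the femur except the TF (and
    PF, when modelled) reactions, about the femoral reference point, in the
    tibia FEA basis."""
    exclude = (knee_child,) if isinstance(knee_child, str) else tuple(knee_child)
    if not any(rd.joint_segment == femur_segment for rd in problem.reactions):
        raise ValueError("solution carries no hip reaction for the femur segment")
    return equivalent_segment_load(model, kin, frame, problem, solution,
                                   femur_segment, exclude, reference_point,
                                   tibia_frame.axes, externals, gravity)


def equivalent_patella_load(model, kin, frame, problem, solution,
                            patella_segment: str, reference_point: np.ndarray,
                            tibia_frame: AnatomicalFrame, externals=(),
                            gravity=GRAVITY):
    """Equivalent patellar load: everything on the patella except the PF
    reaction and the rigid patellar tendon reaction (both are joint
    reactions of the patella segment), about the femoral reference point."""
    return equivalent_segment_load(model, kin, frame, problem, solution,
                                   patella_segment, (patella_segment,),
                                   reference_point, tibia_frame.axes,
                                   externals, gravity)


# ---------------------------------------------------------------------------
# stance detection and trial selection
# ---------------------------------------------------------------------------


def detect_stance(time: np.ndarray, vertical_grf: np.ndarray,
                  threshold: float = 20.0, hysteresis: float = 5.0) -> tuple[float, float]:
    """(start, end) of stance from the vertical ground reaction.

    Rising edge at ``threshold``, falling edge at ``threshold - hysteresis``.
    """
    fz = np.asarray(vertical_grf, dtype=float)
    above = fz > threshold
    if not above.any():
        raise ValueError("no stance detected: vertical GRF never exceeds threshold")
    i0 = int(np.argmax(above))
    below = fz[i0:] < (threshold - hysteresis)
    i1 = int(i0 + np.argmax(below)) - 1 if below.any() else len(fz) - 1
    return float(time[i0]), float(time[i1])


@dataclass
class TrialRecord:
    """One processed gait trial: stance time plus exported load curves
    resampled on a common %-stance grid (channel name -> array)."""

    name: str
    stance_time: float
    curves: dict[str, np.ndarray] = field(default_factory=dict)


def select_trials(trials: list[TrialRecord], reference_stance_time: float,
                  max_deviation: float = 0.10) -> tuple[list[TrialRecord], TrialRecord | None]:
    """Retain trials within the stance-time deviation band, ranked by
    closeness; flag the most-average-trend representative.

    The representative minimises the summed RMS distance of its load curves
    to the retained-set mean over all channels.  Returns (retained,
    representative); retained may be empty (representative None).
    """
    if reference_stance_time <= 0:
        raise ValueError("reference stance time must be positive")
    retained = [t for t in trials
                if abs(t.stance_time - reference_stance_time) / reference_stance_time
                <= max_deviation]
    retained.sort(key=lambda t: abs(t.stance_time - reference_stance_time))
    if not retained:
        return [], None
    channels = sorted(set().union(*[set(t.curves) for t in retained])) if any(
        t.curves for t in retained) else []
    if not channels:
        return retained, retained[0]
    means = {ch: np.mean([t.curves[ch] for t in retained if ch in t.curves], axis=0)
             for ch in channels}

    def score(t: TrialRecord) -> float:
        return sum(np.sqrt(np.mean((t.curves[ch] - means[ch]) ** 2))
                   for ch in channels if ch in t.curves)

    return retained, min(retained, key=score)
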