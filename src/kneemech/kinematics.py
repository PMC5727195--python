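"""Marker data handling, multibody pose estimation and joint-angle extraction.

The segment model is a kinematic tree (pelvis root, spherical hip, revolute
knee/ankle by default).  Generalised coordinates q concatenate, per segment:
free root 6 (3 translations + XYZ Euler), spherical 3 (XYZ Euler), revolute 1
(angle about a fixed axis).  Marker records use a documented wide-CSV dialect
(`time` column plus `<marker>.x/.y/.z` columns, metres) so the test suite has
no binary-format dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from .geometry import RigidTransform


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------


def rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_xyz(angles):
    ax, ay, az = angles
    return rot_x(ax) @ rot_y(ay) @ rot_z(az)


def axis_angle(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One rigid segment of the chain.

    ``joint_center_parent`` locates the connecting joint in the parent frame;
    the segment's own frame has its origin at that joint.  ``joint_axis`` is
    used by revolute joints (expressed in the parent frame at q = 0).
    """

    name: str
    parent: str | None
    joint_type: str  # 'free' | 'spherical' | 'revolute'
    joint_center_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    joint_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    mass: float = 1.0
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))  # in segment frame
    inertia: np.ndarray = field(default_factory=lambda: np.eye(3) * 1e-3)  # body-fixed, about COM

    def __post_init__(self):
        self.joint_center_parent = np.asarray(self.joint_center_parent, dtype=float)
        self.joint_axis = np.asarray(self.joint_axis, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        self.inertia = np.asarray(self.inertia, dtype=float)
        if not np.allclose(self.inertia, self.inertia.T):
            raise ValueError(f"segment {self.name}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ValueError(f"segment {self.name}: inertia must be positive definite")

    @property
    def ndof(self) -> int:
        return {"free": 6, "spherical": 3, "revolute": 1}[self.joint_type]


@dataclass
class SegmentModel:
    """Tree of segments plus marker placements (marker -> segment, local xyz)."""

    segments: list[Segment]
    markers: dict[str, tuple[str, np.ndarray | None]] = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        byname = set(names)
        for s in self.segments:
            if s.parent is not None and s.parent not in byname:
                raise ValueError(f"segment {s.name}: unknown parent {s.parent}")

    @property
    def nq(self) -> int:
        return sum(s.ndof for s in self.segments)

    def q_slices(self) -> dict[str, slice]:
        out, i = {}, 0
        for s in self.segments:
            out[s.name] = slice(i, i + s.ndof)
            i += s.ndof
        return out

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def forward_kinematics(self, q: np.ndarray) -> dict[str, RigidTransform]:
        """World pose of every segment at generalised coordinates q."""
        q = np.asarray(q, dtype=float)
        sl = self.q_slices()
        poses: dict[str, RigidTransform] = {}
        for s in self.segments:
            qi = q[sl[s.name]]
            if s.joint_type == "free":
                R, o = euler_xyz(qi[3:6]), qi[:3].copy()
            else:
                parent = poses[s.parent]
                o = parent.rotation @ s.joint_center_parent + parent.translation
                if s.joint_type == "spherical":
                    R = parent.rotation @ euler_xyz(qi)
                else:
                    R = parent.rotation @ axis_angle(s.joint_axis, qi[0])
            poses[s.name] = RigidTransform(R, o)
        return poses

    def marker_positions(self, q: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        poses = self.forward_kinematics(q)
        names = names if names is not None else list(self.markers)
        out = np.empty((len(names), 3))
        for i, nm in enumerate(names):
            seg, local = self.markers[nm]
            if local is None:
                raise ValueError(f"marker {nm!r} has no local coordinates; run localize_markers")
            out[i] = poses[seg].apply(local)
        return out


@dataclass
class MarkerRecord:
    """Marker trajectories (T x M x 3, metres) with a validity mask, plus
    optional per-plate ground reaction force/moment channels."""

    marker_names: list[str]
    positions: np.ndarray  # (T, M, 3)
    sample_rate: float  # Hz
    mask: np.ndarray | None = None  # (T, M) True = valid
    grf: pd.DataFrame | None = None  # time, fx..fz, mx..mz, copx..copz per plate

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.positions).all(axis=2)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.positions.shape[0]) / self.sample_rate

    def to_csv(self, path) -> None:
        cols = {"time": self.time}
        for j, nm in enumerate(self.marker_names):
            for k, ax in enumerate("xyz"):
                cols[f"{nm}.{ax}"] = self.positions[:, j, k]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_rate: float | None = None) -> "MarkerRecord":
        df = pd.read_csv(path)
        t = df["time"].to_numpy()
        if sample_rate is None:
            sample_rate = 1.0 / np.mean(np.diff(t))
        names = sorted({c.rsplit(".", 1)[0] for c in df.columns if c != "time"})
        pos = np.stack([df[[f"{n}.x", f"{n}.y", f"{n}.z"]].to_numpy() for n in names], axis=1)
        return cls(names, pos, float(sample_rate))


@dataclass
class PoseTrajectory:
    """Generalised coordinates over time with optional derivatives."""

    time: np.ndarray
    q: np.ndarray  # (T, nq)
    qd: np.ndarray | None = None
    qdd: np.ndarray | None = None
    residual_rms: np.ndarray | None = None  # per-frame IK marker residual

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.time)))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def localize_markers(static_record: MarkerRecord, model: SegmentModel) -> SegmentModel:
    """Set each marker's segment-local coordinates from a static trial.

    The static pose is found by IK on the markers that already carry local
    coordinates (the anatomical/MRI markers); every marker in the record is
    then expressed in its segment frame, averaged over visible frames.
    """
    known = [nm for nm, (_, loc) in model.markers.items() if loc is not None]
    if not known:
        raise ValueError("localize_markers needs at least some markers with known local coordinates")
    for nm in static_record.marker_names:
        if nm in model.markers and not static_record.mask[:, static_record.marker_names.index(nm)].any():
            raise ValueError(f"marker {nm!r} never visible in the static trial")
    traj = solve_inverse_kinematics(static_record, model, marker_subset=known)

    new_markers = dict(model.markers)
    for nm in static_record.marker_names:
        if nm not in model.markers:
            continue
        seg, _ = model.markers[nm]
        j = static_record.marker_names.index(nm)
        locals_ = []
        for f in range(static_record.positions.shape[0]):
            if not static_record.mask[f, j]:
                continue
            pose = model.forward_kinematics(traj.q[f])[seg]
            locals_.append(pose.inverse().apply(static_record.positions[f, j]))
        new_markers[nm] = (seg, np.mean(locals_, axis=0))
    return replace(model, markers=new_markers)


def solve_inverse_kinematics(record: MarkerRecord, model: SegmentModel,
                             q0: np.ndarray | None = None,
                             marker_subset: list[str] | None = None) -> PoseTrajectory:
    """Per-frame nonlinear least-squares pose estimate tracking the markers.

    Each frame minimises sum ||p_model(q) - p_measured||^2 over the joint
    coordinates, warm-started from the previous frame.  Under-determined
    frames are flagged, interpolated from the neighbours and warned about.
    """
    use = marker_subset if marker_subset is not None else [
        nm for nm, (_, loc) in model.markers.items() if loc is not None]
    idx = [record.marker_names.index(nm) for nm in use]
    T = record.positions.shape[0]
    nq = model.nq
    q = np.zeros((T, nq))
    rms = np.zeros(T)
    bad = []
    qprev = np.zeros(nq) if q0 is None else np.asarray(q0, dtype=float)
    for f in range(T):
        vis = [k for k, j in enumerate(idx) if record.mask[f, j]]
        if 3 * len(vis) < nq:
            bad.append(f)
            q[f] = qprev
            continue
        names = [use[k] for k in vis]
        meas = record.positions[f, [idx[k] for k in vis]]

        def resid(qv):
            return (model.marker_positions(qv, names) - meas).ravel()

        sol = least_squares(resid, qprev, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        q[f] = sol.x
        rms[f] = np.sqrt(np.mean(sol.fun**2))
        qprev = sol.x
    if bad:
        warnings.warn(f"{len(bad)} under-determined frames interpolated: {bad[:10]}...")
        good = np.setdiff1d(np.arange(T), bad)
        for k in range(nq):
            q[bad, k] = np.interp(np.asarray(bad, dtype=float), good.astype(float), q[good, k])
    return PoseTrajectory(record.time, q, residual_rms=rms)


def cardan_knee_angles(femur_frame, tibia_frame) -> tuple[float, float, float]:
    """Flexion / adduction / internal-rotation Cardan angles femur -> tibia.

    Decomposes the relative rotation as Rx(flexion) Rz(adduction)
    Ry(internal rotation) in the anatomical frames (x medial-lateral,
    y longitudinal towards the hip, z = x cross y), flexion first.
    """
    Rf = femur_frame.axes if hasattr(femur_frame, "axes") else np.asarray(femur_frame)
    Rt = tibia_frame.axes if hasattr(tibia_frame, "axes") else np.asarray(tibia_frame)
    R = Rf.T @ Rt
    beta = float(np.arcsin(np.clip(-R[0, 1], -1.0, 1.0)))
    if abs(beta) > np.deg2rad(89.0):
        warnings.warn("Cardan decomposition near gimbal lock (|adduction| > 89 deg)")
    alpha = float(np.arctan2(R[2, 1], R[1, 1]))
    gamma = float(np.arctan2(R[0, 2], R[0, 0]))
    return alpha, beta, gamma


def cardan_to_matrix(flexion: float, adduction: float, internal: float) -> np.ndarray:
    return rot_x(flexion) @ rot_z(adduction) @ rot_y(internal)


def differentiate(traj: PoseTrajectory, lowpass_hz: float | None = None) -> PoseTrajectory:
    """Central-difference velocities/accelerations (one-sided at the ends),
    with an optional 4th-order zero-lag Butterworth low-pass beforehand."""
    if len(traj.time) < 3:
        raise ValueError("differentiation needs at least 3 frames")
    q = traj.q
    dt = traj.dt
    if lowpass_hz is not None:
        b, a = butter(2, lowpass_hz * 2 * dt)  # filtfilt doubles the order
        q = filtfilt(b, a, q, axis=0)
    qd = np.gradient(q, dt, axis=0, edge_order=2)
    qdd = np.gradient(qd, dt, axis=0, edge_order=2)
    return replace(traj, q=q, qd=qd, qdd=qdd)


# ---------------------------------------------------------------------------
# segment spatial kinematics (shared by the load-vector assembly and the
# dynamically-consistent gait generator)
# ---------------------------------------------------------------------------


@dataclass
class SegmentKinematics:
    """Per-frame spatial kinematics of every segment (world poses, body-frame
    angular velocity/acceleration, world COM acceleration)."""

    poses: list[dict[str, RigidTransform]]
    omega_body: dict[str, np.ndarray]  # (T, 3)
    domega_body: dict[str, np.ndarray]
    acc_com_world: dict[str, np.ndarray]
    com_world: dict[str, np.ndarray]


def segment_kinematics(model: SegmentModel, traj: PoseTrajectory) -> SegmentKinematics:
    """Numerically consistent segment kinematics from a pose trajectory.

    Angular velocity is taken from R^T dR/dt (central differences), so the
    same discrete operators are used when generating consistent ground
    reactions and when assembling the inverse-dynamics load vector.
    """
    T = len(traj.time)
    dt = traj.dt
    poses = [model.forward_kinematics(traj.q[f]) for f in range(T)]
    names = [s.name for s in model.segments]
    Rs = {n: np.stack([poses[f][n].rotation for f in range(T)]) for n in names}
    omega, domega, acc, comw = {}, {}, {}, {}
    for s in model.segments:
        n = s.name
        dR = np.gradient(Rs[n], dt, axis=0, edge_order=2)
        Om = np.einsum("tji,tjk->tik", Rs[n], dR)  # R^T dR, skew
        w = np.stack([Om[:, 2, 1], Om[:, 0, 2], Om[:, 1, 0]], axis=1)
        omega[n] = w
        domega[n] = np.gradient(w, dt, axis=0, edge_order=2)
        cw = np.stack([poses[f][n].apply(s.com) for f in range(T)])
        comw[n] = cw
        acc[n] = np.gradient(np.gradient(cw, dt, axis=0, edge_order=2), dt, axis=0, edge_order=2)
    return SegmentKinematics(poses, omega, domega, acc, comw)
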