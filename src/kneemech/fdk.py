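"""Force-dependent kinematics (FDK) of the knee.

The primary flexion angles are prescribed (tibiofemoral from inverse
kinematics, patellofemoral by a rigid patellar tendon); the remaining
secondary DOFs — 5 tibiofemoral (3 translations, adduction, internal
rotation) and 5 patellofemoral — are found quasi-statically: at each
candidate pose the equilibrium problem is solved with residual-force
unknowns f_FDK along the secondary DOFs, and an outer damped Newton drives
those residuals below tolerance (0.3 N for translations, 0.3 N m for
rotations).

Forces on the moving bodies come from elastic-foundation cartilage contact
(pressure = K * penetration with K = 9.3 GN/m^3), nonlinear
slack/toe/linear ligament bundles, and whatever external wrench the
musculoskeletal stage hands over.

Knee frame convention here: x medial-lateral, y longitudinal (proximal,
towards the hip), z anterior; adduction is rotation about z, internal
rotation about y, flexion about x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import RigidTransform, SurfaceMesh, closest_point_on_triangles
from .kinematics import rot_x, rot_y, rot_z

#: elastic-foundation pressure modulus for cartilage-cartilage contact [N/m^3]
PRESSURE_MODULUS = 9.3e9
#: FDK residual tolerance: N for translations, N m for rotations
FDK_TOLERANCE = 0.3


class FDKConvergenceError(RuntimeError):
    def __init__(self, residuals, iterations):
        super().__init__(
            f"FDK did not converge in {iterations} iterations; "
            f"residuals {np.array2string(np.asarray(residuals), precision=3)}")
        self.residuals = residuals


# ---------------------------------------------------------------------------
# ligaments
# ---------------------------------------------------------------------------


@dataclass
class LigamentBundleMS:
    """Nonlinear slack/toe/linear ligament for the musculoskeletal stage.

    ``stiffness`` is the printed linear-region slope in N per metre of
    elongation (e.g. ACL 306 N/mm = 306e3 N/m).  The toe region is the
    Blankevoort quadratic, spanning strains 0..2*toe_strain, C1-continuous
    with the linear region.  Slack length comes from the pre-strain at the
    reference pose: L0 = L_ref / (1 + pre_strain).
    """

    name: str
    attach_femur: np.ndarray  # femur-fixed point [m]
    attach_tibia: np.ndarray  # tibia-fixed (world) point [m]
    stiffness: float  # N/m of elongation in the linear region
    pre_strain: float = 0.0
    toe_strain: float = 0.03
    reference_length: float | None = None  # L_ref at the imaging pose

    def __post_init__(self):
        self.attach_femur = np.asarray(self.attach_femur, dtype=float)
        self.attach_tibia = np.asarray(self.attach_tibia, dtype=float)
        if self.stiffness <= 0:
            raise ValueError(f"ligament {self.name}: stiffness must be positive")
        if self.reference_length is None:
            self.reference_length = float(
                np.linalg.norm(self.attach_femur - self.attach_tibia))
        self.slack_length = self.reference_length / (1.0 + self.pre_strain)
        if self.slack_length <= 0:
            raise ValueError(f"ligament {self.name}: non-positive slack length")


def ligament_force(bundle: LigamentBundleMS, current_length: float) -> float:
    """Tensile force [N] of the slack/toe/linear law at the given length.

    strain e = (L - L0)/L0; force is 0 for e <= 0, the Blankevoort quadratic
    k_eps * e^2 / (4 e_t) for 0 < e <= 2 e_t and linear k_eps * (e - e_t)
    beyond, with k_eps = stiffness * L0 so the linear-region slope in N per
    metre of elongation equals the printed stiffness exactly.
    """
    if current_length <= 0:
        raise ValueError("ligament length must be positive")
    L0 = bundle.slack_length
    eps = (current_length - L0) / L0
    if eps <= 0.0:
        return 0.0
    k_eps = bundle.stiffness * L0  # N per unit strain
    et = bundle.toe_strain
    if et > 0.0 and eps <= 2.0 * et:
        return k_eps * eps * eps / (4.0 * et)
    return k_eps * (eps - et)


def ligament_wrench(bundle: LigamentBundleMS, femur_pose: RigidTransform,
                    about: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Force/moment on the femur from one bundle, moment about ``about``.

    Returns (force, moment, tension)."""
    pf = femur_pose.apply(bundle.attach_femur)
    d = bundle.attach_tibia - pf
    L = float(np.linalg.norm(d))
    t = ligament_force(bundle, L)
    f = t * d / L if L > 0 else np.zeros(3)
    return f, np.cross(pf - about, f), t


# ---------------------------------------------------------------------------
# elastic foundation contact
# ---------------------------------------------------------------------------


@dataclass
class ElasticFoundationContact:
    """Cartilage-cartilage contact: slave surface faces against a master
    surface, pressure = modulus * penetration (nearest-point projection).

    The master moves with the femur (or patella); the slave is tibia-fixed.
    """

    master: SurfaceMesh  # in the moving body's frame
    slave: SurfaceMesh  # world/tibia frame
    pressure_modulus: float = PRESSURE_MODULUS
    label: str = ""

    def wrench(self, master_pose: RigidTransform, about: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Contact force/moment on the *master* body, moment about ``about``.

        Penetration of each slave face centroid is its distance to the master
        surface when inside the master (sign from the master's outward normal
        at the nearest point); pressure acts along the slave face normal.
        """
        normals, areas = self.slave.face_normals_areas
        centroids = self.slave.face_centroids
        mverts = master_pose.apply(self.master.vertices)
        mtris = mverts[self.master.faces]
        mnormals_ref, _ = self.master.face_normals_areas
        mnormals = mnormals_ref @ master_pose.rotation.T

        nearest, dist, tri_idx = closest_point_on_triangles(centroids, mtris)
        # inside the master if the vector to the nearest point opposes the
        # master's outward normal there
        signed = np.einsum("ij,ij->i", centroids - nearest, mnormals[tri_idx])
        penetration = np.where(signed < 0, dist, 0.0)
        pressure = self.pressure_modulus * penetration
        # pressure pushes the master body away, along the slave outward normal
        face_force = (pressure * areas)[:, None] * normals
        force = face_force.sum(axis=0)
        moment = np.cross(centroids - about, face_force).sum(axis=0)
        detail = {"penetration": penetration, "pressure": pressure, "areas": areas}
        return force, moment, detail


def contact_wrench(contact: ElasticFoundationContact, relative_pose: RigidTransform,
                   about: np.ndarray | None = None):
    """Module-level convenience wrapper (wrench on the master body)."""
    about = np.zeros(3) if about is None else np.asarray(about, dtype=float)
    return contact.wrench(relative_pose, about)


# ---------------------------------------------------------------------------
# FDK state and toy knee assembly
# ---------------------------------------------------------------------------


@dataclass
class FDKState:
    """Secondary knee DOFs and residuals.

    tf = (ml, prox, ap translations [m], adduction, internal rotation [rad]);
    flexion is prescribed.  pf likewise for the patella (its flexion comes
    from the rigid-tendon closure).  ``residuals`` has 11 entries: 5 TF,
    5 PF and the PF-flexion component balanced by the tendon tension.
    """

    tf: np.ndarray = field(default_factory=lambda: np.zeros(5))
    pf: np.ndarray = field(default_factory=lambda: np.zeros(5))
    tf_flexion: float = 0.0
    pf_flexion: float = 0.0
    tendon_tension: float = 0.0
    residuals: np.ndarray = field(default_factory=lambda: np.full(11, np.nan))

    def copy(self) -> "FDKState":
        return FDKState(self.tf.copy(), self.pf.copy(), self.tf_flexion,
                        self.pf_flexion, self.tendon_tension, self.residuals.copy())


def _pose_from_dofs(dofs: np.ndarray, flexion: float) -> RigidTransform:
    """Body pose from (ml, prox, ap, adduction, internal) + prescribed flexion.

    Rotation order: flexion (x), adduction (z), internal (y)."""
    R = rot_x(flexion) @ rot_z(dofs[3]) @ rot_y(dofs[4])
    t = np.array([dofs[0], dofs[1], dofs[2]])
    return RigidTransform.fast(R, t)


@dataclass
class KneeAssembly:
    """Desk-scale knee for the FDK solver.

    The tibia is fixed; the femur pose is parametrised by the 5 TF secondary
    DOFs plus prescribed flexion (about the x-axis through the origin).  The
    optional patella hangs off the femur trochlea via its own 5 DOFs, loaded
    by a quadriceps pull and closed by a rigid patellar tendon to the tibial
    tuberosity.
    """

    tf_contacts: list[ElasticFoundationContact]
    ligaments: list[LigamentBundleMS] = field(default_factory=list)
    pf_contacts: list[ElasticFoundationContact] = field(default_factory=list)
    patella_tendon_attach: np.ndarray | None = None  # patella-fixed point
    tibial_tuberosity: np.ndarray | None = None  # world point
    tendon_length: float | None = None
    quadriceps_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quadriceps_point: np.ndarray = field(default_factory=lambda: np.zeros(3))  # patella-fixed
    pf_origin_femur: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def has_patella(self) -> bool:
        return bool(self.pf_contacts) and self.tendon_length is not None

    # -- femur ----------------------------------------------------------------

    def femur_pose(self, tf_dofs: np.ndarray, flexion: float) -> RigidTransform:
        return _pose_from_dofs(tf_dofs, flexion)

    def femur_wrench(self, tf_dofs: np.ndarray, flexion: float,
                     external: np.ndarray) -> np.ndarray:
        """Total (force, moment) on the femur about the TF origin."""
        pose = self.femur_pose(tf_dofs, flexion)
        about = np.zeros(3)
        f_tot = external[:3].copy()
        m_tot = external[3:].copy()
        for c in self.tf_contacts:
            f, m, _ = c.wrench(pose, about)
            f_tot += f
            m_tot += m
        for lig in self.ligaments:
            f, m, _ = ligament_wrench(lig, pose, about)
            f_tot += f
            m_tot += m
        return np.concatenate([f_tot, m_tot])

    # -- patella --------------------------------------------------------------

    def patella_pose(self, pf_dofs: np.ndarray, pf_flexion: float,
                     femur_pose: RigidTransform) -> RigidTransform:
        local = _pose_from_dofs(pf_dofs, pf_flexion)
        base = RigidTransform.fast(femur_pose.rotation,
                                   femur_pose.apply(self.pf_origin_femur))
        return base.compose(local)

    def tendon_gap(self, pf_dofs: np.ndarray, pf_flexion: float,
                   femur_pose: RigidTransform) -> float:
        pose = self.patella_pose(pf_dofs, pf_flexion, femur_pose)
        d = np.linalg.norm(pose.apply(self.patella_tendon_attach) - self.tibial_tuberosity)
        return float(d - self.tendon_length)

    def patella_wrench(self, pf_dofs, pf_flexion, femur_pose,
                       tendon_tension: float) -> np.ndarray:
        """(force, moment) on the patella about the PF origin, including the
        quadriceps pull, PF contact and the tendon tension."""
        pose = self.patella_pose(pf_dofs, pf_flexion, femur_pose)
        about = femur_pose.apply(self.pf_origin_femur)
        fq = self.quadriceps_force
        pq = pose.apply(self.quadriceps_point)
        f_tot = fq.copy()
        m_tot = np.cross(pq - about, fq)
        for c in self.pf_contacts:
            # master = patella surface (patella-fixed), slave = femur-fixed
            # trochlea expressed in world through the femur pose: here the
            # slave meshes are stored pre-posed per call by the caller being
            # the femur at the reference pose; for the toy fixture the femur
            # is near the reference so the stored slave is used directly.
            f, m, _ = c.wrench(pose, about)
            f_tot += f
            m_tot += m
        pt = pose.apply(self.patella_tendon_attach)
        d = self.tibial_tuberosity - pt
        L = np.linalg.norm(d)
        ft = tendon_tension * d / L if L > 0 else np.zeros(3)
        f_tot += ft
        m_tot += np.cross(pt - about, ft)
        return np.concatenate([f_tot, m_tot])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def patellar_tendon_closure(knee: KneeAssembly, pf_dofs: np.ndarray,
                            femur_pose: RigidTransform,
                            bracket: tuple[float, float] = (-1.2, 1.2),
                            hint: float | None = None) -> float:
    """PF flexion angle at which the tendon attains its rigid length.

    Root-finds the tuberosity-to-patella distance (secant from ``hint`` when
    given, bracketed grid + Brent otherwise); raises if the tendon length is
    geometrically unreachable over the bracket.
    """
    f = lambda a: knee.tendon_gap(pf_dofs, a, femur_pose)
    if hint is not None:
        a0, a1 = hint, hint + 1e-4
        f0, f1 = f(a0), f(a1)
        for _ in range(30):
            if abs(f1) < 1e-12:
                return float(a1)
            if f1 == f0:
                break
            a0, a1, f0 = a1, a1 - f1 * (a1 - a0) / (f1 - f0), f1
            if not (bracket[0] - 0.5 <= a1 <= bracket[1] + 0.5):
                break
            f1 = f(a1)
        # fall through to the robust bracketed search
    lo, hi = bracket
    grid = np.linspace(lo, hi, 49)
    vals = np.array([f(a) for a in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("patellar tendon length unreachable: no closure angle in bracket")
    i = sign_change[np.argmin(np.abs(grid[sign_change]))]
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-12))


def _generalized_residual(wrench: np.ndarray, dof_axes: np.ndarray) -> np.ndarray:
    """Project a (force, moment) 6-vector onto generalised DOF directions."""
    return dof_axes @ wrench


# TF DOF directions: unit force along x, y, z; unit moment about z (adduction)
# and y (internal rotation)
_TF_AXES = np.array([
    [1, 0, 0, 0, 0, 0],
    [0, 1, 0, 0, 0, 0],
    [0, 0, 1, 0, 0, 0],
    [0, 0, 0, 0, 0, 1],
    [0, 0, 0, 0, 1, 0],
], dtype=float)


def solve_fdk_frame(knee: KneeAssembly, flexion: float, external: np.ndarray,
                    state0: FDKState | None = None, tolerance: float = FDK_TOLERANCE,
                    max_iter: int = 100, step_limit: tuple[float, float] = (2e-3, np.deg2rad(2.0)),
                    ) -> FDKState:
    """Find the secondary DOFs at which all FDK residual forces vanish.

    Damped Newton with a finite-difference Jacobian over the <= 10 free
    DOFs; steps are clamped to ``step_limit`` (2 mm / 2 deg per iteration).
    On convergence every residual satisfies |r| < tolerance, which the
    caller can re-verify by independent wrench summation.
    """
    state = state0.copy() if state0 is not None else FDKState()
    state.tf_flexion = flexion
    n_tf = 5
    has_pat = knee.has_patella
    n = n_tf + (5 if has_pat else 0)
    x = np.concatenate([state.tf, state.pf]) if has_pat else state.tf.copy()

    def _pf_tension(pf, pf_flex, fp, h=1e-7):
        """Tendon tension balancing the PF-flexion direction (at fixed pf)."""
        about = fp.apply(knee.pf_origin_femur)
        p0 = knee.patella_pose(pf, pf_flex, fp)
        p1 = knee.patella_pose(pf, pf_flex + h, fp)
        omega = _rotation_increment(p0.rotation, p1.rotation) / h
        v_o = (p1.translation - p0.translation) / h
        v_about = v_o + np.cross(omega, about - p0.translation)
        e = np.concatenate([v_about, omega])
        w0 = knee.patella_wrench(pf, pf_flex, fp, 0.0)
        w1 = knee.patella_wrench(pf, pf_flex, fp, 1.0)
        denom = e @ (w1 - w0)
        tension = -(e @ w0) / denom if abs(denom) > 1e-12 else 0.0
        resid = e @ (w0 + tension * (w1 - w0))
        return tension, resid

    flex_hint = [None]

    def residual(xv: np.ndarray):
        tf = xv[:n_tf]
        fp = knee.femur_pose(tf, flexion)
        r_tf = _generalized_residual(knee.femur_wrench(tf, flexion, external), _TF_AXES)
        if not has_pat:
            return r_tf, 0.0, 0.0
        pf = xv[n_tf:]
        pf_flex = patellar_tendon_closure(knee, pf, fp, hint=flex_hint[0])
        flex_hint[0] = pf_flex
        # closure-consistent directions: the rigid tendon does no work along
        # them, so the patella wrench is evaluated without the tendon force
        wp = knee.patella_wrench(pf, pf_flex, fp, 0.0)
        about = fp.apply(knee.pf_origin_femur)
        p0 = knee.patella_pose(pf, pf_flex, fp)
        r_pf = np.empty(5)
        h = 1e-7
        for i in range(5):
            pf_i = pf.copy()
            pf_i[i] += h
            flex_i = patellar_tendon_closure(knee, pf_i, fp, hint=pf_flex)
            p1 = knee.patella_pose(pf_i, flex_i, fp)
            omega = _rotation_increment(p0.rotation, p1.rotation) / h
            v_o = (p1.translation - p0.translation) / h
            v_about = v_o + np.cross(omega, about - p0.translation)
            r_pf[i] = np.concatenate([v_about, omega]) @ wp
        tension, _ = _pf_tension(pf, pf_flex, fp)
        return np.concatenate([r_tf, r_pf]), pf_flex, tension

    def try_residual(xv):
        try:
            return residual(xv)
        except (ValueError, FloatingPointError):
            return None  # e.g. tendon closure unreachable at this trial pose

    r, pf_flex, tension = residual(x)
    for it in range(max_iter):
        if np.all(np.abs(r) < tolerance):
            break
        J = np.empty((len(r), n))
        for j in range(n):
            xp = x.copy()
            h = 1e-7
            xp[j] += h
            trial = try_residual(xp)
            if trial is None:  # backward difference at an infeasible edge
                xp[j] -= 2 * h
                trial = residual(xp)
                h = -h
            J[:, j] = (trial[0] - r) / h
        try:
            dx = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -r, rcond=None)[0]
        # clamp translations / rotations separately
        for j in range(n):
            lim = step_limit[0] if (j % 5) < 3 else step_limit[1]
            dx[j] = np.clip(dx[j], -lim, lim)
        # backtracking on the residual norm; infeasible trials shrink alpha
        alpha = 1.0
        best = None
        rnorm = np.linalg.norm(r)
        for _ in range(10):
            trial = try_residual(x + alpha * dx)
            if trial is not None:
                rt, pf_t, tens_t = trial
                if np.linalg.norm(rt) < rnorm:
                    best = (x + alpha * dx, rt, pf_t, tens_t)
                    break
                if best is None:  # keep one feasible fallback step
                    best = (x + alpha * dx, rt, pf_t, tens_t)
            alpha *= 0.5
        if best is None:
            raise FDKConvergenceError(r, it)
        x, r, pf_flex, tension = best
    else:
        raise FDKConvergenceError(r, max_iter)

    state.tf = x[:n_tf].copy()
    state.pf = x[n_tf:].copy() if has_pat else state.pf
    state.pf_flexion = pf_flex
    state.tendon_tension = tension
    res11 = np.zeros(11)
    res11[:5] = r[:5]
    if has_pat:
        res11[5:10] = r[5:]
        # 11th component: PF-flexion equilibrium carried by the tendon tension
        fp = knee.femur_pose(state.tf, flexion)
        _, res11[10] = _pf_tension(state.pf, pf_flex, fp)
    state.residuals = res11
    return state


def _rotation_increment(R0: np.ndarray, R1: np.ndarray) -> np.ndarray:
    """Small rotation vector taking R0 to R1 (world axes)."""
    W = R1 @ R0.T - np.eye(3)
    return np.array([W[2, 1] - W[1, 2], W[0, 2] - W[2, 0], W[1, 0] - W[0, 1]]) / 2.0
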