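"""Dynamic-equilibrium assembly and muscle recruitment optimisation.

Equilibrium is written segment-wise (6 Newton-Euler rows per segment, forces
in the body frame, moments about the segment mass centre):

    C f = d,    f = [f_M, f_R (, f_FDK)],

where the load vector is d_j = g_j^app - diag(m_j I, J'_j) vdot_j -
[0; ~w'_j J'_j w'_j].  Muscle columns come from the attachment-point forces
of a unit tension along the (polyline) path, which by virtual work equals
the tendon-excursion moment arm; reaction columns from the joint constraint
directions; FDK columns select residual-force directions at the knee.

Recruitment minimises the volume-normalised cubic criterion
G = sum_i v_i (f_i / N_i)^3 subject to C f = d and f_M >= 0 (muscles only
pull; reactions and FDK residuals are free and unpenalised).  A scipy SLSQP
pass finds the active set, then an in-house KKT Newton polish drives the
optimality system to near machine precision, which is what makes the
muscle-subdivision invariance of the volume-normalised criterion hold to
1e-9 in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .kinematics import SegmentKinematics, SegmentModel, PoseTrajectory, skew

GRAVITY = np.array([0.0, 0.0, -9.81])


class InfeasibleEquilibriumError(RuntimeError):
    def __init__(self, residual_rows, message="equilibrium infeasible"):
        super().__init__(f"{message}; worst rows {residual_rows}")
        self.residual_rows = residual_rows


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Muscle:
    """Ideal force generator routed along a polyline of segment-fixed points.

    ``path`` is a list of (segment_name, local_point).  Strength N_i [N] and
    volume v_i [m^3] enter only the recruitment cost.
    """

    name: str
    path: list[tuple[str, np.ndarray]]
    strength: float
    volume: float
    tags: tuple[str, ...] = ()

    def __post_init__(self):
        self.path = [(s, np.asarray(p, dtype=float)) for s, p in self.path]
        if self.strength <= 0 or self.volume <= 0:
            raise ValueError(f"muscle {self.name}: strength and volume must be positive")
        if len(self.path) < 2 or len({s for s, _ in self.path}) < 2:
            raise ValueError(f"muscle {self.name}: path needs >= 2 points on >= 2 segments")


@dataclass
class ExternalLoad:
    """External wrench applied to a segment at a world point (e.g. the GRF
    at the centre of pressure, plus a free moment)."""

    segment: str
    force: np.ndarray
    point: np.ndarray
    moment: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.point = np.asarray(self.point, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)


@dataclass
class ReactionDef:
    """One scalar reaction unknown: a unit force or moment (world direction)
    acting on ``child`` (+) and ``parent`` (-) at the joint centre."""

    joint_segment: str  # child segment name (joint connects it to its parent)
    kind: str  # 'force' | 'moment'
    direction: np.ndarray  # world unit vector


@dataclass
class RecruitmentProblem:
    C: np.ndarray
    d: np.ndarray
    muscles: list[Muscle]
    reactions: list[ReactionDef]
    n_fdk: int = 0

    @property
    def n_m(self) -> int:
        return len(self.muscles)


@dataclass
class RecruitmentSolution:
    f_muscle: np.ndarray
    f_reaction: np.ndarray
    f_fdk: np.ndarray
    objective: float
    kkt_residual: float
    equilibrium_residual: float

    @property
    def f(self) -> np.ndarray:
        return np.concatenate([self.f_muscle, self.f_reaction, self.f_fdk])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_load_vector(model: SegmentModel, kin: SegmentKinematics, frame: int,
                         externals: list[ExternalLoad] = (),
                         gravity: np.ndarray = GRAVITY) -> np.ndarray:
    """Load vector d (applied + gravity - inertia) at one frame.

    Forces in body-fixed coordinates, moments about the segment mass centre.
    """
    names = [s.name for s in model.segments]
    for ext in externals:
        if ext.segment not in names:
            raise ValueError(f"external load targets unknown segment {ext.segment!r}")
    d = np.zeros(6 * len(model.segments))
    poses = kin.poses[frame]
    for j, s in enumerate(model.segments):
        R = poses[s.name].rotation
        com_w = kin.com_world[s.name][frame]
        fb = R.T @ (s.mass * np.asarray(gravity, dtype=float))
        mb = np.zeros(3)
        for ext in externals:
            if ext.segment != s.name:
                continue
            fb += R.T @ ext.force
            mb += R.T @ (np.cross(ext.point - com_w, ext.force) + ext.moment)
        w = kin.omega_body[s.name][frame]
        dw = kin.domega_body[s.name][frame]
        fb -= s.mass * (R.T @ kin.acc_com_world[s.name][frame])
        mb -= s.inertia @ dw + skew(w) @ s.inertia @ w
        d[6 * j: 6 * j + 3] = fb
        d[6 * j + 3: 6 * j + 6] = mb
    return d


def _apply_point_force(model: SegmentModel, poses, kin_com, seg_name: str,
                       point_w: np.ndarray, force_w: np.ndarray, col: np.ndarray,
                       moment_w: np.ndarray | None = None) -> None:
    """Accumulate a world force at a world point on a segment into a C column."""
    j = [s.name for s in model.segments].index(seg_name)
    R = poses[seg_name].rotation
    com_w = kin_com[seg_name]
    col[6 * j: 6 * j + 3] += R.T @ force_w
    m = np.cross(point_w - com_w, force_w)
    if moment_w is not None:
        m = m + moment_w
    col[6 * j + 3: 6 * j + 6] += R.T @ m


def reaction_definitions(model: SegmentModel, poses) -> list[ReactionDef]:
    """Constraint force/moment unknowns implied by the joint types."""
    out = []
    for s in model.segments:
        if s.joint_type == "free":
            continue
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            out.append(ReactionDef(s.name, "force", e))
        if s.joint_type == "revolute":
            axis_w = poses[s.parent].rotation @ s.joint_axis
            axis_w = axis_w / np.linalg.norm(axis_w)
            # two moment directions perpendicular to the hinge axis
            a = np.array([1.0, 0.0, 0.0]) if abs(axis_w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            u = np.cross(axis_w, a)
            u /= np.linalg.norm(u)
            v = np.cross(axis_w, u)
            out.append(ReactionDef(s.name, "moment", u))
            out.append(ReactionDef(s.name, "moment", v))
    return out


def assemble_coefficients(model: SegmentModel, kin: SegmentKinematics, frame: int,
                          muscles: list[Muscle],
                          fdk_columns: np.ndarray | None = None) -> RecruitmentProblem:
    """Coefficient matrix C = [C_M  C_R (C_FDK)] at one frame.

    The columns follow the d'Alembert convention that pairs with the load
    vector d = g_app - M vdot - gyro: each muscle column is +dL/dq (the
    tendon-excursion derivative, i.e. the *negative* of the generalised
    force of a unit tension) and reaction columns are the joint-constraint
    Jacobian rows.  With this pairing the solved f are the physical muscle
    tensions and reaction forces.

    ``fdk_columns`` (n_rows x n_fdk), when given, appends residual-force
    directions for force-dependent-kinematics DOFs.
    """
    poses = kin.poses[frame]
    com_w = {s.name: kin.com_world[s.name][frame] for s in model.segments}
    nrow = 6 * len(model.segments)

    cols = []
    for m in muscles:
        col = np.zeros(nrow)
        pts = [poses[s].apply(p) for s, p in m.path]
        for k in range(len(pts) - 1):
            seg_vec = pts[k + 1] - pts[k]
            ln = np.linalg.norm(seg_vec)
            if ln < 1e-12:
                raise ValueError(f"muscle {m.name}: zero-length path segment {k}")
        for k, (seg_name, _) in enumerate(m.path):
            fdir = np.zeros(3)
            if k > 0:
                u = pts[k - 1] - pts[k]
                fdir += u / np.linalg.norm(u)
            if k < len(pts) - 1:
                u = pts[k + 1] - pts[k]
                fdir += u / np.linalg.norm(u)
            _apply_point_force(model, poses, com_w, seg_name, pts[k], fdir, col)
        cols.append(col)
    C_M = np.column_stack(cols) if cols else np.zeros((nrow, 0))

    rdefs = reaction_definitions(model, poses)
    rcols = []
    for rd in rdefs:
        col = np.zeros(nrow)
        s = model.segment(rd.joint_segment)
        jc_w = poses[s.name].translation  # child frame origin sits at the joint
        if rd.kind == "force":
            _apply_point_force(model, poses, com_w, s.name, jc_w, rd.direction, col)
            _apply_point_force(model, poses, com_w, s.parent, jc_w, -rd.direction, col)
        else:
            _apply_point_force(model, poses, com_w, s.name, jc_w, np.zeros(3), col,
                               moment_w=rd.direction)
            _apply_point_force(model, poses, com_w, s.parent, jc_w, np.zeros(3), col,
                               moment_w=-rd.direction)
        rcols.append(col)
    C_R = np.column_stack(rcols) if rcols else np.zeros((nrow, 0))

    parts = [C_M, C_R]
    n_fdk = 0
    if fdk_columns is not None:
        parts.append(np.asarray(fdk_columns, dtype=float))
        n_fdk = fdk_columns.shape[1]
    # negate: columns are +dL/dq / constraint Jacobians, not generalised
    # forces (see docstring)
    C = -np.hstack(parts)
    d = np.zeros(nrow)  # caller fills via assemble_load_vector
    return RecruitmentProblem(C, d, muscles, rdefs, n_fdk)


def path_length(model: SegmentModel, poses, muscle: Muscle) -> float:
    pts = [poses[s].apply(p) for s, p in muscle.path]
    return float(sum(np.linalg.norm(pts[k + 1] - pts[k]) for k in range(len(pts) - 1)))


# ---------------------------------------------------------------------------
# recruitment solve
# ---------------------------------------------------------------------------


def _grad_G(fm, v, N):
    return 3.0 * v * np.maximum(fm, 0.0) ** 2 / N**3


def _G(fm, v, N):
    return float(np.sum(v * (np.maximum(fm, 0.0) / N) ** 3))


def solve_recruitment(problem: RecruitmentProblem, x0: np.ndarray | None = None,
                      tol: float = 1e-10) -> RecruitmentSolution:
    """Minimise the cubic criterion subject to C f = d, f_M >= 0.

    SLSQP locates the optimum and its active set; a KKT Newton polish then
    refines muscle forces, free forces and multipliers simultaneously.
    """
    C, d = problem.C, problem.d
    n_m = problem.n_m
    n = C.shape[1]
    n_free = n - n_m
    v = np.array([m.volume for m in problem.muscles])
    N = np.array([m.strength for m in problem.muscles])
    scale = max(1.0, float(np.linalg.norm(d)))

    # nondimensionalise: muscle unknowns as activations x = f/N, free
    # unknowns scaled by the load norm, equilibrated rows, O(1) volumes —
    # otherwise the cubic cost gradient (~1e-9 in SI) is invisible next to
    # the O(1) equilibrium block and the flat directions never converge
    col_scale = np.concatenate([N, np.full(n_free, scale)])
    Cs = C * col_scale[None, :]
    row_abs = np.abs(Cs).max(axis=1)
    row_scale = np.maximum(row_abs, 1e-9 * max(row_abs.max(), 1.0))
    Cs = Cs / row_scale[:, None]
    ds = d / row_scale
    vs = v / v.mean() if n_m else v
    Ns = np.ones(n_m)
    s_eq = max(1.0, float(np.linalg.norm(ds)))

    # project the (possibly redundant) equality rows onto the row space so
    # the constraint set is full-rank; the component of ds outside it is the
    # true infeasibility
    U, S, _ = np.linalg.svd(Cs, full_matrices=True)
    rank = int(np.sum(S > 1e-12 * max(S[0], 1.0)))
    Ur = U[:, :rank]
    C_eq = Ur.T @ Cs
    d_eq = Ur.T @ ds
    out_of_range = float(np.linalg.norm(ds - Ur @ d_eq))
    if out_of_range > 1e-6 * s_eq:
        rows = np.argsort(-np.abs(ds - Ur @ d_eq))[:3]
        raise InfeasibleEquilibriumError(rows.tolist())
    Cs, ds = C_eq, d_eq
    s_eq = max(1.0, float(np.linalg.norm(ds)))

    x_ls, *_ = np.linalg.lstsq(Cs, ds, rcond=None)
    x_init = x_ls if x0 is None else np.asarray(x0, dtype=float) / col_scale
    x_init = x_init.copy()
    x_init[:n_m] = np.maximum(x_init[:n_m], 0.0)

    def fun(x):
        return _G(x[:n_m], vs, Ns)

    def jac(x):
        g = np.zeros_like(x)
        g[:n_m] = _grad_G(x[:n_m], vs, Ns)
        return g

    bounds = [(0.0, None)] * n_m + [(None, None)] * n_free
    starts = [x_init]
    if x0 is not None:
        xa = x_ls.copy()
        xa[:n_m] = np.maximum(xa[:n_m], 0.0)
        starts.append(xa)
    starts.append(np.zeros(n))
    best = None
    for xs in starts:
        res = minimize(fun, xs, jac=jac, bounds=bounds, method="SLSQP",
                       constraints=[{"type": "eq", "fun": lambda x: Cs @ x - ds,
                                     "jac": lambda x: Cs}],
                       options={"maxiter": 400, "ftol": 1e-16})
        x = res.x.copy()
        x[:n_m] = np.maximum(x[:n_m], 0.0)
        x, lam = _kkt_polish(Cs, ds, vs, Ns, n_m, x, s_eq)
        eq = np.linalg.norm(Cs @ x - ds)
        kkt = _kkt_residual(Cs, ds, vs, Ns, n_m, x, lam)
        score = max(eq, kkt)
        if best is None or score < best[0]:
            best = (score, x, lam)
        if score < 1e-11 * s_eq:
            break
    _, x, lam = best

    if np.linalg.norm(Cs @ x - ds) > 1e-6 * s_eq:
        rows = np.argsort(-np.abs(Cs @ x - ds))[:3]
        raise InfeasibleEquilibriumError(rows.tolist())

    f = x * col_scale
    fm = f[:n_m]
    kkt = _kkt_residual(Cs, ds, vs, Ns, n_m, x, lam)
    eq = float(np.linalg.norm(C @ f - d))
    return RecruitmentSolution(
        f_muscle=fm,
        f_reaction=f[n_m: n_m + n_free - problem.n_fdk],
        f_fdk=f[n - problem.n_fdk:] if problem.n_fdk else np.zeros(0),
        objective=_G(fm, v, N),
        kkt_residual=kkt,
        equilibrium_residual=eq,
    )


def _kkt_residual(C, d, v, N, n_m, x, lam):
    g = _grad_G(x[:n_m], v, N)
    stat_m = g - C[:, :n_m].T @ lam
    # at active bounds the multiplier absorbs the (nonnegative) stationarity gap
    stat_m = np.where(x[:n_m] > 1e-9 * max(1.0, x[:n_m].max(initial=0.0)),
                      stat_m, np.minimum(stat_m, 0.0))
    stat_f = C[:, n_m:].T @ lam
    feas = C @ x - d
    return float(max(np.abs(stat_m).max(initial=0.0), np.abs(stat_f).max(initial=0.0),
                     np.abs(feas).max(initial=0.0)))


def _kkt_polish(C, d, v, N, n_m, x, scale, max_outer=8, max_newton=40):
    """Active-set Newton refinement of the KKT system."""
    n = C.shape[1]
    fscale = max(1.0, float(np.abs(x[:n_m]).max(initial=0.0)))
    active = x[:n_m] < 1e-7 * fscale
    lam = np.zeros(C.shape[0])
    for _ in range(max_outer):
        inact = ~active
        idx = np.concatenate([np.flatnonzero(inact), np.arange(n_m, n)])
        Ci = C[:, idx]
        ni = len(idx)
        xi = x[idx].copy()

        def F(xi_, lam_):
            f_full = np.zeros(n)
            f_full[idx] = xi_
            r1 = C @ f_full - d
            g = _grad_G(f_full[:n_m], v, N)
            stat = np.concatenate([g[inact], np.zeros(n - n_m)]) - Ci.T @ lam_
            return np.concatenate([r1, stat]), f_full

        ok = True
        for _ in range(max_newton):
            r, f_full = F(xi, lam)
            if np.linalg.norm(r) < 1e-13 * scale:
                break
            H = np.zeros((ni, ni))
            kk = 0
            for i_m in np.flatnonzero(inact):
                H[kk, kk] = 6.0 * v[i_m] * max(f_full[i_m], 0.0) / N[i_m] ** 3
                kk += 1
            J = np.block([[Ci, np.zeros((C.shape[0], C.shape[0]))],
                          [H, -Ci.T]])
            try:
                dx = np.linalg.lstsq(J, -r, rcond=None)[0]
            except np.linalg.LinAlgError:
                ok = False
                break
            xi += dx[:ni]
            lam += dx[ni:]
        if not ok:
            break
        x = np.zeros(n)
        x[idx] = xi
        # active-set updates: release bound muscles with negative multipliers,
        # clamp inactive muscles that went negative
        g = _grad_G(x[:n_m], v, N)
        mu = g - C[:, :n_m].T @ lam  # should be >= 0 on the active set
        changed = False
        for i in range(n_m):
            if active[i] and mu[i] < -1e-10 * max(1.0, np.abs(mu).max()):
                active[i] = False
                changed = True
            elif not active[i] and x[i] < -1e-12 * fscale:
                active[i] = True
                changed = True
        x[:n_m] = np.maximum(x[:n_m], 0.0)
        if not changed:
            break
    return x, lam


# ---------------------------------------------------------------------------
# model editing
# ---------------------------------------------------------------------------


def subdivide_muscle(muscle: Muscle, k: int) -> list[Muscle]:
    """Split into k identical sub-muscles with strength N/k and volume v/k.

    With the volume-normalised cubic criterion this leaves the optimal total
    force, reactions and objective unchanged - the stated purpose of the
    normalisation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return [muscle]
    return [replace(muscle, name=f"{muscle.name}#{i+1}", strength=muscle.strength / k,
                    volume=muscle.volume / k) for i in range(k)]


def scale_group_strength(muscles: list[Muscle], group_tag: str, factor: float) -> list[Muscle]:
    """Multiply the strength of every muscle carrying ``group_tag``."""
    if not 0.0 < factor <= 1.5:
        raise ValueError("factor must be in (0, 1.5]")
    if not any(group_tag in m.tags for m in muscles):
        raise KeyError(f"no muscle carries tag {group_tag!r}")
    return [replace(m, strength=m.strength * factor) if group_tag in m.tags else m
            for m in muscles]


def scale_muscle_parameters(muscles: list[Muscle], subject_mass: float, subject_height: float,
                            fat_fraction: float, reference_mass: float = 75.0,
                            reference_height: float = 1.75, reference_fat: float = 0.2,
                            mass_exponent: float = 2.0 / 3.0, height_exponent: float = 1.0,
                            fat_exponent: float = 1.0) -> list[Muscle]:
    """Length-mass-fat strength scaling.

    strength *= (m/m0)^a * (h/h0)^b * ((1-fat)/(1-fat0))^c with documented,
    configurable exponents (a = 2/3, b = 1, c = 1 by default); volumes scale
    with the lean-mass ratio so the cost normalisation stays consistent.
    """
    if min(subject_mass, subject_height) <= 0 or not 0 <= fat_fraction < 1:
        raise ValueError("inputs must be positive (fat fraction in [0, 1))")
    sf = ((subject_mass / reference_mass) ** mass_exponent
          * (subject_height / reference_height) ** height_exponent
          * ((1 - fat_fraction) / (1 - reference_fat)) ** fat_exponent)
    vf = (subject_mass / reference_mass) * (1 - fat_fraction) / (1 - reference_fat)
    return [replace(m, strength=m.strength * sf, volume=m.volume * vf) for m in muscles]


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------


def joint_reaction_force(problem: RecruitmentProblem, solution: RecruitmentSolution,
                         joint_segment: str) -> np.ndarray:
    """World-frame reaction force acting on ``joint_segment`` at its joint."""
    out = np.zeros(3)
    for rd, f in zip(problem.reactions, solution.f_reaction):
        if rd.joint_segment == joint_segment and rd.kind == "force":
            out += f * rd.direction
    return out
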