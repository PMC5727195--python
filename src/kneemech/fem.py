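"""Small implicit u-p finite-element solver for biphasic soft tissue.

8-node hexahedral porous elements with equal-order trilinear displacement
and pore pressure (an open equivalent of the commercial C3D8P element),
carrying the FRPVE material at 2x2x2 Gauss points.  Geometrically linear
kinematics; backward Euler in time; monolithic Newton.  The non-fibrillar
Gauss tangent is obtained by complex-step differentiation of the
Neo-Hookean stress (machine precision, so the assembled tangent is
consistent with the residual to finite-difference accuracy), the fibril
tangent is analytic, and the strain-dependent permeability is lagged one
step (standard staggered treatment that keeps the within-step tangent
exact).

Units: SI (m, N, Pa, s) at this level; `frpve` works in MPa and is
converted on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import frpve
from .kinematics import skew

MPA = 1e6

# hex8 reference nodes
_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)
_GP = np.array(np.meshgrid(*3 * [[-1 / np.sqrt(3), 1 / np.sqrt(3)]],
                           indexing="ij")).reshape(3, -1).T  # (8, 3)

#: local node ids of the six hex faces (outward when nodes follow _XI order)
HEX_FACES = {
    "xmin": [0, 4, 7, 3], "xmax": [1, 2, 6, 5],
    "ymin": [0, 1, 5, 4], "ymax": [3, 7, 6, 2],
    "zmin": [0, 3, 2, 1], "zmax": [4, 5, 6, 7],
}


def shape_functions(xi):
    s = (1 + _XI[:, 0] * xi[0]) * (1 + _XI[:, 1] * xi[1]) * (1 + _XI[:, 2] * xi[2]) / 8.0
    d = np.empty((8, 3))
    d[:, 0] = _XI[:, 0] * (1 + _XI[:, 1] * xi[1]) * (1 + _XI[:, 2] * xi[2]) / 8.0
    d[:, 1] = _XI[:, 1] * (1 + _XI[:, 0] * xi[0]) * (1 + _XI[:, 2] * xi[2]) / 8.0
    d[:, 2] = _XI[:, 2] * (1 + _XI[:, 0] * xi[0]) * (1 + _XI[:, 1] * xi[1]) / 8.0
    return s, d


# ---------------------------------------------------------------------------
# mesh / state
# ---------------------------------------------------------------------------


@dataclass
class PorousMesh:
    """Hex8 porous mesh with per-node depth/tangent fields and named sets."""

    nodes: np.ndarray  # (N, 3) [m]
    elements: np.ndarray  # (E, 8) int
    material_tags: list[str] | None = None  # per element
    depth: np.ndarray | None = None  # per node, normalised 0 (surface) .. 1 (bone)
    tangent: np.ndarray | None = None  # per node split-line direction
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.material_tags is None:
            self.material_tags = ["tibial cartilage"] * len(self.elements)
        for name, ns in self.node_sets.items():
            ns = np.asarray(ns, dtype=int)
            if ns.size and (ns.min() < 0 or ns.max() >= len(self.nodes)):
                raise ValueError(f"node set {name!r} references invalid nodes")
            self.node_sets[name] = ns
        self._check_jacobians()

    def _check_jacobians(self):
        for e, conn in enumerate(self.elements):
            X = self.nodes[conn]
            for gp in _GP:
                _, dN = shape_functions(gp)
                J = dN.T @ X
                if np.linalg.det(J) <= 0:
                    raise ValueError(f"element {e}: non-positive Jacobian in reference configuration")

    @property
    def n_nodes(self):
        return len(self.nodes)

    def face_nodes(self, face_set: str) -> np.ndarray:
        out = set()
        for e, fname in self.face_sets[face_set]:
            out.update(self.elements[e][HEX_FACES[fname]])
        return np.array(sorted(out), dtype=int)

    def nodal_areas(self, face_set: str) -> dict[int, float]:
        """Tributary area per node of a face set (bilinear lumping)."""
        areas: dict[int, float] = {}
        for e, fname in self.face_sets[face_set]:
            quad = self.elements[e][HEX_FACES[fname]]
            X = self.nodes[quad]
            a = 0.5 * np.linalg.norm(np.cross(X[2] - X[0], X[3] - X[1]))
            for nid in quad:
                areas[nid] = areas.get(nid, 0.0) + a / 4.0
        return areas


@dataclass
class BiphasicState:
    """Nodal displacements/pressures plus per-Gauss-point material state."""

    u: np.ndarray  # (N, 3)
    p: np.ndarray  # (N,)
    time: float = 0.0
    gp_state: list = None  # per element: list of per-gp dicts

    @classmethod
    def zero(cls, mesh: PorousMesh) -> "BiphasicState":
        return cls(np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_nodes), 0.0, None)

    def copy(self) -> "BiphasicState":
        import copy
        return BiphasicState(self.u.copy(), self.p.copy(), self.time,
                             copy.deepcopy(self.gp_state))


@dataclass
class LigamentSpringFE:
    """Linear spring element between a (possibly rigid-body-attached) point
    and a fixed point, with pre-strain setting the initial tension."""

    attach_body: np.ndarray  # point on the moving body [m]
    attach_fixed: np.ndarray  # fixed (tibial) point [m]
    stiffness: float  # N/m
    pre_strain: float = 0.0

    def __post_init__(self):
        self.attach_body = np.asarray(self.attach_body, dtype=float)
        self.attach_fixed = np.asarray(self.attach_fixed, dtype=float)
        L_ref = np.linalg.norm(self.attach_body - self.attach_fixed)
        self.slack_length = L_ref / (1.0 + self.pre_strain)

    def force_on_body(self, body_point: np.ndarray, prestrain_scale: float = 1.0) -> np.ndarray:
        d = self.attach_fixed - body_point
        L = np.linalg.norm(d)
        L0 = np.linalg.norm(self.attach_body - self.attach_fixed) / (
            1.0 + prestrain_scale * self.pre_strain)
        stretch = L - L0
        if stretch <= 0:
            return np.zeros(3)
        return self.stiffness * stretch * d / L


# ---------------------------------------------------------------------------
# Gauss-point material wrapper
# ---------------------------------------------------------------------------

_VOIGT_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


def _voigt_to_tensor(v):
    E = np.empty((3, 3), dtype=v.dtype)
    E[0, 0], E[1, 1], E[2, 2] = v[0], v[1], v[2]
    E[0, 1] = E[1, 0] = 0.5 * v[3]
    E[1, 2] = E[2, 1] = 0.5 * v[4]
    E[0, 2] = E[2, 0] = 0.5 * v[5]
    return E


def _tensor_to_voigt_stress(S):
    return np.array([S[0, 0], S[1, 1], S[2, 2], S[0, 1], S[1, 2], S[0, 2]], dtype=S.dtype)


class GaussMaterial:
    """FRPVE response at one Gauss point (SI stress units)."""

    def __init__(self, mat: frpve.FRPVEMaterial, depth: float = 0.5,
                 tangent_dir=(1.0, 0.0, 0.0), surface_normal=(0.0, 0.0, 1.0),
                 fibrils_enabled: bool = False, seed: int = 7):
        self.mat = mat
        self.depth = float(depth)
        self.e0 = float(mat.void_ratio(depth))
        self.k_lag = mat.k0_si
        self.fibrils_enabled = fibrils_enabled
        if fibrils_enabled:
            self.directions = frpve.build_fibril_architecture(
                np.array([depth]), np.asarray(surface_normal, dtype=float),
                np.asarray(tangent_dir, dtype=float), mat.tissue or "tibial cartilage",
                D=mat.D, seed=seed)
            nfib = self.directions.primary.shape[1] + len(self.directions.secondary)
            self.states = [frpve.FibrilState() for _ in range(nfib)]
        else:
            self.directions, self.states = None, []

    def stress(self, eps_voigt, dt):
        """Effective stress (Pa, voigt) and trial fibril states."""
        E = _voigt_to_tensor(np.asarray(eps_voigt))
        F = np.eye(3, dtype=E.dtype) + E
        sig = frpve.nonfibrillar_stress(F, self.mat) * MPA
        trial = self.states
        if self.fibrils_enabled:
            sf, trial = frpve.total_fibrillar_stress(self.directions, np.real(E),
                                                     self.states, dt, self.mat,
                                                     commit=True)
            sig = sig + sf * MPA
        return _tensor_to_voigt_stress(sig), trial

    def tangent(self, eps_voigt, dt, h: float = 1e-30):
        """Consistent 6x6 d(sigma)/d(eps) (Pa): complex step on the matrix
        part, analytic fibril contribution."""
        D = np.empty((6, 6))
        base = np.asarray(eps_voigt, dtype=complex)
        for j in range(6):
            pert = base.copy()
            pert[j] += 1j * h
            E = _voigt_to_tensor(pert)
            F = np.eye(3, dtype=complex) + E
            sig = frpve.nonfibrillar_stress(F, self.mat) * MPA
            D[:, j] = np.imag(_tensor_to_voigt_stress(sig)) / h
        if self.fibrils_enabled:
            E = _voigt_to_tensor(np.real(np.asarray(eps_voigt)))
            prim = self.directions.primary[0]
            dirs = np.vstack([prim, self.directions.secondary])
            weights = np.concatenate([
                np.full(len(prim), self.directions.primary_weight),
                np.full(len(self.directions.secondary), self.directions.secondary_weight)])
            for n_vec, w, st in zip(dirs, weights, self.states):
                eps_n = float(n_vec @ E @ n_vec)
                dsig = frpve.fibril_tangent(st, eps_n, dt, self.mat) * MPA
                if dsig == 0.0:
                    continue
                g = np.array([n_vec[0]**2, n_vec[1]**2, n_vec[2]**2,
                              n_vec[0] * n_vec[1], n_vec[1] * n_vec[2], n_vec[0] * n_vec[2]])
                D += w * dsig * np.outer(g, g)
        return D

    def permeability(self) -> float:
        return self.k_lag

    def commit(self, eps_voigt, trial_states):
        if self.fibrils_enabled:
            self.states = trial_states
        tr = float(np.real(eps_voigt[0] + eps_voigt[1] + eps_voigt[2]))
        e = self.e0 + (1.0 + self.e0) * tr
        self.k_lag = float(frpve.permeability(max(e, -0.99), self.e0, self.mat))


# ---------------------------------------------------------------------------
# rigid surfaces, contact and indenter
# ---------------------------------------------------------------------------


@dataclass
class RigidSphere:
    """Analytic rigid sphere; gap is positive outside the sphere."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    def gap_normal(self, x, center_offset=np.zeros(3)):
        c = self.center + center_offset
        d = x - c
        r = np.linalg.norm(d)
        n = d / r if r > 0 else np.array([0.0, 0.0, 1.0])
        return r - self.radius, n


@dataclass
class RigidPlane:
    """Analytic rigid half-space; gap positive on the +normal side."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal /= np.linalg.norm(self.normal)

    def gap_normal(self, x, center_offset=np.zeros(3)):
        return float((x - self.point - center_offset) @ self.normal), self.normal


@dataclass
class RigidContact:
    """Frictionless node-to-rigid-surface penalty contact.

    The pressure-overclosure law is linear with a quadratic blend over the
    first ``smoothing`` metres of overclosure, which keeps the Newton
    tangent continuous at gap = 0 (suppresses active-set chatter)."""

    surface: object  # RigidSphere | RigidPlane
    slave_nodes: np.ndarray
    slave_areas: np.ndarray  # tributary area per slave node
    penalty: float = 1e12  # Pa/m
    smoothing: float = 2e-5  # m

    def __post_init__(self):
        self.slave_nodes = np.asarray(self.slave_nodes, dtype=int)
        self.slave_areas = np.asarray(self.slave_areas, dtype=float)

    def pressure_and_stiffness(self, overclosure: float) -> tuple[float, float]:
        """(pressure, d pressure/d overclosure) of the regularised law."""
        g0 = self.smoothing
        if overclosure <= 0:
            return 0.0, 0.0
        if overclosure < g0:
            return self.penalty * overclosure**2 / (2 * g0), self.penalty * overclosure / g0
        return self.penalty * (overclosure - g0 / 2), self.penalty


@dataclass
class RigidIndenter:
    """Force/moment-driven rigid body carrying contact surfaces.

    6 unknown DOFs per analysis (translation + small rotation about the
    reference point); contacts reference its surfaces; ligament springs may
    attach to it.
    """

    reference_point: np.ndarray
    contacts: list[RigidContact] = field(default_factory=list)
    ligaments: list[LigamentSpringFE] = field(default_factory=list)
    prescribed: dict[int, float] = field(default_factory=dict)  # dof -> value
    #: rotational restraint [N m/rad] standing in for the capsule and soft
    #: tissue; keeps the frictionless-contact rotation modes regular and the
    #: equilibrium tilt within a few degrees
    rotational_stiffness: float = 50.0
    #: tiny translational stabilisation [N/m] so free rigid-body rows stay
    #: regular when contact momentarily opens; forces are negligible
    #: (sub-newton at millimetre motion)
    translational_stiffness: float = 200.0

    def __post_init__(self):
        self.reference_point = np.asarray(self.reference_point, dtype=float)

    def point_motion(self, x0, dofs):
        """Displacement of a body point under (t, theta) small motion."""
        t, th = dofs[:3], dofs[3:]
        return t + np.cross(th, x0 - self.reference_point)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


class BiphasicFEM:
    """Assembled u-p problem on one mesh with optional rigid indenter."""

    def __init__(self, mesh: PorousMesh, materials: dict[str, GaussMaterial] | None = None,
                 material_factory=None, fibrils_enabled: bool = False, seed: int = 7):
        self.mesh = mesh
        self.ndof_u = 3 * mesh.n_nodes
        self.ndof = self.ndof_u + mesh.n_nodes
        self.dirichlet: dict[int, float] = {}
        self.external_force = np.zeros(self.ndof)
        self.indenter: RigidIndenter | None = None
        self.contacts: list[RigidContact] = []  # contacts on fixed rigid surfaces
        self.prestrain_scale = 1.0

        # precompute element geometry
        self._elem_dN = []  # (E, 8gp, 8node, 3)
        self._elem_w = []  # detJ * gauss weight
        self._elem_N = []
        for conn in mesh.elements:
            X = mesh.nodes[conn]
            dNs, ws, Ns = [], [], []
            for gp in _GP:
                N, dN = shape_functions(gp)
                J = dN.T @ X
                dNdx = dN @ np.linalg.inv(J)
                dNs.append(dNdx)
                ws.append(np.linalg.det(J))  # gauss weights are 1
                Ns.append(N)
            self._elem_dN.append(np.array(dNs))
            self._elem_w.append(np.array(ws))
            self._elem_N.append(np.array(Ns))

        # per-element per-gp materials
        self.gp_materials: list[list[GaussMaterial]] = []
        for e, conn in enumerate(mesh.elements):
            tag = mesh.material_tags[e]
            mats = []
            for g, gp in enumerate(_GP):
                if material_factory is not None:
                    gm = material_factory(e, g)
                else:
                    depth = 0.5
                    if mesh.depth is not None:
                        depth = float(self._elem_N[e][g] @ mesh.depth[conn])
                    tan = (1.0, 0.0, 0.0)
                    if mesh.tangent is not None:
                        tv = self._elem_N[e][g] @ mesh.tangent[conn]
                        tan = tuple(tv)
                    gm = GaussMaterial(frpve.FRPVEMaterial.from_preset(tag), depth,
                                       tangent_dir=tan, fibrils_enabled=fibrils_enabled,
                                       seed=seed)
                mats.append(gm)
            self.gp_materials.append(mats)

    # -- boundary conditions -------------------------------------------------

    def fix_nodes(self, nodes, components=(0, 1, 2), value: float = 0.0):
        for n in np.atleast_1d(nodes):
            for c in components:
                self.dirichlet[3 * int(n) + c] = value

    def prescribe_pressure(self, nodes, value: float = 0.0):
        for n in np.atleast_1d(nodes):
            self.dirichlet[self.ndof_u + int(n)] = value

    def apply_face_traction(self, face_set: str, traction: np.ndarray):
        """Consistent nodal loads of a uniform traction on a face set."""
        areas = self.mesh.nodal_areas(face_set)
        t = np.asarray(traction, dtype=float)
        for nid, a in areas.items():
            self.external_force[3 * nid: 3 * nid + 3] += a * t

    # -- residual and tangent -------------------------------------------------

    def _element_rt(self, e, u, p, u_prev, dt, want_tangent=True):
        conn = self.mesh.elements[e]
        ue, pe = u[conn], p[conn]
        ue_prev = u_prev[conn]
        r_u = np.zeros((8, 3))
        r_p = np.zeros(8)
        K_uu = np.zeros((24, 24)) if want_tangent else None
        K_up = np.zeros((24, 8)) if want_tangent else None
        K_pu = np.zeros((8, 24)) if want_tangent else None
        K_pp = np.zeros((8, 8)) if want_tangent else None
        trial_states = []
        eps_store = []
        for g in range(8):
            dN = self._elem_dN[e][g]
            N = self._elem_N[e][g]
            w = self._elem_w[e][g]
            grad = ue.T @ dN  # (3, 3) du_i/dx_j
            grad_prev = ue_prev.T @ dN
            E = 0.5 * (grad + grad.T)
            eps = np.array([E[0, 0], E[1, 1], E[2, 2], 2 * E[0, 1], 2 * E[1, 2], 2 * E[0, 2]])
            gm = self.gp_materials[e][g]
            sig, trial = gm.stress(eps, dt)
            trial_states.append(trial)
            eps_store.append(eps)
            pg = float(N @ pe)
            gradp = dN.T @ pe
            k = gm.permeability()

            B = np.zeros((6, 24))
            for a in range(8):
                bx, by, bz = dN[a]
                B[0, 3 * a] = bx
                B[1, 3 * a + 1] = by
                B[2, 3 * a + 2] = bz
                B[3, 3 * a], B[3, 3 * a + 1] = by, bx
                B[4, 3 * a + 1], B[4, 3 * a + 2] = bz, by
                B[5, 3 * a], B[5, 3 * a + 2] = bz, bx
            m = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])

            r_u += w * (B.T @ (sig - pg * m)).reshape(8, 3)
            dv = np.trace(grad) - np.trace(grad_prev)
            r_p += w * (N * dv / dt + dN @ (k * gradp))

            if want_tangent:
                D = gm.tangent(eps, dt)
                K_uu += w * (B.T @ D @ B)
                K_up += -w * np.outer(B.T @ m, N)
                K_pu += w * np.outer(N, m @ B) / dt
                K_pp += w * k * (dN @ dN.T)
        return r_u, r_p, K_uu, K_up, K_pu, K_pp, trial_states, eps_store

    def assemble(self, state: BiphasicState, state_prev: BiphasicState, dt: float,
                 want_tangent: bool = True):
        """Global residual and (sparse) tangent at the current iterate."""
        mesh = self.mesh
        R = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        trial_all = []
        eps_all = []
        for e in range(len(mesh.elements)):
            conn = mesh.elements[e]
            r_u, r_p, K_uu, K_up, K_pu, K_pp, trial, eps_s = self._element_rt(
                e, state.u, state.p, state_prev.u, dt, want_tangent)
            trial_all.append(trial)
            eps_all.append(eps_s)
            udofs = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in conn])
            pdofs = self.ndof_u + conn
            R[udofs] += r_u.ravel()
            R[pdofs] += r_p
            if want_tangent:
                for K, rd, cd in ((K_uu, udofs, udofs), (K_up, udofs, pdofs),
                                  (K_pu, pdofs, udofs), (K_pp, pdofs, pdofs)):
                    rr, cc = np.meshgrid(rd, cd, indexing="ij")
                    rows.append(rr.ravel())
                    cols.append(cc.ravel())
                    vals.append(K.ravel())
        R -= self.external_force
        K = None
        if want_tangent:
            K = sp.csr_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(self.ndof, self.ndof))
        return R, K, trial_all, eps_all

    # -- contact contributions (nodal, analytic tangent blocks) ---------------

    def _contact_contrib(self, contact: RigidContact, u, indenter_dofs=None,
                         indenter: RigidIndenter | None = None):
        """Per-node contact force (on the mesh) and data for tangents."""
        out = []
        for nid, area in zip(contact.slave_nodes, contact.slave_areas):
            x = self.mesh.nodes[nid] + u[nid]
            off = np.zeros(3)
            if indenter is not None and indenter_dofs is not None:
                anchor = (contact.surface.center if isinstance(contact.surface, RigidSphere)
                          else contact.surface.point)
                off = indenter.point_motion(anchor, indenter_dofs)
            g, n = contact.surface.gap_normal(x, off)
            if g >= 0:
                continue
            pres, dpres = contact.pressure_and_stiffness(-g)
            f = pres * area * n  # pushes the node outward
            out.append((nid, area, g, n, f, dpres))
        return out


# ---------------------------------------------------------------------------
# reference-point coupling
# ---------------------------------------------------------------------------


def apply_reference_point_coupling(fem: BiphasicFEM, reference_point: np.ndarray,
                                   coupled_nodes: np.ndarray) -> dict:
    """Rigidly couple a node set to a 6-DOF reference point.

    Returns the constraint description consumed by :func:`solve_step`:
    coupled u-dofs are eliminated, u_node = t + theta x r (small rotation).
    """
    coupled_nodes = np.asarray(coupled_nodes, dtype=int)
    if coupled_nodes.size == 0:
        raise ValueError("reference-point coupling needs a non-empty node set")
    return {"reference_point": np.asarray(reference_point, dtype=float),
            "nodes": coupled_nodes}


def _build_transform(fem: BiphasicFEM, couplings: list[dict]):
    """Map full dofs -> reduced unknowns [plain dofs, 6 per coupling,
    6 indenter dofs]; Dirichlet dofs are eliminated with their values."""
    ndof = fem.ndof
    coupled_udof = {}
    for ci, c in enumerate(couplings):
        for n in c["nodes"]:
            for k in range(3):
                coupled_udof[3 * n + k] = (ci, n, k)
    plain = [i for i in range(ndof) if i not in fem.dirichlet and i not in coupled_udof]
    nred = len(plain) + 6 * len(couplings) + (6 if fem.indenter is not None else 0)
    col_of_plain = {d: i for i, d in enumerate(plain)}
    c0 = len(plain)
    rows, cols, vals = [], [], []
    fixed = np.zeros(ndof)
    for d, v in fem.dirichlet.items():
        fixed[d] = v
    for d in plain:
        rows.append(d)
        cols.append(col_of_plain[d])
        vals.append(1.0)
    for d, (ci, n, k) in coupled_udof.items():
        r = fem.mesh.nodes[n] - couplings[ci]["reference_point"]
        # u_k = t_k + (theta x r)_k
        rows.append(d)
        cols.append(c0 + 6 * ci + k)
        vals.append(1.0)
        eps = np.zeros((3, 3, 3))
        eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1
        eps[0, 2, 1] = eps[2, 1, 0] = eps[1, 0, 2] = -1
        for j in range(3):
            coef = sum(eps[k, j, l] * r[l] for l in range(3))
            if coef != 0.0:
                rows.append(d)
                cols.append(c0 + 6 * ci + 3 + j)
                vals.append(coef)
    T = sp.csr_matrix((vals, (rows, cols)), shape=(ndof, nred))
    ind_col0 = c0 + 6 * len(couplings) if fem.indenter is not None else None
    # per-reduced-dof kind for step limiting: 0 displacement [m],
    # 1 pressure [Pa], 2 rotation [rad]
    kind = np.zeros(nred, dtype=int)
    for i, d in enumerate(plain):
        kind[i] = 0 if d < fem.ndof_u else 1
    for ci in range(len(couplings)):
        kind[c0 + 6 * ci + 3: c0 + 6 * ci + 6] = 2
    if fem.indenter is not None:
        kind[ind_col0 + 3: ind_col0 + 6] = 2
    return T, fixed, col_of_plain, c0, ind_col0, kind


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------


class NewtonError(RuntimeError):
    pass


def solve_step_adaptive(fem: "BiphasicFEM", state: BiphasicState, dt: float,
                        couplings=(), depth: int = 0, **kw) -> BiphasicState:
    """solve_step with recursive step bisection on Newton failure."""
    try:
        return solve_step(fem, state, dt, couplings, **kw)
    except (NewtonError, ValueError):
        if depth >= 3:
            raise
        mid = solve_step_adaptive(fem, state, dt / 2, couplings, depth + 1, **kw)
        return solve_step_adaptive(fem, mid, dt / 2, couplings, depth + 1, **kw)


def solve_step(fem: BiphasicFEM, state: BiphasicState, dt: float,
               couplings: list[dict] = (), coupling_wrench: dict[int, np.ndarray] | None = None,
               indenter_wrench: np.ndarray | None = None,
               rtol: float = 1e-6, atol: float = 1e-8, max_iter: int = 60) -> BiphasicState:
    """Advance one backward-Euler step with monolithic Newton.

    ``coupling_wrench`` maps coupling index -> applied (force, moment)
    6-vector at its reference point; ``indenter_wrench`` likewise for the
    rigid indenter.  Gauss-point states and the lagged permeability commit
    on convergence only.
    """
    couplings = list(couplings)
    T, fixed, _, c0, ind_col0, dof_kind = _build_transform(fem, couplings)
    nred = T.shape[1]
    new = state.copy()
    new.time = state.time + dt
    x_full = np.concatenate([new.u.ravel(), new.p])
    # reduced iterate consistent with the current state; indenter columns of
    # T are empty (no mesh dof maps to them), so regularise their diagonal
    # and seed them from the previous step's converged rigid-body dofs
    TtT = (T.T @ T).tocsc()
    diag = TtT.diagonal()
    empty = np.flatnonzero(diag == 0)
    if len(empty):
        TtT = (TtT + sp.csr_matrix((np.ones(len(empty)), (empty, empty)),
                                   shape=TtT.shape)).tocsc()
    y = spla.spsolve(TtT, T.T @ (x_full - fixed))
    ind_dofs = np.zeros(6)
    if fem.indenter is not None:
        y[ind_col0: ind_col0 + 6] = getattr(state, "indenter_dofs", np.zeros(6))
        ind_dofs = y[ind_col0: ind_col0 + 6].copy()

    last = None
    nrm0 = None
    dy_prev = None
    for it in range(max_iter):
        x_full = T @ y + fixed
        u = x_full[: fem.ndof_u].reshape(-1, 3)
        p = x_full[fem.ndof_u:]
        try:
            R, K, trial_all, eps_all = fem.assemble(
                BiphasicState(u, p, new.time, new.gp_state), state, dt)
        except ValueError:
            # inverted element at an overshot iterate: backtrack half-way
            if dy_prev is None:
                raise
            y = y - 0.5 * dy_prev
            dy_prev = 0.5 * dy_prev
            if fem.indenter is not None:
                ind_dofs = y[ind_col0: ind_col0 + 6]
            continue

        # contact on fixed rigid surfaces and on the indenter
        C_rows, C_cols, C_vals = [], [], []
        R_ind = np.zeros(6)
        if indenter_wrench is not None:
            R_ind -= indenter_wrench
        for contact, on_ind in ([(c, False) for c in fem.contacts]
                                + ([(c, True) for c in fem.indenter.contacts]
                                   if fem.indenter is not None else [])):
            entries = fem._contact_contrib(contact, u,
                                           ind_dofs if on_ind else None,
                                           fem.indenter if on_ind else None)
            for nid, area, g, n, f, dpres in entries:
                R[3 * nid: 3 * nid + 3] -= f
                kblk = dpres * area * np.outer(n, n)
                for a in range(3):
                    for b in range(3):
                        C_rows.append(3 * nid + a)
                        C_cols.append(3 * nid + b)
                        C_vals.append(kblk[a, b])
                if on_ind:
                    # reaction on the indenter: -f at the node position
                    R_ind[:3] += f  # equilibrium: applied - contact reaction
                    x = fem.mesh.nodes[nid] + u[nid]
                    R_ind[3:] += np.cross(x - fem.indenter.reference_point, f)
        if fem.indenter is not None:
            for lig in fem.indenter.ligaments:
                bp = lig.attach_body + fem.indenter.point_motion(lig.attach_body, ind_dofs)
                fl = lig.force_on_body(bp, fem.prestrain_scale)
                R_ind[:3] -= fl
                R_ind[3:] -= np.cross(lig.attach_body - fem.indenter.reference_point, fl)
            R_ind[3:] += fem.indenter.rotational_stiffness * ind_dofs[3:]
            R_ind[:3] += fem.indenter.translational_stiffness * ind_dofs[:3]

        K = K + sp.csr_matrix((C_vals, (C_rows, C_cols)), shape=(fem.ndof, fem.ndof)) \
            if C_vals else K

        R_red = np.asarray(T.T @ R).ravel()
        if fem.indenter is not None:
            R_red[ind_col0: ind_col0 + 6] += R_ind
        K_red = (T.T @ K @ T).tolil()
        if fem.indenter is not None:
            K_red = _indenter_tangent(fem, K_red, T, u, ind_dofs, ind_col0, dt,
                                      state, new, couplings, coupling_wrench,
                                      indenter_wrench, y)
        if coupling_wrench:
            for ci, w in coupling_wrench.items():
                R_red[c0 + 6 * ci: c0 + 6 * ci + 6] -= np.asarray(w, dtype=float)
        if fem.indenter is not None:
            for dof, val in fem.indenter.prescribed.items():
                r = ind_col0 + dof
                K_red[r, :] = 0.0
                K_red[r, r] = 1.0
                R_red[r] = y[r] - val

        # row/column equilibration: displacement, pressure and indenter rows
        # live on wildly different scales (mm-size domains put the Darcy
        # block ~1e-16 against an elastic block ~1e1), so the raw system is
        # numerically singular for the direct solver without scaling
        Kc = K_red.tocsr()
        row_max = np.maximum.reduceat(np.abs(Kc.data), Kc.indptr[:-1],
                                      ) if Kc.nnz else np.ones(Kc.shape[0])
        row_max = np.where((np.diff(Kc.indptr) > 0) & (row_max > 0), row_max, 1.0)
        dr = 1.0 / row_max
        K1 = sp.diags(dr) @ Kc
        K1c = K1.tocsc()
        col_max = np.zeros(K1c.shape[1])
        for j in range(K1c.shape[1]):
            sl = slice(K1c.indptr[j], K1c.indptr[j + 1])
            col_max[j] = np.abs(K1c.data[sl]).max() if sl.stop > sl.start else 1.0
        dc = 1.0 / np.where(col_max > 0, col_max, 1.0)
        K2 = K1c @ sp.diags(dc)

        nrm = np.linalg.norm(dr * R_red)
        if nrm0 is None:
            nrm0 = max(nrm, 1e-30)
            best_nrm = nrm
            no_improve = 0
        if nrm < 0.9 * best_nrm:
            best_nrm = nrm
            no_improve = 0
        else:
            no_improve += 1
        # accept on tolerance, or when the iteration has stalled at a level
        # already far below the step's driving residual (linear-solver floor
        # / contact- and fibril-kink chatter at negligible amplitude)
        # the equilibrated norm is a Newton-correction size (metres for
        # displacement rows, pascals for pressure rows), so ``atol`` is an
        # absolute physical convergence floor
        stalled = no_improve >= 5 and it > 10 and nrm < max(1e-4 * nrm0, atol)
        if nrm < max(rtol * nrm0, 1e-13) or stalled:
            new.u, new.p = u, p
            new.gp_state = None
            for e, mats in enumerate(fem.gp_materials):
                for g, gm in enumerate(mats):
                    gm.commit(eps_all[e][g], trial_all[e][g])
            if fem.indenter is not None:
                new.indenter_dofs = ind_dofs.copy()
            return new
        if last is not None and nrm > 1e4 * max(last, nrm0) and it > 6:
            raise NewtonError(f"Newton diverging at iteration {it}: |R| = {nrm:.3e}")
        last = nrm
        dy = dc * spla.spsolve(K2.tocsc(), -(dr * R_red))
        # limit displacement/rotation increments (penalty contact can
        # overshoot violently when the active set is wrong); pressures are
        # left free — they live on a Pa scale
        caps = np.where(dof_kind == 0, 5e-4, np.where(dof_kind == 2, 0.05, np.inf))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = caps / np.abs(dy)
        factor = min(1.0, np.nanmin(np.where(np.abs(dy) > 0, ratios, np.inf)))
        dy = dy * factor
        y = y + dy
        dy_prev = dy
        if fem.indenter is not None:
            ind_dofs = y[ind_col0: ind_col0 + 6]
    raise NewtonError(f"Newton did not converge in {max_iter} iterations (|R| = {nrm:.3e})")


def _indenter_tangent(fem, K_red, T, u, ind_dofs, ind_col0, dt, state, new,
                      couplings, coupling_wrench, indenter_wrench, y):
    """Finite-difference rows/cols coupling the 6 indenter DOFs to the
    contact residuals (cheap: contact-only re-evaluation)."""
    def contact_residual(ind_d):
        R = np.zeros(fem.ndof)
        R_ind = np.zeros(6)
        if indenter_wrench is not None:
            R_ind -= indenter_wrench
        for contact in fem.indenter.contacts:
            for nid, area, g, n, f, dpres in fem._contact_contrib(contact, u, ind_d, fem.indenter):
                R[3 * nid: 3 * nid + 3] -= f
                R_ind[:3] += f
                x = fem.mesh.nodes[nid] + u[nid]
                R_ind[3:] += np.cross(x - fem.indenter.reference_point, f)
        for lig in fem.indenter.ligaments:
            bp = lig.attach_body + fem.indenter.point_motion(lig.attach_body, ind_d)
            fl = lig.force_on_body(bp, fem.prestrain_scale)
            R_ind[:3] -= fl
            R_ind[3:] -= np.cross(lig.attach_body - fem.indenter.reference_point, fl)
        R_ind[3:] += fem.indenter.rotational_stiffness * ind_d[3:]
        R_ind[:3] += fem.indenter.translational_stiffness * ind_d[:3]
        return np.concatenate([np.asarray(T.T @ R).ravel(), R_ind])

    base = contact_residual(ind_dofs)
    h = 1e-7
    nred = K_red.shape[0]
    for j in range(6):
        d = ind_dofs.copy()
        d[j] += h
        col = (contact_residual(d) - base) / h
        mesh_part = col[:nred]
        nz = np.nonzero(mesh_part)[0]
        for r in nz:
            if ind_col0 <= r < ind_col0 + 6:
                continue
            K_red[r, ind_col0 + j] += mesh_part[r]
            # contact/ligament penalty energy is symmetric, so the indenter
            # rows' dependence on mesh dofs is the transpose of this block
            K_red[ind_col0 + j, r] += mesh_part[r]
        for r in range(6):
            K_red[ind_col0 + r, ind_col0 + j] += col[nred + r]
    return K_red


# ---------------------------------------------------------------------------
# load protocol / stance simulation
# ---------------------------------------------------------------------------


@dataclass
class LoadProtocol:
    """Staged loading: (1) approach + ligament pre-strain, (2) initial stance
    loads, (3) stance sweep of the equivalent load series."""

    approach_displacement: float = 1e-4  # m, stage-1 axial approach
    approach_steps: int = 4
    initial_steps: int = 4
    stance_steps: int = 50
    stance_duration: float = 0.65  # s


@dataclass
class FrameResult:
    time: float
    pct_stance: float
    u: np.ndarray
    p: np.ndarray
    contact_pressure: dict[int, float]  # node -> Pa
    indenter_dofs: np.ndarray | None = None


def nodal_contact_pressures(fem: BiphasicFEM, u: np.ndarray,
                            ind_dofs=None) -> dict[int, float]:
    out: dict[int, float] = {}
    all_contacts = list(fem.contacts)
    if fem.indenter is not None:
        all_contacts += fem.indenter.contacts
    for contact in all_contacts:
        on_ind = fem.indenter is not None and any(
            contact is c for c in fem.indenter.contacts)
        entries = fem._contact_contrib(contact, u, ind_dofs if on_ind else None,
                                       fem.indenter if on_ind else None)
        for nid, area, g, n, f, dpres in entries:
            out[int(nid)] = out.get(int(nid), 0.0) + float(np.linalg.norm(f)) / area
    return out


def run_stance_simulation(fem: BiphasicFEM, load_series, protocol: LoadProtocol,
                          couplings: list[dict] = ()) -> list[FrameResult]:
    """Execute the staged stance protocol on a prepared FE fixture.

    ``load_series`` provides femoral wrenches over stance (an
    EquivalentLoadSeries or a callable pct -> 6-vector).  Results carry the
    tibial-surface contact pressures per output frame.
    """
    state = BiphasicState.zero(fem.mesh)
    history: list[FrameResult] = []

    def wrench_at(pct):
        if callable(load_series):
            return np.asarray(load_series(pct), dtype=float)
        return load_series.wrench_at_pct(pct)

    # stage 1: approach (axial, dof 2) with ramped pre-strain, no loads.
    # Indenter rotations stay prescribed throughout: the desk-scale fixture
    # carries applied moments through the prescribed-rotation constraint
    # (the frictionless sphere-on-slab rotational equilibrium is nearly
    # indeterminate and is not the quantity of interest here).
    dt0 = 1e-3
    base_prescribed = dict(fem.indenter.prescribed) if fem.indenter is not None else {}
    rot_lock = {3: 0.0, 4: 0.0, 5: 0.0, **base_prescribed}
    for i in range(protocol.approach_steps):
        fem.prestrain_scale = (i + 1) / protocol.approach_steps
        if fem.indenter is not None:
            fem.indenter.prescribed = {**rot_lock,
                                       2: -(i + 1) / protocol.approach_steps
                                       * protocol.approach_displacement}
        state = solve_step_adaptive(fem, state, dt0, couplings,
                                    indenter_wrench=np.zeros(6))
    if fem.indenter is not None:
        fem.indenter.prescribed = dict(rot_lock)

    # stage 2: ramp on the initial stance wrench
    w0 = wrench_at(0.0)
    for i in range(protocol.initial_steps):
        f = (i + 1) / protocol.initial_steps
        state = solve_step_adaptive(fem, state, dt0, couplings, indenter_wrench=f * w0)

    # stage 3: stance sweep
    dt = protocol.stance_duration / protocol.stance_steps
    for i in range(protocol.stance_steps + 1):
        pct = 100.0 * i / protocol.stance_steps
        w = wrench_at(pct)
        state = solve_step_adaptive(fem, state, dt if i else dt0, couplings,
                                    indenter_wrench=w)
        ind = getattr(state, "indenter_dofs", None)
        cp = nodal_contact_pressures(fem, state.u, ind)
        history.append(FrameResult(state.time, pct, state.u.copy(), state.p.copy(), cp,
                                   None if ind is None else ind.copy()))
    return history


# ---------------------------------------------------------------------------
# postprocessing
# ---------------------------------------------------------------------------


def postprocess(history: list[FrameResult], mesh: PorousMesh,
                surface_set: str = "articular", medial_set: str = "medial_base",
                lateral_set: str = "lateral_base",
                pressure_threshold: float = 0.01 * MPA) -> dict:
    """Surface summaries per frame.

    Contact area counts surface nodes with pressure exceeding the threshold
    (0.01 MPa by default), area-weighted by tributary areas; peak/mean are
    over contacting nodes; medial/lateral axial reactions are summed contact
    loads over the respective node-set columns.
    """
    areas = {}
    if surface_set in mesh.face_sets:
        areas = mesh.nodal_areas(surface_set)
    med = set(mesh.node_sets.get(medial_set, np.array([], dtype=int)).tolist())
    lat = set(mesh.node_sets.get(lateral_set, np.array([], dtype=int)).tolist())
    out = {"time": [], "pct_stance": [], "peak_pressure": [], "mean_pressure": [],
           "contact_area": [], "medial_force": [], "lateral_force": [], "no_contact": []}
    for fr in history:
        ps = {n: p for n, p in fr.contact_pressure.items()}
        vals = np.array(list(ps.values())) if ps else np.array([])
        contacting = vals[vals > 0]
        out["time"].append(fr.time)
        out["pct_stance"].append(fr.pct_stance)
        out["no_contact"].append(len(contacting) == 0)
        out["peak_pressure"].append(float(contacting.max()) if len(contacting) else 0.0)
        out["mean_pressure"].append(float(contacting.mean()) if len(contacting) else 0.0)
        area = sum(areas.get(n, 0.0) for n, p in ps.items() if p > pressure_threshold)
        out["contact_area"].append(area)
        fm = sum(p * areas.get(n, 0.0) for n, p in ps.items() if _col(n) in med)
        fl = sum(p * areas.get(n, 0.0) for n, p in ps.items() if _col(n) in lat)
        out["medial_force"].append(fm)
        out["lateral_force"].append(fl)
    return out


_COLUMN_OF: dict[int, int] = {}


def set_column_map(mapping: dict[int, int]):
    """Register surface-node -> base-node column mapping for medial/lateral
    reaction splits (columns run through the slab thickness)."""
    global _COLUMN_OF
    _COLUMN_OF = dict(mapping)


def _col(n: int) -> int:
    return _COLUMN_OF.get(int(n), int(n))
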