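"""Synthetic fixtures with known ground truth for every pipeline stage.

* a parametric 3-D leg (pelvis, thigh, shank, foot) with redundant
  uni-/bi-articular muscles, used for IK, recruitment and the strength
  sweep;
* a gait-like stance trial whose ground reaction wrench is derived from the
  prescribed motion itself (left-null-space closure of the equilibrium
  system), so inverse dynamics is exactly feasible with no residual hacks;
* a desk-scale toy knee (spherical femoral condyles on tibial plateau
  meshes, four ligament bundles, optional patella) for the FDK solver;
* hex-meshed cartilage slabs: a confined-compression column for the
  poroelastic benchmarks and a two-compartment simplified knee for the
  stance FE run;
* corresponded surface-mesh pairs for the morphing round-trips.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from . import fdk, fem
from .geometry import SurfaceMesh
from .kinematics import (MarkerRecord, PoseTrajectory, Segment, SegmentModel,
                         SegmentKinematics, differentiate, segment_kinematics)
from .recruitment import (ExternalLoad, Muscle, assemble_coefficients,
                          assemble_load_vector)

GRAVITY = np.array([0.0, 0.0, -9.81])


# ---------------------------------------------------------------------------
# parametric leg
# ---------------------------------------------------------------------------

THIGH_LEN = 0.41
SHANK_LEN = 0.42


def build_leg_model(body_mass: float = 61.2) -> tuple[SegmentModel, list[Muscle]]:
    """Generic right leg: free pelvis, spherical hip, revolute knee/ankle.

    Geometry is planar in the sagittal (x-z) plane — a single-leg model has
    no contralateral support, so in-plane consistency requires the hip under
    the pelvis mass centre — but the formulation is fully three-dimensional.
    Muscle redundancy includes uniarticular (vasti, soleus, tibialis
    anterior, gluteus, iliopsoas) and biarticular (rectus femoris,
    hamstrings, gastrocnemius) paths so recruitment trade-offs exist.
    """
    m_th, m_sh, m_ft = 0.123 * body_mass, 0.057 * body_mass, 0.016 * body_mass
    m_pe = body_mass - m_th - m_sh - m_ft
    segs = [
        Segment("pelvis", None, "free", mass=m_pe, com=np.zeros(3),
                inertia=np.diag([1.2, 1.1, 0.9])),
        Segment("thigh", "pelvis", "spherical", joint_center_parent=[0, 0, -0.08],
                mass=m_th, com=[0, 0, -0.18],
                inertia=np.diag([0.13, 0.13, 0.025])),
        Segment("shank", "thigh", "revolute", joint_center_parent=[0, 0, -THIGH_LEN],
                joint_axis=[0, 1, 0], mass=m_sh, com=[0, 0, -0.18],
                inertia=np.diag([0.05, 0.05, 0.006])),
        Segment("foot", "shank", "revolute", joint_center_parent=[0, 0, -SHANK_LEN],
                joint_axis=[0, 1, 0], mass=m_ft, com=[0.06, 0, -0.04],
                inertia=np.diag([0.004, 0.004, 0.002])),
    ]
    markers = {
        "PEL1": ("pelvis", np.array([0.10, 0.10, 0.05])),
        "PEL2": ("pelvis", np.array([0.10, -0.10, 0.05])),
        "PEL3": ("pelvis", np.array([-0.10, 0.00, 0.06])),
        "PEL4": ("pelvis", np.array([0.00, 0.00, 0.12])),
        "THI1": ("thigh", np.array([0.05, 0.05, -0.10])),
        "THI2": ("thigh", np.array([0.05, -0.05, -0.20])),
        "THI3": ("thigh", np.array([-0.05, 0.03, -0.30])),
        "THI4": ("thigh", np.array([0.02, 0.06, -0.38])),
        "SHA1": ("shank", np.array([0.04, 0.04, -0.10])),
        "SHA2": ("shank", np.array([0.04, -0.04, -0.22])),
        "SHA3": ("shank", np.array([-0.04, 0.02, -0.32])),
        "SHA4": ("shank", np.array([0.02, 0.05, -0.40])),
        "FOO1": ("foot", np.array([0.15, 0.03, -0.04])),
        "FOO2": ("foot", np.array([0.15, -0.03, -0.04])),
        "FOO3": ("foot", np.array([-0.04, 0.00, -0.02])),
        "FOO4": ("foot", np.array([0.02, 0.05, 0.00])),
    }
    model = SegmentModel(segs, markers)

    heel = np.array([-0.05, 0.0, -0.05])
    muscles = [
        Muscle("iliopsoas", [("pelvis", [0.05, 0, 0.0]), ("thigh", [0.03, 0, -0.10])],
               strength=1500, volume=2.5e-4, tags=("hip-flexor",)),
        Muscle("gluteus", [("pelvis", [-0.08, 0, 0.02]), ("thigh", [-0.03, 0, -0.10])],
               strength=2200, volume=6.0e-4, tags=("hip-extensor",)),
        Muscle("vasti", [("thigh", [0.035, 0, -0.15]), ("thigh", [0.05, 0, -0.38]),
                         ("shank", [0.045, 0, -0.07])],
               strength=4000, volume=1.2e-3, tags=("knee-extensor",)),
        Muscle("rectus_femoris", [("pelvis", [0.045, 0, -0.02]),
                                  ("thigh", [0.05, 0, -0.38]),
                                  ("shank", [0.045, 0, -0.07])],
               strength=1200, volume=3.0e-4, tags=("knee-extensor", "hip-flexor")),
        Muscle("hamstrings", [("pelvis", [-0.07, 0, 0.0]), ("shank", [-0.035, 0, -0.05])],
               strength=2500, volume=7.0e-4, tags=("knee-flexor", "hip-extensor")),
        Muscle("gastrocnemius", [("thigh", [-0.025, 0, -0.38]), ("foot", heel)],
               strength=1800, volume=4.0e-4, tags=("knee-flexor", "plantarflexor")),
        Muscle("soleus", [("shank", [-0.025, 0, -0.15]), ("foot", heel)],
               strength=3500, volume=5.0e-4, tags=("plantarflexor",)),
        Muscle("tibialis_anterior", [("shank", [0.03, 0, -0.20]),
                                     ("foot", [0.08, 0, -0.03])],
               strength=1300, volume=1.5e-4, tags=("dorsiflexor",)),
    ]
    return model, muscles


# ---------------------------------------------------------------------------
# gait trial
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGaitSpec:
    """Study conditions of the synthetic stance trial.

    Defaults mirror the recorded subject: 0.65 s stance, 61.2 kg body mass,
    vertical GRF peaks near 20 % and 80 % of stance.
    """

    stance_duration: float = 0.65
    sample_rate: float = 100.0
    body_mass: float = 61.2
    marker_noise: float = 0.0  # m, isotropic
    grf_peak_fraction: float = 0.25  # two-peak amplitude relative to BW
    peak_times: tuple[float, float] = (0.20, 0.80)  # fraction of stance
    seed: int = 0


@dataclass
class GaitTrial:
    """Synthetic trial: record, ground truth and per-frame external loads."""

    spec: SyntheticGaitSpec
    model: SegmentModel
    muscles: list[Muscle]
    record: MarkerRecord
    truth: PoseTrajectory
    kin: SegmentKinematics
    grf: pd.DataFrame
    externals: list[list[ExternalLoad]]

    @property
    def n_frames(self) -> int:
        return len(self.truth.time)


def _smoothstep(s):
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3 - 2 * s)


def _gait_waveforms(s: np.ndarray) -> np.ndarray:
    """Joint-angle waveforms over normalised stance s in [0, 1]:
    hip (about +y, extension positive), knee flexion, ankle angle [rad].

    Shaped so the stance shows the usual loading-response knee flexion wave
    and a pronounced push-off (knee flexion + plantarflexion) near 80-90 %
    of stance, where the second axial force peak falls."""
    hip = -0.22 + 0.37 * _smoothstep(s)
    knee = 0.08 + 0.04 * np.exp(-((s - 0.20) / 0.15) ** 2) \
        + 0.28 * np.exp(-((s - 0.92) / 0.18) ** 2)
    ankle = -0.03 + 0.04 * np.exp(-((s - 0.45) / 0.25) ** 2) \
        - 0.38 * np.exp(-((s - 0.92) / 0.15) ** 2)
    return np.stack([hip, knee, ankle], axis=1)


def external_load_columns(model: SegmentModel, kin: SegmentKinematics, frame: int,
                          segment: str) -> np.ndarray:
    """Map a world wrench (force, moment about the origin) applied to
    ``segment`` into load-vector space: d = d0 + B @ w."""
    j = [s.name for s in model.segments].index(segment)
    R = kin.poses[frame][segment].rotation
    com = kin.com_world[segment][frame]
    B = np.zeros((6 * len(model.segments), 6))
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        B[6 * j: 6 * j + 3, k] = R.T @ e
        B[6 * j + 3: 6 * j + 6, k] = R.T @ np.cross(-com, e)
        B[6 * j + 3: 6 * j + 6, 3 + k] = R.T @ e
    return B


def generate_gait_record(spec: SyntheticGaitSpec | None = None,
                         model: SegmentModel | None = None,
                         muscles: list[Muscle] | None = None) -> GaitTrial:
    """Forward-kinematics markers plus a dynamically consistent GRF.

    The motion is prescribed (pelvis trajectory shaped so the vertical GRF
    shows the two stance peaks); the foot wrench is then solved per frame
    from the left null space of the equilibrium coefficient matrix, so
    C f = d is exactly feasible for the recruitment stage.
    """
    spec = spec or SyntheticGaitSpec()
    if model is None or muscles is None:
        model, muscles = build_leg_model(spec.body_mass)
    rng = np.random.default_rng(spec.seed)
    T = spec.stance_duration
    n = int(round(T * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    s = t / T

    # pelvis vertical motion from the target two-peak vertical GRF
    g = 9.81
    p1, p2 = spec.peak_times
    bump = (np.exp(-((s - p1) / 0.08) ** 2) + np.exp(-((s - p2) / 0.08) ** 2))
    bump -= np.trapezoid(bump, s)  # zero-mean acceleration over stance
    az = spec.grf_peak_fraction * g * bump
    vz = np.concatenate([[0.0], np.cumsum(0.5 * (az[1:] + az[:-1]) * np.diff(t))])
    z = 0.955 + np.concatenate([[0.0], np.cumsum(0.5 * (vz[1:] + vz[:-1]) * np.diff(t))])
    x = 0.25 * T * (s + 0.2 * np.sin(np.pi * s)) * 0.8

    ang = _gait_waveforms(s)
    q = np.zeros((n, model.nq))
    q[:, 0] = x
    q[:, 2] = z
    q[:, 7] = ang[:, 0]  # hip about y (middle XYZ-Euler angle)
    q[:, 9] = ang[:, 1]  # knee flexion
    q[:, 10] = ang[:, 2]  # ankle

    truth = differentiate(PoseTrajectory(t, q))
    kin = segment_kinematics(model, truth)

    externals: list[list[ExternalLoad]] = []
    rows = []
    for f in range(n):
        prob = assemble_coefficients(model, kin, f, muscles)
        d0 = assemble_load_vector(model, kin, f, externals=[], gravity=GRAVITY)
        B = external_load_columns(model, kin, f, "foot")
        U, S, Vt = np.linalg.svd(prob.C)
        rank = int(np.sum(S > 1e-10 * S[0]))
        Nl = U[:, rank:]
        # the null space can exceed 6 dims (unspanned out-of-plane joint
        # torques); those directions carry zero demand for the planar motion,
        # so the 6-dof foot wrench solves the system in the least-squares
        # sense exactly
        w, res, *_ = np.linalg.lstsq(Nl.T @ B, -Nl.T @ d0, rcond=None)
        closure = np.linalg.norm(Nl.T @ (d0 + B @ w))
        if closure > 1e-8 * max(1.0, np.linalg.norm(d0)):
            raise RuntimeError(f"frame {f}: generated motion is not dynamically"
                               f" consistent (closure {closure:.2e})")
        F, M = w[:3], w[3:]
        if abs(F[2]) > 1e-9:
            px, py = -M[1] / F[2], M[0] / F[2]
        else:
            px = py = 0.0
        mz = M[2] - (px * F[1] - py * F[0])
        cop = np.array([px, py, 0.0])
        free = np.array([0.0, 0.0, mz])
        externals.append([ExternalLoad("foot", F, cop, free)])
        rows.append([t[f], *F, *free, *cop])
    grf = pd.DataFrame(rows, columns=["time", "fx", "fy", "fz",
                                      "mx", "my", "mz", "copx", "copy", "copz"])

    names = list(model.markers)
    pos = np.stack([model.marker_positions(q[f], names) for f in range(n)])
    if spec.marker_noise > 0:
        pos = pos + rng.normal(scale=spec.marker_noise, size=pos.shape)
    record = MarkerRecord(names, pos, spec.sample_rate, grf=grf)
    return GaitTrial(spec, model, muscles, record, truth, kin, grf, externals)


# ---------------------------------------------------------------------------
# toy knee (FDK)
# ---------------------------------------------------------------------------

#: printed ligament stiffnesses [N/m] and pre-strains
LIGAMENT_TABLE = {
    "ACL": (306e3, 0.03), "PCL": (406e3, 0.03),
    "MCL": (168e3, 0.02), "LCL": (99e3, 0.03),
    "MPFL": (49e3, 0.05), "LPFL": (68e3, 0.05),
}
PATELLAR_TENDON_STIFFNESS = 545e3  # N/m (FE stage spring)


@dataclass
class FixtureKnee:
    """Desk-scale stand-in for the segmented knee.

    Spherical femoral condyles over a pair of plateau meshes, four
    tibiofemoral ligament bundles, optional patellar block against a
    trochlea plate.  ``params`` records every dimension used.
    """

    params: dict
    tibial_surfaces: list[SurfaceMesh]  # [medial, lateral] plateau meshes
    condyle_meshes: list[SurfaceMesh]  # femur-frame icospheres
    condyle_centers: np.ndarray  # (2, 3) femur frame
    condyle_radius: float
    ligaments: list[fdk.LigamentBundleMS]
    trochlea_surface: SurfaceMesh | None = None
    patella_mesh: SurfaceMesh | None = None


def _plate_mesh(x0, x1, z0, z1, nx=8, nz=8, y=0.0, label="plate",
                dish_center=None, dish_radius=None) -> SurfaceMesh:
    """Rectangular grid in the y = const plane with outward normal +y.

    With ``dish_center`` (x, z) and ``dish_radius`` the plate becomes a
    shallow concave spherical dish (lowest point at the centre), giving the
    contact lateral stiffness like a conforming tibial plateau."""
    xs = np.linspace(x0, x1, nx + 1)
    zs = np.linspace(z0, z1, nz + 1)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    Y = np.full(X.size, float(y))
    if dish_center is not None and dish_radius is not None:
        rho2 = (X.ravel() - dish_center[0]) ** 2 + (Z.ravel() - dish_center[1]) ** 2
        rho2 = np.minimum(rho2, 0.98 * dish_radius**2)
        Y = y + dish_radius - np.sqrt(dish_radius**2 - rho2)
    verts = np.stack([X.ravel(), Y, Z.ravel()], axis=1)
    faces = []
    for i in range(nx):
        for j in range(nz):
            a = i * (nz + 1) + j
            b = (i + 1) * (nz + 1) + j
            # winding chosen so normals point along +y
            faces.append([a, b + 1, b])
            faces.append([a, a + 1, b + 1])
    return SurfaceMesh(verts, np.array(faces), label)


def generate_fixture_knee(condyle_radius: float = 0.035, condyle_offset: float = 0.025,
                          plateau_halfwidth: float = 0.035, plateau_gap: float = 0.004,
                          plateau_depth: float = 0.06, clearance: float = 0.0,
                          n_grid: int = 10, symmetric_ligaments: bool = False,
                          with_patella: bool = False, icosphere_subdiv: int = 2) -> FixtureKnee:
    """Build the toy knee geometry (knee frame: x ML, y proximal, z anterior)."""
    r, cx = condyle_radius, condyle_offset
    centers = np.array([[cx, r + clearance, 0.0], [-cx, r + clearance, 0.0]])
    spheres = []
    for c in centers:
        tm = trimesh.creation.icosphere(subdivisions=icosphere_subdiv, radius=r)
        spheres.append(SurfaceMesh(np.asarray(tm.vertices) + c, np.asarray(tm.faces),
                                   "condyle"))
    dish_r = 2.0 * r  # conforming but not congruent plateau dish
    plates = [
        _plate_mesh(plateau_gap / 2, plateau_gap / 2 + 2 * plateau_halfwidth,
                    -plateau_depth / 2, plateau_depth / 2, n_grid, n_grid,
                    label="medial plateau", dish_center=(cx, 0.0), dish_radius=dish_r),
        _plate_mesh(-plateau_gap / 2 - 2 * plateau_halfwidth, -plateau_gap / 2,
                    -plateau_depth / 2, plateau_depth / 2, n_grid, n_grid,
                    label="lateral plateau", dish_center=(-cx, 0.0), dish_radius=dish_r),
    ]
    k_mcl, e_mcl = LIGAMENT_TABLE["MCL"]
    k_lcl, e_lcl = LIGAMENT_TABLE["LCL"]
    k_acl, e_acl = LIGAMENT_TABLE["ACL"]
    k_pcl, e_pcl = LIGAMENT_TABLE["PCL"]
    if symmetric_ligaments:
        # mirror-symmetric collaterals and cruciates for the symmetry checks
        k_mcl = k_lcl = 0.5 * (k_mcl + k_lcl)
        e_mcl = e_lcl = 0.5 * (e_mcl + e_lcl)
        k_acl = k_pcl = 0.5 * (k_acl + k_pcl)
        e_acl = e_pcl = 0.5 * (e_acl + e_pcl)
    lx = cx + r + 0.01
    ligs = [
        fdk.LigamentBundleMS("MCL", [lx, 0.03, 0.0], [lx, -0.03, 0.0], k_mcl, e_mcl),
        fdk.LigamentBundleMS("LCL", [-lx, 0.03, 0.0], [-lx, -0.03, 0.0], k_lcl, e_lcl),
        fdk.LigamentBundleMS("ACL", [0.0, 0.04, -0.015], [0.0, -0.01, 0.025], k_acl, e_acl),
        fdk.LigamentBundleMS("PCL", [0.0, 0.04, 0.015], [0.0, -0.01, -0.025], k_pcl, e_pcl),
    ]
    params = dict(condyle_radius=r, condyle_offset=cx, plateau_halfwidth=plateau_halfwidth,
                  plateau_gap=plateau_gap, plateau_depth=plateau_depth,
                  clearance=clearance, symmetric_ligaments=symmetric_ligaments,
                  with_patella=with_patella)
    troch = pat = None
    if with_patella:
        # trochlea: plate facing anterior (+z), fixed at the reference femur pose
        troch = _plate_mesh(-0.02, 0.02, -0.02, 0.02, 6, 6, y=0.0, label="trochlea")
        v = troch.vertices.copy()
        # rotate the +y-normal plate to face +z and place it anteriorly
        v = v[:, [0, 2, 1]]
        v[:, 2] += 0.0435  # slight initial engagement with the patellar facet
        v[:, 1] += 0.015
        troch = SurfaceMesh(v, troch.faces[:, ::-1], "trochlea")
        tm = trimesh.creation.box(extents=[0.03, 0.03, 0.008])
        pat = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "patella")
    return FixtureKnee(params, plates, spheres, centers, r, ligs, troch, pat)


def toy_knee_assembly(fixture: FixtureKnee, quadriceps_force: float = 600.0,
                      pressure_modulus: float = fdk.PRESSURE_MODULUS) -> fdk.KneeAssembly:
    """Wire a FixtureKnee into an FDK KneeAssembly."""
    tf_contacts = [
        fdk.ElasticFoundationContact(fixture.condyle_meshes[0], fixture.tibial_surfaces[0],
                                     pressure_modulus, "medial"),
        fdk.ElasticFoundationContact(fixture.condyle_meshes[1], fixture.tibial_surfaces[1],
                                     pressure_modulus, "lateral"),
    ]
    knee = fdk.KneeAssembly(tf_contacts=tf_contacts, ligaments=list(fixture.ligaments))
    if fixture.params["with_patella"]:
        knee.pf_contacts = [fdk.ElasticFoundationContact(
            fixture.patella_mesh, fixture.trochlea_surface,
            pressure_modulus, "patellofemoral")]
        knee.pf_origin_femur = np.array([0.0, 0.015, 0.046])
        knee.patella_tendon_attach = np.array([0.0, -0.018, 0.0])
        knee.tibial_tuberosity = np.array([0.0, -0.045, 0.043])
        knee.quadriceps_point = np.array([0.0, 0.015, 0.0])
        knee.quadriceps_force = np.array([0.0, quadriceps_force, -0.25 * quadriceps_force])
        # rigid tendon length taken at the reference configuration
        ref = knee.patella_pose(np.zeros(5), 0.0, fdk._pose_from_dofs(np.zeros(5), 0.0))
        knee.tendon_length = float(np.linalg.norm(
            ref.apply(knee.patella_tendon_attach) - knee.tibial_tuberosity))
    return knee


# ---------------------------------------------------------------------------
# hex meshes for the FE stage
# ---------------------------------------------------------------------------


def box_hex_mesh(nx: int, ny: int, nz: int, lx: float, ly: float, lz: float,
                 origin=(0.0, 0.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
    """Structured hex grid: returns (nodes, elements)."""
    ox, oy, oz = origin
    xs = np.linspace(ox, ox + lx, nx + 1)
    ys = np.linspace(oy, oy + ly, ny + 1)
    zs = np.linspace(oz, oz + lz, nz + 1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    nodes = np.array([[xs[i], ys[j], zs[k]]
                      for i in range(nx + 1) for j in range(ny + 1)
                      for k in range(nz + 1)])
    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append([nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                              nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    return nodes, np.array(elems)


def confined_compression_column(n_elem: int = 16, height: float = 2e-3,
                                width: float = 1e-3, grading: float = 1.0,
                                tissue: str = "tibial cartilage") -> fem.PorousMesh:
    """1 x 1 x n column for the consolidation benchmarks (z = thickness,
    top z = height is the drained, loaded articular surface).

    ``grading`` > 1 grades the element heights geometrically, finest at the
    drained top, to resolve the early consolidation front."""
    nodes, elems = box_hex_mesh(1, 1, n_elem, width, width, height)
    if grading != 1.0:
        # remap uniform z levels to geometric spacing, finest at z = height
        spacing = grading ** (n_elem - 1 - np.arange(n_elem))
        spacing = spacing / spacing.sum()
        zl = np.concatenate([[0.0], np.cumsum(spacing)]) * height
        uniform_levels = np.linspace(0.0, height, n_elem + 1)
        for i, zu in enumerate(uniform_levels):
            nodes[np.isclose(nodes[:, 2], zu), 2] = zl[i]
    depth = 1.0 - nodes[:, 2] / height  # 0 at the (top) articular surface
    mesh = fem.PorousMesh(nodes, elems, [tissue] * len(elems), depth=depth)
    zt, zb = nodes[:, 2].max(), nodes[:, 2].min()
    mesh.node_sets["top"] = np.nonzero(np.isclose(nodes[:, 2], zt))[0]
    mesh.node_sets["bottom"] = np.nonzero(np.isclose(nodes[:, 2], zb))[0]
    mesh.face_sets["top"] = [(len(elems) - 1, "zmax")]
    mesh.face_sets["bottom"] = [(0, "zmin")]
    return mesh


def confined_compression_fem(mesh: fem.PorousMesh, fibrils: bool = False,
                             drained_top: bool = True) -> fem.BiphasicFEM:
    """Column with lateral rollers, fixed base, optional drained top."""
    model = fem.BiphasicFEM(mesh, fibrils_enabled=fibrils)
    nodes = mesh.nodes
    model.fix_nodes(mesh.node_sets["bottom"], components=(2,))
    for c, ax in ((0, 0), (1, 1)):
        lo, hi = nodes[:, ax].min(), nodes[:, ax].max()
        side = np.nonzero(np.isclose(nodes[:, ax], lo) | np.isclose(nodes[:, ax], hi))[0]
        model.fix_nodes(side, components=(c,))
    if drained_top:
        model.prescribe_pressure(mesh.node_sets["top"], 0.0)
    return model


@dataclass
class SimplifiedKneeFE:
    """Two-compartment FE fixture: slab pair, rigid condyle indenter,
    ligament springs, node/face sets for postprocessing."""

    mesh: fem.PorousMesh
    model: fem.BiphasicFEM
    indenter: fem.RigidIndenter
    column_map: dict[int, int]
    params: dict


def simplified_knee_fe(nx: int = 5, nz: int = 5, n_through: int = 2,
                       halfwidth: float = 0.018, depth: float = 0.030,
                       thickness: float = 3e-3, gap: float = 0.006,
                       condyle_radius: float = 0.035, fibrils: bool = False,
                       penalty: float = 5e10, seed: int = 7) -> SimplifiedKneeFE:
    """Build the simplified-knee FE model (z up = knee axial direction).

    Medial (+x) and lateral (-x) tibial cartilage slabs are fixed at their
    base (cartilage-bone interface); rigid spherical femoral condyles on a
    force-driven indenter body press down; linear ligament springs with the
    printed stiffnesses stabilise the remaining rigid-body modes.
    """
    slabs = []
    offs = [gap / 2, -gap / 2 - 2 * halfwidth]
    all_nodes, all_elems, tags = [], [], []
    n0 = 0
    sets: dict[str, list] = {"medial_base": [], "lateral_base": [],
                             "medial_top": [], "lateral_top": []}
    faces = {"articular": []}
    for side, ox in zip(("medial", "lateral"), offs):
        nodes, elems = box_hex_mesh(nx, nz, n_through, 2 * halfwidth, depth, thickness,
                                    origin=(ox, -depth / 2, -thickness))
        e0 = len(all_elems)
        all_nodes.append(nodes)
        all_elems.extend((elems + n0).tolist())
        tags.extend(["tibial cartilage"] * len(elems))
        top = np.nonzero(np.isclose(nodes[:, 2], 0.0))[0] + n0
        base = np.nonzero(np.isclose(nodes[:, 2], -thickness))[0] + n0
        sets[f"{side}_top"] = top
        sets[f"{side}_base"] = base
        for e in range(len(elems)):
            if (e % n_through) == n_through - 1:
                faces["articular"].append((e0 + e, "zmax"))
        n0 += len(nodes)
    nodes = np.vstack(all_nodes)
    elems = np.array(all_elems)
    depth_field = -nodes[:, 2] / thickness  # 0 at articular surface, 1 at bone
    mesh = fem.PorousMesh(nodes, elems, tags, depth=depth_field,
                          node_sets={k: np.asarray(v, dtype=int) for k, v in sets.items()},
                          face_sets=faces)

    # surface node -> base node column map (same x-y grid position)
    column_map = {}
    for side in ("medial", "lateral"):
        for nt in mesh.node_sets[f"{side}_top"]:
            xy = nodes[nt, :2]
            base = mesh.node_sets[f"{side}_base"]
            nb = base[np.argmin(np.linalg.norm(nodes[base, :2] - xy, axis=1))]
            column_map[int(nt)] = int(nb)
    fem.set_column_map(column_map)

    model = fem.BiphasicFEM(mesh, fibrils_enabled=fibrils, seed=seed)
    model.fix_nodes(np.concatenate([mesh.node_sets["medial_base"],
                                    mesh.node_sets["lateral_base"]]))
    model.prescribe_pressure(np.concatenate([mesh.node_sets["medial_top"],
                                             mesh.node_sets["lateral_top"]]), 0.0)

    areas = mesh.nodal_areas("articular")
    cx = gap / 2 + halfwidth
    ref = np.array([0.0, 0.0, condyle_radius])
    contacts = []
    for side, sx in (("medial", 1.0), ("lateral", -1.0)):
        top = mesh.node_sets[f"{side}_top"]
        sph = fem.RigidSphere([sx * cx, 0.0, condyle_radius], condyle_radius)
        contacts.append(fem.RigidContact(sph, top,
                                         np.array([areas.get(int(n), 0.0) for n in top]),
                                         penalty))
    lx = cx + condyle_radius
    # collaterals nearly vertical (mild compressive preload), cruciates
    # nearly horizontal and crossed (AP stiffness, preloads cancelling)
    ligs = [
        fem.LigamentSpringFE([lx, 0.0, 0.02], [lx, 0.0, -0.02],
                             LIGAMENT_TABLE["MCL"][0], LIGAMENT_TABLE["MCL"][1]),
        fem.LigamentSpringFE([-lx, 0.0, 0.02], [-lx, 0.0, -0.02],
                             LIGAMENT_TABLE["LCL"][0], LIGAMENT_TABLE["LCL"][1]),
        fem.LigamentSpringFE([0.0, 0.028, 0.012], [0.0, -0.028, 0.008],
                             LIGAMENT_TABLE["ACL"][0], LIGAMENT_TABLE["ACL"][1]),
        fem.LigamentSpringFE([0.0, -0.028, 0.012], [0.0, 0.028, 0.008],
                             LIGAMENT_TABLE["PCL"][0], LIGAMENT_TABLE["PCL"][1]),
    ]
    indenter = fem.RigidIndenter(ref, contacts, ligs)
    model.indenter = indenter
    params = dict(nx=nx, nz=nz, n_through=n_through, halfwidth=halfwidth, depth=depth,
                  thickness=thickness, gap=gap, condyle_radius=condyle_radius,
                  penalty=penalty)
    return SimplifiedKneeFE(mesh, model, indenter, column_map, params)


# ---------------------------------------------------------------------------
# morphing pairs
# ---------------------------------------------------------------------------


def generate_morph_pair(kind: str = "affine", seed: int = 0, amplitude: float = 0.1,
                        subdivisions: int = 2) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Corresponded mesh pair under a known smooth deformation.

    kind: 'identity', 'affine' (random well-conditioned affine), 'rigid'
    (random rotation + translation), 'scale' (uniform 1.1x), or 'bump'
    (smooth Gaussian bump along the surface normal direction).
    """
    rng = np.random.default_rng(seed)
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=0.05)
    src = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "source")
    V = src.vertices
    if kind == "identity":
        tgt = V.copy()
    elif kind == "affine":
        A = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        while abs(np.linalg.det(A)) < 0.3:
            A = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        tgt = V @ A.T + rng.standard_normal(3) * 0.02
    elif kind == "rigid":
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        tgt = V @ R.T + rng.standard_normal(3) * 0.03
    elif kind == "scale":
        tgt = 1.1 * V
    elif kind == "bump":
        center = V[int(rng.integers(len(V)))]
        r = np.linalg.norm(V - center, axis=1)
        disp = amplitude * 0.05 * np.exp(-(r / 0.03) ** 2)
        nrm = V / np.linalg.norm(V, axis=1, keepdims=True)
        tgt = V + disp[:, None] * nrm
    else:
        raise ValueError(f"unknown deformation kind {kind!r}")
    return src, SurfaceMesh(tgt, src.faces.copy(), "target")
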