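"""Biphasic u-p finite elements: residual/tangent consistency, poroelastic
benchmarks, coupling, rigid contact, stance protocol and postprocessing."""

import warnings

import numpy as np
import pytest

from kneemech import fem, fixtures
from _oracles import terzaghi_pressure

warnings.filterwarnings("ignore", category=RuntimeWarning)

E_TIB, NU_TIB = 0.106e6, 0.15
HA = E_TIB * (1 - NU_TIB) / ((1 + NU_TIB) * (1 - 2 * NU_TIB))
K_TIB = 18e-15
CV = K_TIB * HA


@pytest.fixture(scope="module")
def column_small():
    return fixtures.confined_compression_column(n_elem=2)


class TestAssembly:
    def test_zero_state_zero_residual(self, column_small):
        model = fixtures.confined_compression_fem(column_small)
        st = fem.BiphasicState.zero(column_small)
        R, K, _, _ = model.assemble(st, st, dt=1.0)
        assert np.abs(R).max() == 0.0

    def test_tangent_matches_central_difference(self, column_small):
        model = fixtures.confined_compression_fem(column_small)
        rng = np.random.default_rng(3)
        st0 = fem.BiphasicState.zero(column_small)
        st = fem.BiphasicState.zero(column_small)
        st.u = rng.normal(scale=1e-5, size=st.u.shape)
        st.p = rng.normal(scale=10.0, size=st.p.shape)
        dt = 0.1
        _, K0, _, _ = model.assemble(st, st0, dt)
        K0 = K0.toarray()
        Kfd = np.zeros_like(K0)
        h_u, h_p = 1e-9, 1e-4
        for j in range(model.ndof):
            sp_, sm_ = st.copy(), st.copy()
            if j < model.ndof_u:
                i, c = divmod(j, 3)
                sp_.u[i, c] += h_u
                sm_.u[i, c] -= h_u
                h = h_u
            else:
                sp_.p[j - model.ndof_u] += h_p
                sm_.p[j - model.ndof_u] -= h_p
                h = h_p
            Rp, _, _, _ = model.assemble(sp_, st0, dt, want_tangent=False)
            Rm, _, _, _ = model.assemble(sm_, st0, dt, want_tangent=False)
            Kfd[:, j] = (Rp - Rm) / (2 * h)
        assert np.abs(K0 - Kfd).max() / np.abs(K0).max() < 1e-5

    def test_patch_uniform_drained_stress_uniform_strain(self):
        mesh = fixtures.confined_compression_column(n_elem=1, height=1e-3)
        model = fixtures.confined_compression_fem(mesh)
        sigma0 = 100.0
        model.apply_face_traction("top", [0, 0, -sigma0])
        st = fem.BiphasicState.zero(mesh)
        for dt in (1e6, 1e7):
            st = fem.solve_step(model, st, dt)
        # uniform axial strain: displacement linear in z
        z = mesh.nodes[:, 2]
        eps = st.u[:, 2] / np.where(z == 0, 1.0, z)
        active = z > 0
        assert np.abs(eps[active] - eps[active][0]).max() < 1e-10 * abs(eps[active][0])

    def test_inverted_element_rejected(self, column_small):
        model = fixtures.confined_compression_fem(column_small)
        st = fem.BiphasicState.zero(column_small)
        bad = fem.BiphasicState.zero(column_small)
        bad.u[:, 2] = -10.0 * column_small.nodes[:, 2]  # crush below zero volume
        with pytest.raises(ValueError, match="inverted"):
            model.assemble(bad, st, 1.0)


class TestPoroelasticBenchmarks:
    def test_drained_equilibrium_aggregate_modulus(self):
        mesh = fixtures.confined_compression_column(n_elem=12)
        model = fixtures.confined_compression_fem(mesh)
        sigma0 = 200.0
        model.apply_face_traction("top", [0, 0, -sigma0])
        st = fem.BiphasicState.zero(mesh)
        for dt in (1e5, 1e6, 1e7, 1e7):
            st = fem.solve_step(model, st, dt)
        h = 2e-3
        eps = -st.u[mesh.node_sets["top"], 2].mean() / h
        assert abs(HA * eps - sigma0) / sigma0 < 0.01
        assert np.abs(st.p).max() < 1e-6 * sigma0

    def test_transient_matches_consolidation_series(self):
        h = 2e-3
        tau = h * h / CV
        sigma0 = 20.0  # linear limit
        mesh = fixtures.confined_compression_column(n_elem=18, grading=1.25)
        model = fixtures.confined_compression_fem(mesh)
        model.apply_face_traction("top", [0, 0, -sigma0])
        st = fem.BiphasicState.zero(mesh)
        steps = np.concatenate([np.geomspace(1e-4, 1e-2, 30),
                                np.full(49, 1e-2)]) * tau
        tgrid = np.cumsum(steps)
        prev, errs = 0.0, []
        for t in tgrid:
            st = fem.solve_step(model, st, t - prev)
            prev = t
            T = CV * t / h**2
            if T < 0.01:
                continue
            pa = terzaghi_pressure(h - mesh.nodes[:, 2], h, CV, t, sigma0)
            errs.append(np.linalg.norm(st.p - pa) / np.linalg.norm(pa))
        assert max(errs) < 0.02

    def test_instantaneous_response_isochoric(self):
        mesh = fixtures.confined_compression_column(n_elem=1, height=1e-3)
        model = fem.BiphasicFEM(mesh)
        bot = mesh.node_sets["bottom"]
        model.fix_nodes(bot, components=(2,))
        model.fix_nodes([bot[0]], components=(0, 1))
        model.fix_nodes([bot[1]], components=(1,))
        model.apply_face_traction("top", [0, 0, -50.0])
        st = fem.solve_step(model, fem.BiphasicState.zero(mesh), dt=1e-4)
        eps_ax = -st.u[mesh.node_sets["top"], 2].mean() / 1e-3
        dN = model._elem_dN[0].mean(axis=0)
        vol = np.trace(st.u[mesh.elements[0]].T @ dN)
        assert abs(vol) / abs(eps_ax) < 0.01

    def test_fluid_mass_conserved_when_sealed(self):
        # sealed everywhere: volumetric strain stays zero however hard loaded
        mesh = fixtures.confined_compression_column(n_elem=2, height=1e-3)
        model = fixtures.confined_compression_fem(mesh, drained_top=False)
        model.apply_face_traction("top", [0, 0, -100.0])
        st = fem.solve_step(model, fem.BiphasicState.zero(mesh), dt=1.0)
        for e in range(len(mesh.elements)):
            dN = model._elem_dN[e].mean(axis=0)
            vol = np.trace(st.u[mesh.elements[e]].T @ dN)
            assert abs(vol) < 1e-8

    def test_time_step_refinement_converges(self):
        # slow drained ramp: halving dt changes the final stress state < 0.5%
        def run(nsteps):
            mesh = fixtures.confined_compression_column(n_elem=4)
            model = fixtures.confined_compression_fem(mesh)
            model.apply_face_traction("top", [0, 0, -100.0])
            st = fem.BiphasicState.zero(mesh)
            for _ in range(nsteps):
                st = fem.solve_step(model, st, 4e6 / nsteps)
            return -st.u[mesh.node_sets["top"], 2].mean()

        u1, u2 = run(4), run(8)
        assert abs(u1 - u2) / u2 < 0.005


class TestCouplingAndContact:
    def test_reference_point_translation(self):
        mesh = fixtures.confined_compression_column(n_elem=2)
        model = fem.BiphasicFEM(mesh)
        top = mesh.node_sets["top"]
        coup = fem.apply_reference_point_coupling(model, [0.0005, 0.0005, 2.5e-3], top)
        model.fix_nodes(mesh.node_sets["bottom"])
        model.prescribe_pressure(np.arange(mesh.n_nodes), 0.0)
        w = np.array([0, 0, -1e-4, 0, 0, 0])
        st = fem.solve_step(model, fem.BiphasicState.zero(mesh), 1.0,
                            couplings=[coup], coupling_wrench={0: w})
        # all coupled nodes translate identically
        assert np.abs(st.u[top] - st.u[top][0]).max() < 1e-12

    def test_reference_point_rotation_lever_arms(self):
        mesh = fixtures.confined_compression_column(n_elem=2)
        model = fem.BiphasicFEM(mesh)
        top = mesh.node_sets["top"]
        ref = np.array([0.0005, 0.0005, 2.5e-3])
        coup = fem.apply_reference_point_coupling(model, ref, top)
        model.fix_nodes(mesh.node_sets["bottom"])
        model.prescribe_pressure(np.arange(mesh.n_nodes), 0.0)
        w = np.array([0, 0, 0, 1e-9, 0, 0])  # small moment about x
        st = fem.solve_step(model, fem.BiphasicState.zero(mesh), 1.0,
                            couplings=[coup], coupling_wrench={0: w})
        # displacements form one linearised rigid motion u = t + theta x r
        rows, rhs = [], []
        for n in top:
            r = mesh.nodes[n] - ref
            rx = np.array([[0, r[2], -r[1]], [-r[2], 0, r[0]], [r[1], -r[0], 0]])
            rows.append(np.hstack([np.eye(3), rx]))
            rhs.append(st.u[n])
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        assert np.abs(A @ sol - b).max() < 1e-14
        assert np.abs(sol[3:]).max() > 1e-7  # the moment did rotate the set

    def test_empty_coupling_set_rejected(self):
        mesh = fixtures.confined_compression_column(n_elem=1)
        model = fem.BiphasicFEM(mesh)
        with pytest.raises(ValueError):
            fem.apply_reference_point_coupling(model, np.zeros(3), np.array([], dtype=int))

    def test_rigid_plane_uniform_pressure(self):
        contact = fem.RigidContact(fem.RigidPlane([0, 0, 1e-4], [0, 0, 1.0]),
                                   np.array([0]), np.array([1e-6]),
                                   penalty=1e9, smoothing=1e-12)
        mesh = fixtures.confined_compression_column(n_elem=1)
        model = fem.BiphasicFEM(mesh)
        model.contacts = [contact]
        # node 0 sits at z=0, below the plane by 1e-4 (gap negative)
        entries = model._contact_contrib(contact, np.zeros((mesh.n_nodes, 3)))
        assert len(entries) == 1
        nid, area, g, n, f, dp = entries[0]
        assert g == pytest.approx(-1e-4)
        assert f[2] == pytest.approx(1e9 * 1e-4 * 1e-6, rel=1e-6)

    def test_separated_contact_no_contribution(self):
        contact = fem.RigidContact(fem.RigidPlane([0, 0, -1e-3], [0, 0, 1.0]),
                                   np.array([0]), np.array([1e-6]))
        mesh = fixtures.confined_compression_column(n_elem=1)
        model = fem.BiphasicFEM(mesh)
        assert model._contact_contrib(contact, np.zeros((mesh.n_nodes, 3))) == []


@pytest.fixture(scope="module")
def stance_history():
    knee = fixtures.simplified_knee_fe()
    knee.model.indenter.ligaments = []
    knee.model.indenter.prescribed = {0: 0.0, 1: 0.0}
    proto = fem.LoadProtocol(stance_steps=4, approach_steps=2, initial_steps=2)

    def wrench(pct):
        return np.array([0, 0, -(100.0 + 200.0 * pct / 100.0), 0, 0, 0])

    history = fem.run_stance_simulation(knee.model, wrench, proto)
    return knee, history


class TestStanceSimulation:
    def test_axial_ramp_global_equilibrium(self, stance_history):
        knee, history = stance_history
        last = history[-1]
        Fz = 0.0
        for c in knee.model.indenter.contacts:
            for nid, area, g, n, f, dp in knee.model._contact_contrib(
                    c, last.u, last.indenter_dofs, knee.model.indenter):
                Fz += f[2]
        stab = knee.model.indenter.translational_stiffness * last.indenter_dofs[2]
        # mesh receives -(applied) through contact + stabiliser: sums to zero
        assert abs(Fz + stab + 300.0) / 300.0 < 0.01

    def test_peak_pressure_increases_with_load(self, stance_history):
        knee, history = stance_history
        peaks = [max(h.contact_pressure.values()) for h in history]
        assert peaks[-1] > peaks[0]

    def test_deformation_below_damage_threshold(self):
        """With the fibril network active, peak compressive engineering
        strain under the body-weight-scaled load stays below the 30 %
        chondrocyte-damage threshold (and in the physiological 6-16 %
        range reported for gait)."""
        knee = fixtures.simplified_knee_fe(fibrils=True)
        knee.model.indenter.ligaments = []
        knee.model.indenter.prescribed = {0: 0.0, 1: 0.0}
        proto = fem.LoadProtocol(stance_steps=4, approach_steps=2, initial_steps=2)

        def wrench(pct):
            return np.array([0, 0, -(50.0 + 100.0 * pct / 100.0), 0, 0, 0])

        history = fem.run_stance_simulation(knee.model, wrench, proto)
        strain = np.abs(history[-1].u[:, 2]).max() / knee.params["thickness"]
        assert 0.03 < strain < 0.30


class TestPostprocess:
    def _frame(self, mesh, pressures):
        return fem.FrameResult(0.0, 0.0, np.zeros((mesh.n_nodes, 3)),
                               np.zeros(mesh.n_nodes), pressures)

    def test_threshold_counts_exactly(self):
        knee = fixtures.simplified_knee_fe(nx=3, nz=3)
        mesh = knee.mesh
        areas = mesh.nodal_areas("articular")
        med_top = mesh.node_sets["medial_top"]
        field = {int(n): (0.5e6 if i % 2 == 0 else 0.005e6)
                 for i, n in enumerate(med_top)}
        post = fem.postprocess([self._frame(mesh, field)], mesh)
        above = [n for n, p in field.items() if p > 0.01e6]
        assert post["contact_area"][0] == pytest.approx(
            sum(areas[n] for n in above))
        assert post["peak_pressure"][0] == pytest.approx(0.5e6)
        vals = np.array(list(field.values()))
        assert post["mean_pressure"][0] == pytest.approx(vals[vals > 0].mean())

    def test_all_below_threshold_zero_area(self):
        knee = fixtures.simplified_knee_fe(nx=3, nz=3)
        field = {int(n): 0.005e6 for n in knee.mesh.node_sets["medial_top"]}
        post = fem.postprocess([self._frame(knee.mesh, field)], knee.mesh)
        assert post["contact_area"][0] == 0.0

    def test_no_contact_flagged(self):
        knee = fixtures.simplified_knee_fe(nx=3, nz=3)
        post = fem.postprocess([self._frame(knee.mesh, {})], knee.mesh)
        assert post["no_contact"][0] is True
        assert post["peak_pressure"][0] == 0.0

    def test_medial_lateral_split_matches_direct_sum(self):
        knee = fixtures.simplified_knee_fe(nx=3, nz=3)
        mesh = knee.mesh
        areas = mesh.nodal_areas("articular")
        field = {}
        for n in mesh.node_sets["medial_top"]:
            field[int(n)] = 1.0e6
        for n in mesh.node_sets["lateral_top"]:
            field[int(n)] = 2.0e6
        post = fem.postprocess([self._frame(mesh, field)], mesh)
        med_direct = sum(1.0e6 * areas[int(n)] for n in mesh.node_sets["medial_top"])
        lat_direct = sum(2.0e6 * areas[int(n)] for n in mesh.node_sets["lateral_top"])
        assert post["medial_force"][0] == pytest.approx(med_direct)
        assert post["lateral_force"][0] == pytest.approx(lat_direct)
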