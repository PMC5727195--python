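"""Load-vector assembly, moment arms, recruitment optimisation and muscle
model editing."""

from types import SimpleNamespace

import numpy as np
import pytest

from kneemech import fixtures
from kneemech.kinematics import PoseTrajectory, differentiate, segment_kinematics
from kneemech.recruitment import (ExternalLoad, Muscle, RecruitmentProblem,
                                  assemble_coefficients, assemble_load_vector,
                                  path_length, scale_group_strength,
                                  scale_muscle_parameters, solve_recruitment,
                                  subdivide_muscle)
from _oracles import barrier_recruitment_oracle, random_recruitment_instance


def _static_kin(model, q=None, n=5):
    q = np.zeros(model.nq) if q is None else q
    t = np.arange(n) / 100.0
    traj = differentiate(PoseTrajectory(t, np.tile(q, (n, 1))))
    return segment_kinematics(model, traj)


class TestLoadVector:
    def test_static_no_loads_zero_gravity(self):
        model, _ = fixtures.build_leg_model()
        kin = _static_kin(model)
        d = assemble_load_vector(model, kin, 2, [], gravity=np.zeros(3))
        assert np.abs(d).max() < 1e-9

    def test_static_gravity_per_segment(self):
        model, _ = fixtures.build_leg_model()
        kin = _static_kin(model)
        d = assemble_load_vector(model, kin, 2, [])
        for j, s in enumerate(model.segments):
            R = kin.poses[2][s.name].rotation
            assert np.allclose(d[6 * j: 6 * j + 3],
                               R.T @ (s.mass * np.array([0, 0, -9.81])), atol=1e-9)
            assert np.abs(d[6 * j + 3: 6 * j + 6]).max() < 1e-9

    def test_gyroscopic_moment_for_steady_spin(self):
        # single free segment spinning at constant omega about a non-principal axis
        from kneemech.kinematics import Segment, SegmentModel, skew
        seg = Segment("body", None, "free", mass=2.0,
                      inertia=np.diag([0.1, 0.2, 0.35]))
        model = SegmentModel([seg])
        w = np.array([3.0, 2.0, 1.0])
        t = np.arange(9) / 100.0
        q = np.zeros((9, 6))
        # XYZ-Euler rates reproducing constant body omega are nontrivial; spin
        # about a single Euler axis instead and check against direct evaluation
        q[:, 3] = w[0] * t
        traj = differentiate(PoseTrajectory(t, q))
        kin = segment_kinematics(model, traj)
        d = assemble_load_vector(model, kin, 4, [], gravity=np.zeros(3))
        om = kin.omega_body["body"][4]
        dom = kin.domega_body["body"][4]
        expected = -(seg.inertia @ dom + skew(om) @ seg.inertia @ om)
        assert np.abs(d[3:6] - expected).max() < 1e-9

    def test_unmapped_external_load(self):
        model, _ = fixtures.build_leg_model()
        kin = _static_kin(model)
        with pytest.raises(ValueError, match="unknown segment"):
            assemble_load_vector(model, kin, 0, [ExternalLoad("tibia", [0, 0, 1], [0, 0, 0])])


class TestCoefficients:
    def test_single_hinge_moment_arm_is_perpendicular_distance(self):
        from kneemech.kinematics import Segment, SegmentModel
        segs = [Segment("base", None, "free", mass=1.0),
                Segment("arm", "base", "revolute", joint_center_parent=[0, 0, 0],
                        joint_axis=[0, 1, 0], mass=1.0, com=[0, 0, -0.1])]
        model = SegmentModel(segs)
        r = 0.05
        mus = Muscle("m", [("base", [-r, 0, 0.2]), ("arm", [-r, 0, -0.2])], 1000, 1e-4)
        kin = _static_kin(model)
        poses = kin.poses[2]
        # moment about the hinge from the attachment forces of unit tension
        prob = assemble_coefficients(model, kin, 2, [mus])
        # generalized column equals +dL/dq: vertical muscle at lever r
        h = 1e-7
        q = np.zeros(model.nq)
        qp, qm = q.copy(), q.copy()
        qp[6] += h
        qm[6] -= h
        dL = (path_length(model, model.forward_kinematics(qp), mus)
              - path_length(model, model.forward_kinematics(qm), mus)) / (2 * h)
        assert abs(abs(dL) - r) < 1e-6

    def test_moment_arm_matches_finite_difference_on_gait_model(self, gait_trial):
        # virtual-work check: C column of a muscle dotted with a joint-rate
        # induced segment velocity equals -dL/dq for that joint coordinate
        model, muscles = gait_trial.model, gait_trial.muscles
        kin = gait_trial.kin
        f = 20
        q = gait_trial.truth.q[f]
        h = 1e-7
        for mus in muscles:
            for qi in (7, 9, 10):  # hip flexion, knee, ankle coordinates
                qp, qm = q.copy(), q.copy()
                qp[qi] += h
                qm[qi] -= h
                dL = (path_length(model, model.forward_kinematics(qp), mus)
                      - path_length(model, model.forward_kinematics(qm), mus)) / (2 * h)
                # generalized force of unit tension along coordinate qi:
                # project attachment forces onto the coordinate velocity field
                from kneemech.loads import muscle_point_forces
                poses = model.forward_kinematics(q)
                tau = 0.0
                for seg, pt, fvec in muscle_point_forces(model, poses, mus, 1.0):
                    pp = model.forward_kinematics(qp)[seg].apply(
                        poses[seg].inverse().apply(pt))
                    pm = model.forward_kinematics(qm)[seg].apply(
                        poses[seg].inverse().apply(pt))
                    tau += fvec @ (pp - pm) / (2 * h)
                assert abs(tau + dL) < 1e-5

    def test_muscle_on_single_segment_rejected(self):
        with pytest.raises(ValueError):
            Muscle("bad", [("thigh", [0, 0, 0]), ("thigh", [0, 0, -0.1])], 100, 1e-5)


class TestSolveRecruitment:
    def test_one_muscle_one_dof_forced(self):
        r, tau, v, N = 0.05, 10.0, 2e-4, 1000.0
        prob = RecruitmentProblem(np.array([[r]]), np.array([tau / 1.0 * r / r * 1.0]),
                                  [SimpleNamespace(volume=v, strength=N)], [], 0)
        prob.d = np.array([tau])
        prob.C = np.array([[r]])
        sol = solve_recruitment(prob)
        assert abs(sol.f_muscle[0] - tau / r) < 1e-8 * tau / r
        assert abs(sol.objective - v * (tau / r / N) ** 3) < 1e-10

    def test_identical_muscles_split_equally(self):
        C = np.array([[0.05, 0.05]])
        d = np.array([10.0])
        ms = [SimpleNamespace(volume=2e-4, strength=1000.0)] * 2
        sol = solve_recruitment(RecruitmentProblem(C, d, ms, [], 0))
        assert abs(sol.f_muscle[0] - sol.f_muscle[1]) < 1e-8 * sol.f_muscle[0]

    def test_matches_independent_barrier_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            C, d, v, N, n_m = random_recruitment_instance(rng)
            ms = [SimpleNamespace(volume=v[i], strength=N[i]) for i in range(n_m)]
            sol = solve_recruitment(RecruitmentProblem(C, d, ms, [], 0))
            fo = barrier_recruitment_oracle(C, d, v, N, n_m)
            scale = max(1.0, np.abs(fo[:n_m]).max())
            assert np.abs(sol.f_muscle - fo[:n_m]).max() / scale < 1e-6
            Go = float(np.sum(v * (fo[:n_m] / N) ** 3))
            assert abs(sol.objective - Go) / max(Go, 1e-30) < 1e-6

    def test_unique_from_random_starts(self):
        rng = np.random.default_rng(5)
        C, d, v, N, n_m = random_recruitment_instance(rng)
        ms = [SimpleNamespace(volume=v[i], strength=N[i]) for i in range(n_m)]
        sols = []
        for seed in range(4):
            r2 = np.random.default_rng(seed)
            x0 = np.abs(r2.standard_normal(C.shape[1])) * N.mean() * 0.1
            sols.append(solve_recruitment(RecruitmentProblem(C, d, ms, [], 0), x0=x0))
        ref = sols[0].f_muscle
        for s in sols[1:]:
            assert np.abs(s.f_muscle - ref).max() < 1e-8 * max(1, np.abs(ref).max())

    def test_infeasible_instance_reported(self):
        # one muscle cannot produce a torque of the opposite sign
        C = np.array([[0.05]])
        d = np.array([-10.0])
        ms = [SimpleNamespace(volume=2e-4, strength=1000.0)]
        from kneemech.recruitment import InfeasibleEquilibriumError
        with pytest.raises(InfeasibleEquilibriumError):
            solve_recruitment(RecruitmentProblem(C, d, ms, [], 0))


class TestModelEditing:
    def test_subdivision_identity_for_k1(self, gait_trial):
        m = gait_trial.muscles[0]
        assert subdivide_muscle(m, 1) == [m]

    @pytest.mark.parametrize("k", [2, 5])
    def test_subdivision_invariance(self, gait_trial, k):
        f = 30
        trial = gait_trial

        def solve(muscles):
            prob = assemble_coefficients(trial.model, trial.kin, f, muscles)
            prob.d = assemble_load_vector(trial.model, trial.kin, f, trial.externals[f])
            return solve_recruitment(prob)

        base = solve(trial.muscles)
        gi = next(i for i, m in enumerate(trial.muscles) if m.name == "soleus")
        mus = []
        for i, m in enumerate(trial.muscles):
            mus.extend(subdivide_muscle(m, k) if i == gi else [m])
        sub = solve(mus)
        assert abs(sub.objective - base.objective) / base.objective < 1e-9
        assert np.abs(sub.f_reaction - base.f_reaction).max() < 1e-9 * max(
            1, np.abs(base.f_reaction).max())
        total = sum(sub.f_muscle[i] for i, m in enumerate(mus)
                    if m.name.startswith("soleus"))
        assert abs(total - base.f_muscle[gi]) / base.f_muscle[gi] < 1e-9

    def test_group_scaling(self, gait_trial):
        out = scale_group_strength(gait_trial.muscles, "knee-extensor", 0.5)
        for m0, m1 in zip(gait_trial.muscles, out):
            factor = 0.5 if "knee-extensor" in m0.tags else 1.0
            assert m1.strength == pytest.approx(m0.strength * factor)
        assert scale_group_strength(gait_trial.muscles, "knee-extensor", 1.0) \
            [2].strength == gait_trial.muscles[2].strength
        with pytest.raises(KeyError):
            scale_group_strength(gait_trial.muscles, "wing-flapper", 0.5)

    def test_length_mass_fat_scaling(self, gait_trial):
        ms = gait_trial.muscles
        same = scale_muscle_parameters(ms, 75.0, 1.75, 0.2)
        assert all(a.strength == pytest.approx(b.strength) for a, b in zip(ms, same))
        heavier = scale_muscle_parameters(ms, 150.0, 1.75, 0.2)
        assert heavier[0].strength / ms[0].strength == pytest.approx(2 ** (2 / 3))
        fatter = scale_muscle_parameters(ms, 75.0, 1.75, 0.35)
        assert all(f.strength <= b.strength for f, b in zip(fatter, ms))
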