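"""Fibril-reinforced poroviscoelastic material: presets, fibril rheology,
architecture, Neo-Hookean matrix and permeability."""

import numpy as np
import pytest

from kneemech import frpve


@pytest.fixture
def tibial():
    return frpve.FRPVEMaterial.from_preset("tibial cartilage")


class TestPresets:
    @pytest.mark.parametrize("tissue,expect", [
        ("femoral cartilage", dict(E_m=0.215, v_m=0.15, E_0=0.92, E_eps=150.0,
                                   k_0=6.0, M=5.09, eta=1062.0, D=12.16)),
        ("tibial cartilage", dict(E_m=0.106, v_m=0.15, E_0=0.18, E_eps=23.6,
                                  k_0=18.0, M=15.64, eta=1062.0, D=12.16)),
        ("patellar cartilage", dict(E_m=0.505, v_m=0.15, E_0=1.88, E_eps=597.0,
                                    k_0=1.9, M=15.93, eta=1062.0, D=12.16)),
        ("meniscus", dict(E_m=0.5, v_m=0.36, E_0=28.0, E_eps=0.0,
                          k_0=1.25, M=5.09, eta=0.0, D=12.16)),
    ])
    def test_tissue_presets_exact(self, tissue, expect):
        mat = frpve.FRPVEMaterial.from_preset(tissue)
        for key, val in expect.items():
            assert getattr(mat, key) == val

    def test_fluid_fraction_profiles(self):
        cart = frpve.FRPVEMaterial.from_preset("tibial cartilage")
        men = frpve.FRPVEMaterial.from_preset("meniscus")
        z = np.linspace(0, 1, 5)
        assert np.allclose(cart.fluid_fraction(z), 0.8 - 0.15 * z)
        assert np.allclose(men.fluid_fraction(z), 0.72)

    def test_unknown_tissue(self):
        with pytest.raises(KeyError):
            frpve.FRPVEMaterial.from_preset("bone")


class TestFibrilRheology:
    def test_compression_gives_zero_stress(self, tibial):
        st = frpve.FibrilState()
        for eps in (-0.05, -0.01, 0.0):
            s, st = frpve.fibril_stress_update(st, eps, 0.01, tibial)
            assert s == 0.0

    def test_relaxation_to_parallel_branch(self, tibial):
        eps, dt = 0.05, 0.5
        st = frpve.FibrilState()
        for _ in range(200000):
            s, st = frpve.fibril_stress_update(st, eps, dt, tibial)
        equilibrium = tibial.E_0 * eps + 0.5 * tibial.E_eps * eps**2
        assert abs(s - equilibrium) / equilibrium < 1e-6

    def test_limit_stiffnesses(self, tibial):
        from dataclasses import replace
        eps = 1e-4
        # damper locked: both springs in parallel
        stiffmat = replace(tibial, eta=1e30)
        s, _ = frpve.fibril_stress_update(frpve.FibrilState(), eps, 1e-6, stiffmat)
        tang_locked = s / eps
        assert abs(tang_locked - (tibial.E_0 + tibial.E_eps)) / (tibial.E_0 + tibial.E_eps) < 1e-2
        # damper free: parallel branch only
        softmat = replace(tibial, eta=1e-30)
        s, _ = frpve.fibril_stress_update(frpve.FibrilState(), eps, 1.0, softmat)
        assert abs(s / eps - tibial.E_0) / tibial.E_0 < 1e-2

    def test_dissipation_nonnegative_over_cycle(self, tibial):
        dt = 0.05
        t = np.arange(0, 40, dt)
        eps = 0.03 * (1 - np.cos(2 * np.pi * t / 20)) / 2
        st = frpve.FibrilState()
        work = 0.0
        s_prev = 0.0
        for k in range(1, len(t)):
            s, st = frpve.fibril_stress_update(st, eps[k], dt, tibial)
            work += 0.5 * (s + s_prev) * (eps[k] - eps[k - 1])
            s_prev = s
        assert work >= -1e-12

    def test_rate_independent_limit_under_dt_refinement(self, tibial):
        def final_stress(nsteps):
            t = np.linspace(0, 1000.0, nsteps + 1)
            st = frpve.FibrilState()
            s = 0.0
            for k in range(1, len(t)):
                s, st = frpve.fibril_stress_update(st, 0.04 * t[k] / 1000.0,
                                                   t[k] - t[k - 1], tibial)
            return s
        s1, s2 = final_stress(400), final_stress(800)
        assert abs(s1 - s2) / s2 < 0.005

    def test_tangent_consistent_with_update(self, tibial):
        st = frpve.FibrilState(viscous_strain=0.01)
        eps, dt, h = 0.04, 0.1, 1e-8
        sp, _ = frpve.fibril_stress_update(st, eps + h, dt, tibial)
        sm, _ = frpve.fibril_stress_update(st, eps - h, dt, tibial)
        fd = (sp - sm) / (2 * h)
        an = frpve.fibril_tangent(st, eps, dt, tibial)
        assert abs(fd - an) / abs(an) < 1e-6


class TestFibrillarStressTensor:
    def _dirs(self, primaries, tibial, weight_one=True):
        sec = frpve.secondary_direction_set(13)
        n_p = len(primaries)
        D = 1e12 if weight_one else tibial.D
        return frpve.FibrilDirections(np.array([primaries]), sec, np.zeros(1),
                                      primary_weight=D / (D * n_p + 13) if not weight_one
                                      else 1.0 / n_p,
                                      secondary_weight=0.0 if weight_one
                                      else 1.0 / (D * n_p + 13))

    def test_isotropic_compression_slack(self, tibial):
        dirs = self._dirs([[1, 0, 0]], tibial)
        states = [frpve.FibrilState() for _ in range(14)]
        sig, _ = frpve.total_fibrillar_stress(dirs, -0.05 * np.eye(3), states, 0.1, tibial)
        assert np.abs(sig).max() == 0.0

    def test_uniaxial_tension_single_dyad(self, tibial):
        n = np.array([1.0, 0, 0])
        dirs = self._dirs([n], tibial)
        states = [frpve.FibrilState() for _ in range(14)]
        E = 0.05 * np.outer(n, n)
        sig, _ = frpve.total_fibrillar_stress(dirs, E, states, 0.1, tibial)
        s_scalar, _ = frpve.fibril_stress_update(frpve.FibrilState(), 0.05, 0.1, tibial)
        assert np.allclose(sig, s_scalar * np.outer(n, n), atol=1e-12)

    def test_two_orthogonal_primaries_superpose(self, tibial):
        n1, n2 = np.eye(3)[0], np.eye(3)[1]
        dirs = self._dirs([n1, n2], tibial)
        states = [frpve.FibrilState() for _ in range(15)]
        E = 0.05 * (np.outer(n1, n1) + np.outer(n2, n2))
        sig, _ = frpve.total_fibrillar_stress(dirs, E, states, 0.1, tibial)
        s_scalar, _ = frpve.fibril_stress_update(frpve.FibrilState(), 0.05, 0.1, tibial)
        expected = 0.5 * s_scalar * (np.outer(n1, n1) + np.outer(n2, n2))
        assert np.allclose(sig, expected, atol=1e-12)


class TestNonfibrillarMatrix:
    def test_reference_state_stress_free(self, tibial):
        assert np.abs(frpve.nonfibrillar_stress(np.eye(3), tibial)).max() == 0.0

    def test_small_strain_matches_linear_elasticity(self, tibial):
        lam = tibial.E_m * tibial.v_m / ((1 + tibial.v_m) * (1 - 2 * tibial.v_m))
        mu = tibial.E_m / (2 * (1 + tibial.v_m))
        eps = 1e-6
        F = np.eye(3)
        F[0, 0] += eps
        sig = frpve.nonfibrillar_stress(F, tibial)
        assert abs(sig[0, 0] - (lam + 2 * mu) * eps) / ((lam + 2 * mu) * eps) < 1e-4
        assert abs(sig[1, 1] - lam * eps) / (lam * eps) < 1e-4

    def test_stress_is_energy_gradient(self, tibial):
        # volumetric stretch: compare pressure against dW/dJ by central FD
        J = 1.1
        lamb = J ** (1 / 3)
        h = 1e-7

        def W_of(lmb):
            return frpve.nonfibrillar_strain_energy(np.eye(3) * lmb, tibial)

        dWdl = (W_of(lamb + h) - W_of(lamb - h)) / (2 * h)
        sig = frpve.nonfibrillar_stress(np.eye(3) * lamb, tibial)
        # for isotropic stretch: sigma_kk * 3 = dW/dlambda * lambda / J
        assert abs(3 * sig[0, 0] - dWdl * lamb / J) / abs(3 * sig[0, 0]) < 1e-6

    def test_inverted_configuration_rejected(self, tibial):
        with pytest.raises(ValueError, match="inverted"):
            frpve.nonfibrillar_stress(-np.eye(3), tibial)


class TestTotalStressAndPermeability:
    def test_total_stress_composition(self, tibial):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((3, 3))
        b = rng.standard_normal((3, 3))
        p = 0.37
        assert np.allclose(frpve.total_stress(a, b, p), a + b - p * np.eye(3))
        assert np.allclose(frpve.total_stress(0 * a, 0 * b, p), -p * np.eye(3))

    def test_permeability_law(self, tibial):
        e0 = tibial.void_ratio(0.5)
        assert frpve.permeability(e0, e0, tibial) == pytest.approx(18e-15)
        assert frpve.permeability(e0 - 0.2, e0, tibial) < tibial.k0_si
        # monotone decrease under compression
        es = e0 - np.linspace(0, 0.5, 6)
        ks = frpve.permeability(es, e0, tibial)
        assert np.all(np.diff(ks) < 0)


class TestFibrilArchitecture:
    def test_arcade_orientation_limits(self):
        nrm = np.array([0.0, 0.0, 1.0])
        tan = np.array([1.0, 0.0, 0.0])
        dirs = frpve.build_fibril_architecture(np.array([0.0, 1.0]), nrm, tan,
                                               "tibial cartilage")
        assert abs(dirs.primary[0, 0] @ nrm) < 1e-12  # surface: in-plane
        assert abs(abs(dirs.primary[1, 0] @ nrm) - 1) < 1e-12  # deep: normal

    def test_meniscus_circumferential(self):
        dirs = frpve.build_fibril_architecture(np.array([0.3]), [0, 0, 1.0],
                                               [0, 1.0, 0], "meniscus")
        assert np.allclose(np.abs(dirs.primary[0] @ np.array([0, 1.0, 0])), 1.0)

    def test_secondary_set_near_isotropic(self):
        n = frpve.secondary_direction_set(13, seed=7)
        M = n.T @ n / len(n)
        dev = np.linalg.norm(M - np.eye(3) / 3) / np.linalg.norm(np.eye(3) / 3)
        assert dev < 0.02

    def test_missing_tangent_field_rejected(self):
        with pytest.raises(ValueError):
            frpve.build_fibril_architecture(np.array([0.5]), [0, 0, 1.0], None,
                                            "tibial cartilage")
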