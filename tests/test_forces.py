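"""Per-particle force model tests: drag correlation and relaxation time,
Saffman lift, Brownian noise, buoyancy-corrected gravity, Lennard-Jones
MB-MB interaction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbtrack.forces import (LJParams, brownian_force, drag_cd_re,
                            drag_coefficient, drag_force, gravity_force,
                            lj_pair_forces, lj_pair_forces_allpairs,
                            relative_reynolds, relaxation_time, saffman_lift)


class TestRelativeReynolds:
    def test_no_slip_zero(self):
        assert relative_reynolds(np.ones(3), np.ones(3), 2e-6, 1050, 0.003) == 0.0

    def test_hand_value(self):
        u = np.array([0.1, 0.0, 0.0])
        assert relative_reynolds(u, np.zeros(3), 4.5e-6, 1050.0, 0.00345) == \
            pytest.approx(0.137, rel=1e-2)

    def test_linearity_in_slip(self):
        u = np.array([0.02, 0.0, 0.01])
        re1 = relative_reynolds(u, np.zeros(3), 2e-6, 1050.0, 0.003)
        re10 = relative_reynolds(10 * u, np.zeros(3), 2e-6, 1050.0, 0.003)
        assert re10 == pytest.approx(10 * re1)


class TestDragCorrelation:
    def test_stokes_branch_hand_value(self):
        assert drag_coefficient(0.005) == pytest.approx(4804.5, rel=1e-6)

    def test_newton_branch_hand_value(self):
        assert drag_coefficient(100.0) == pytest.approx(1.087, rel=1e-3)

    def test_stokes_limit_product(self):
        assert drag_cd_re(0.0) == pytest.approx(24.0)

    @pytest.mark.parametrize("re_edge", [0.01, 20.0])
    def test_branch_continuity(self, re_edge):
        below = drag_cd_re(re_edge * (1 - 1e-9))
        above = drag_cd_re(re_edge * (1 + 1e-9))
        assert abs(above - below) / below < 0.01

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            drag_cd_re(300.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            drag_cd_re(-1.0)


class TestDragForce:
    def test_equal_velocities_no_force(self):
        f, _ = drag_force(np.ones(3), np.ones(3), 2e-6, 1050, 1000, 0.003)
        assert np.allclose(f, 0.0)

    def test_stokes_relaxation_time(self):
        _, tau = drag_force(np.zeros(3), np.zeros(3), 2.2e-6, 1050.0,
                            1000.0, 0.00345)
        assert tau == pytest.approx(7.79e-8, rel=1e-2)
        assert tau == pytest.approx(1000.0 * 2.2e-6**2 / (18 * 0.00345),
                                    rel=1e-12)

    def test_stokes_limit_is_3_pi_eta_d_slip(self):
        u = np.array([1e-6, 0.0, 0.0])  # tiny slip => Stokes branch
        d, eta = 2e-6, 0.003
        f, _ = drag_force(u, np.zeros(3), d, 1050.0, 1000.0, eta)
        assert np.allclose(f, 3 * np.pi * eta * d * u, rtol=1e-4)

    def test_antisymmetric_under_velocity_swap(self, rng):
        u = rng.normal(size=3) * 0.01
        v = rng.normal(size=3) * 0.01
        f1, _ = drag_force(u, v, 2e-6, 1050.0, 1000.0, 0.003)
        f2, _ = drag_force(v, u, 2e-6, 1050.0, 1000.0, 0.003)
        assert np.allclose(f1, -f2)


class TestSaffmanLift:
    def test_no_slip_zero(self):
        g = np.zeros((3, 3))
        g[0, 1] = 100.0
        f = saffman_lift(np.ones(3), np.ones(3), g, 2e-6, 1050.0, 0.003)
        assert np.allclose(f, 0.0)

    def test_irrotational_zero(self):
        g = np.diag([1.0, 1.0, -2.0])  # symmetric => curl-free
        f = saffman_lift(np.array([0.1, 0, 0]), np.zeros(3), g, 2e-6,
                         1050.0, 0.003)
        assert np.allclose(f, 0.0)

    def test_quadratic_diameter_scaling(self):
        g = np.zeros((3, 3))
        g[0, 1] = 100.0
        u = np.array([0.05, 0.0, 0.0])
        f1 = saffman_lift(u, np.zeros(3), g, 2e-6, 1050.0, 0.003)
        f2 = saffman_lift(u, np.zeros(3), g, 4e-6, 1050.0, 0.003)
        assert np.linalg.norm(f2) == pytest.approx(
            4 * np.linalg.norm(f1), rel=1e-12)

    def test_parallel_to_slip_cross_curl(self, rng):
        g = rng.normal(size=(3, 3))
        u = rng.normal(size=3) * 0.01
        v = rng.normal(size=3) * 0.01
        curl = np.array([g[2, 1] - g[1, 2], g[0, 2] - g[2, 0],
                         g[1, 0] - g[0, 1]])
        lv = np.cross(u - v, curl)
        f = saffman_lift(u, v, g, 2e-6, 1050.0, 0.003)
        cosang = np.dot(f, lv) / (np.linalg.norm(f) * np.linalg.norm(lv))
        assert abs(cosang) == pytest.approx(1.0, abs=1e-10)


class TestBrownianForce:
    def test_zero_temperature_zero_force(self, rng):
        f = brownian_force(2e-6, 0.003, 0.0, 1e-4, rng)
        assert np.allclose(f, 0.0)

    def test_amplitude_matches_hand_value(self, rng):
        draws = np.array([brownian_force(2.2e-6, 0.00345, 310.15, 1e-4, rng)
                          for _ in range(4000)])
        assert draws.std() == pytest.approx(2.48e-12, rel=0.05)

    def test_mean_zero_at_fixed_seed(self):
        rng = np.random.default_rng(7)
        draws = brownian_force(np.full(100000, 2.2e-6), 0.00345, 310.15,
                               1e-4, rng)
        se = 2.48e-12 / np.sqrt(draws.size)
        assert abs(draws.mean()) < 4 * se

    def test_invalid_dt_rejected(self, rng):
        with pytest.raises(ValueError):
            brownian_force(2e-6, 0.003, 310.0, 0.0, rng)


class TestGravityForce:
    def test_neutral_buoyancy(self):
        f = gravity_force(1e-14, 1050.0, 1050.0, (0, -9.81, 0))
        assert np.allclose(f, 0.0)

    def test_buoyant_bubble_opposes_gravity(self):
        m = 1e-14
        f = gravity_force(m, 1000.0, 1050.0, (0, -9.81, 0))
        assert f[1] > 0.0  # rises
        assert abs(f[1]) == pytest.approx(0.05 * m * 9.81, rel=1e-12)

    def test_vacuum_limit(self):
        m = 1e-14
        f = gravity_force(m, 1000.0, 0.0, (0, -9.81, 0))
        assert np.allclose(f, m * np.array([0, -9.81, 0]))


class TestLennardJones:
    def test_zero_at_potential_minimum(self):
        d = 1.1e-6
        sig = 0.89 * d
        pos = np.array([[0, 0, 0], [2 ** (1 / 6) * sig, 0, 0]])
        f = lj_pair_forces(pos, d)
        assert np.abs(f).max() < 1e-25

    def test_repulsive_magnitude_at_sigma(self):
        d = 1.1e-6
        sig = 0.89 * d
        pos = np.array([[0.0, 0, 0], [sig, 0, 0]])
        f = lj_pair_forces(pos, d)
        # 24 eps / sigma at r = sigma, directed apart
        assert np.linalg.norm(f[0]) == pytest.approx(2.01e-14, rel=1e-2)
        assert f[0, 0] < 0.0 < f[1, 0]

    def test_momentum_conservation_random_cloud(self, rng):
        pos = rng.uniform(0, 20e-6, size=(40, 3))
        d = rng.uniform(1e-6, 5e-6, size=40)
        f = lj_pair_forces(pos, d)
        assert np.abs(f.sum(axis=0)).max() < 1e-20

    def test_tree_matches_allpairs_oracle(self, rng):
        pos = rng.uniform(0, 15e-6, size=(60, 3))
        d = rng.uniform(1e-6, 4e-6, size=60)
        f_tree = lj_pair_forces(pos, d)
        f_all = lj_pair_forces_allpairs(pos, d)
        assert np.allclose(f_tree, f_all, rtol=1e-12, atol=1e-30)

    def test_overlap_capped_with_warning(self):
        d = 1.1e-6
        pos = np.array([[0.0, 0, 0], [1e-11, 0, 0]])
        with pytest.warns(UserWarning):
            f = lj_pair_forces(pos, d)
        assert np.all(np.isfinite(f))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LJParams(epsilon=-1.0)
        with pytest.raises(ValueError):
            LJParams(cutoff_sigma=0.5)


class TestRelaxationTimeProperties:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(1e-7, 5e-6), st.floats(1e-3, 0.2))
    def test_tau_positive_and_decreasing_in_viscosity(self, d, eta):
        t1 = relaxation_time(d, 1000.0, eta)
        t2 = relaxation_time(d, 1000.0, 2 * eta)
        assert t1 > 0
        assert t2 < t1
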