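"""Musculoskeletal stage: scaling, IK, inverse dynamics, static optimization."""

import numpy as np
import pytest

from fetalkick.errors import ConfigurationError
from fetalkick.msk import (KickInput, inverse_dynamics, inverse_kinematics,
                           reference_model, run_kick, scale_model,
                           solve_frame, static_optimization)


@pytest.fixture(scope="module")
def adult():
    return reference_model()


@pytest.fixture(scope="module")
def fetal(adult):
    return scale_model(adult, 51.02, 54.58)


class TestScaling:
    def test_unit_factors_are_identity(self, adult):
        same = scale_model(adult, 396.0, 430.0)
        for name in ("femur", "tibia", "pelvis", "foot"):
            assert same.segments[name].length_m == pytest.approx(
                adult.segments[name].length_m)
            assert same.segments[name].mass_kg == pytest.approx(
                adult.segments[name].mass_kg)

    def test_per_segment_factors(self, adult, fetal):
        f_fem = 51.02e-3 / adult.segments["femur"].length_m
        f_tib = 54.58e-3 / adult.segments["tibia"].length_m
        assert fetal.segments["femur"].length_m == pytest.approx(51.02e-3)
        assert fetal.segments["tibia"].length_m == pytest.approx(54.58e-3)
        assert fetal.segments["foot"].length_m == pytest.approx(
            adult.segments["foot"].length_m * 0.5 * (f_fem + f_tib))
        assert fetal.segments["femur"].mass_kg == pytest.approx(
            adult.segments["femur"].mass_kg * f_fem**3)

    def test_path_fractions_preserved_offsets_scaled(self, adult, fetal):
        a = {m.name: m for m in adult.muscles}
        f = {m.name: m for m in fetal.muscles}
        f_fem = 51.02e-3 / adult.segments["femur"].length_m
        for seg, frac, off in f["vastus_lateralis"].path:
            pass
        for (s1, fr1, o1), (s2, fr2, o2) in zip(
                a["vastus_lateralis"].path, f["vastus_lateralis"].path):
            assert s1 == s2 and fr1 == fr2
            if s1 == "femur":
                assert o2 == pytest.approx(o1 * f_fem)

    def test_fmax_unchanged_by_scaling(self, adult, fetal):
        for ma, mf in zip(adult.muscles, fetal.muscles):
            assert mf.fmax_n == ma.fmax_n

    def test_nonpositive_lengths_rejected(self, adult):
        with pytest.raises(ConfigurationError):
            scale_model(adult, -3.0, 50.0)

    def test_eighteen_muscles_two_groups(self, adult):
        assert len(adult.muscles) == 18
        assert {m.group for m in adult.muscles} == {"hip", "knee"}


class TestInverseKinematics:
    def test_forward_model_round_trip(self, fetal):
        alpha = np.linspace(-1.9, -0.8, 6)
        phi = np.linspace(1.2, 0.1, 6)
        K, A = [], []
        for a, p in zip(alpha, phi):
            k, an, _ = fetal.joint_positions(
                np.zeros(2), np.array([a, p, fetal.ankle_locked_angle]))
            K.append(k)
            A.append(an)
        ang = inverse_kinematics(fetal, np.zeros((6, 2)),
                                 np.array(K) * 1e3, np.array(A) * 1e3,
                                 auto_mirror=False)
        assert np.allclose(ang.alpha, alpha, atol=1e-6)
        assert np.allclose(ang.phi, phi, atol=1e-6)
        assert ang.residual_mm.max() < 1e-6

    def test_straight_leg_recovers_zero_flexion(self, fetal):
        k, a, _ = fetal.joint_positions(
            np.zeros(2), np.array([-1.2, 0.0, fetal.ankle_locked_angle]))
        ang = inverse_kinematics(fetal, np.zeros((3, 2)),
                                 np.tile(k, (3, 1)) * 1e3,
                                 np.tile(a, (3, 1)) * 1e3, auto_mirror=False)
        assert np.allclose(ang.phi, 0.0, atol=1e-8)

    def test_degenerate_configuration_rejected(self, fetal):
        z = np.zeros((3, 2))
        with pytest.raises(ConfigurationError):
            inverse_kinematics(fetal, z, z, z)

    def test_mirrored_input_is_canonicalized(self, fetal):
        alpha, phi = -1.4, 0.7
        k, a, _ = fetal.joint_positions(
            np.zeros(2), np.array([alpha, phi, fetal.ankle_locked_angle]))
        # reflect across the x-axis: flexion flips sign
        K = np.tile(k * np.array([1, -1]), (3, 1)) * 1e3
        A = np.tile(a * np.array([1, -1]), (3, 1)) * 1e3
        ang = inverse_kinematics(fetal, np.zeros((3, 2)), K, A)
        assert ang.mirrored
        assert np.allclose(ang.phi, phi, atol=1e-6)


class TestInverseDynamics:
    def static_series(self, model, q, n=5):
        k, a, _ = model.joint_positions(np.zeros(2), q)
        return inverse_kinematics(model, np.zeros((n, 2)),
                                  np.tile(k, (n, 1)) * 1e3,
                                  np.tile(a, (n, 1)) * 1e3, auto_mirror=False)

    def test_static_pose_zero_force_zero_moments(self, fetal):
        ang = self.static_series(fetal,
                                 np.array([-1.3, 0.4, fetal.ankle_locked_angle]))
        tau = inverse_dynamics(fetal, ang, np.zeros((5, 2)), 0.303)
        assert np.allclose(tau, 0.0, atol=1e-12)

    def test_static_force_matches_cross_product_oracle(self, fetal):
        q = np.array([-1.3, 0.4, fetal.ankle_locked_angle])
        ang = self.static_series(fetal, q)
        F = np.tile([0.2, 0.45], (5, 1))
        tau = inverse_dynamics(fetal, ang, F, 0.303)
        rc = fetal.calcaneus_position(np.zeros(2), q)
        hip_expect = -(rc[0] * F[0, 1] - rc[1] * F[0, 0])
        assert tau[2, 0] == pytest.approx(hip_expect, rel=1e-6)

    def test_static_moments_linear_in_force(self, fetal):
        q = np.array([-1.3, 0.4, fetal.ankle_locked_angle])
        ang = self.static_series(fetal, q)
        F = np.tile([0.2, 0.45], (5, 1))
        t1 = inverse_dynamics(fetal, ang, F, 0.303)
        t2 = inverse_dynamics(fetal, ang, 2 * F, 0.303)
        assert np.allclose(t2, 2 * t1, atol=1e-15)

    def test_too_short_series_rejected(self, fetal):
        ang = self.static_series(fetal,
                                 np.array([-1.3, 0.4, fetal.ankle_locked_angle]),
                                 n=2)
        with pytest.raises(ConfigurationError):
            inverse_dynamics(fetal, ang, np.zeros((2, 2)), 0.303)


def brute_force_grid(R_torque, M, step=1e-3):
    """Exhaustive grid oracle: minimize sum(a^2) on the moment constraint.

    For one moment row and three muscles the first two activations are
    gridded and the third is eliminated through the constraint, so every
    candidate satisfies the moment balance exactly.
    """
    t = R_torque[0]

    def search(lo1, hi1, lo2, hi2, h):
        a1, a2 = np.meshgrid(np.arange(lo1, hi1 + h / 2, h),
                             np.arange(lo2, hi2 + h / 2, h), indexing="ij")
        a3 = (M[0] - t[0] * a1 - t[1] * a2) / t[2]
        ok = (a3 >= 0.0) & (a3 <= 1.0)
        cost = np.where(ok, a1**2 + a2**2 + a3**2, np.inf)
        i = np.unravel_index(np.argmin(cost), cost.shape)
        return np.array([a1[i], a2[i], a3[i]])

    best = search(0.0, 1.0, 0.0, 1.0, step)
    for h in (step / 10, step / 100):
        lo = np.clip(best[:2] - 15 * h, 0, 1)
        hi = np.clip(best[:2] + 15 * h, 0, 1)
        best = search(lo[0], hi[0], lo[1], hi[1], h)
    return best


class TestStaticOptimization:
    def test_single_muscle_closed_form(self):
        r, fmax, M = 0.05, 1000.0, 20.0
        a, _ = solve_frame(np.array([[r * fmax]]), np.array([M]))
        assert a[0] == pytest.approx(M / (r * fmax), abs=1e-6)

    def test_two_muscle_closed_form(self):
        r = np.array([0.03, 0.05])
        fmax = np.array([500.0, 1000.0])
        M = 10.0
        a, _ = solve_frame((r * fmax)[None, :], np.array([M]))
        F = a * fmax
        expect = r * fmax**2 * M / np.sum(r**2 * fmax**2)
        assert np.allclose(F, expect, atol=1e-6)

    def test_three_muscle_toy_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            r = rng.uniform(0.01, 0.06, size=3)
            fmax = rng.uniform(200, 1500, size=3)
            M = np.array([rng.uniform(2, 15)])
            R_torque = (r * fmax)[None, :]
            a, _ = solve_frame(R_torque, M)
            a_grid = brute_force_grid(R_torque, M)
            assert np.allclose(a * fmax, a_grid * fmax, atol=1e-2)

    def test_activations_bounded_and_forces_nonnegative(self):
        # a huge moment saturates the muscle at its upper bound
        a, res = solve_frame(np.array([[0.005 * 100.0]]), np.array([50.0]))
        assert 0.0 <= a[0] <= 1.0
        assert a[0] == pytest.approx(1.0, abs=1e-9)
        assert res[0] == pytest.approx(50.0 - 0.5, abs=1e-6)


class TestRunKick:
    def make_kick(self, model, force_scale=1.0, n=7):
        alpha = np.linspace(-1.7, -1.1, n)
        phi = np.linspace(0.9, 0.15, n)
        hip = np.zeros((n, 2))
        K, A = [], []
        for a, p in zip(alpha, phi):
            k, an, _ = model.joint_positions(
                np.zeros(2), np.array([a, p, model.ankle_locked_angle]))
            K.append(k)
            A.append(an)
        defl = np.array([0, 0, 0, 0.3, 1.2, 2.8, 4.0])
        direction = -(np.array(A[-1]) / np.linalg.norm(A[-1]))
        force = (defl / defl.max())[:, None] * 0.3 * force_scale \
            * direction[None, :]
        return KickInput(hip_mm=hip, knee_mm=np.array(K) * 1e3,
                         ankle_mm=np.array(A) * 1e3, force_n=force,
                         frame_interval_s=0.303)

    def test_zero_force_static_pose_gives_tiny_forces(self, fetal):
        n = 6
        q = np.array([-1.4, 0.5, fetal.ankle_locked_angle])
        k, a, _ = fetal.joint_positions(np.zeros(2), q)
        kick = KickInput(hip_mm=np.zeros((n, 2)),
                         knee_mm=np.tile(k, (n, 1)) * 1e3,
                         ankle_mm=np.tile(a, (n, 1)) * 1e3,
                         force_n=np.zeros((n, 2)), frame_interval_s=0.303)
        res = run_kick(fetal, kick)
        assert max(res.forces.per_muscle_max.values()) < 0.1

    def test_moment_balance_reproduced(self, fetal):
        kick = self.make_kick(fetal)
        res = run_kick(fetal, kick)
        fmax = np.array([m.fmax_n for m in fetal.muscles])
        for i in range(len(res.moments_nm)):
            R = fetal.moment_arms(res.angles.q(i))
            lhs = R @ (res.forces.forces_n[i]) + res.forces.reserves_nm[i]
            scale = max(np.abs(res.moments_nm[i]).max(), 1e-9)
            assert np.allclose(lhs, res.moments_nm[i], atol=1e-6 * scale + 1e-12)

    def test_group_maxima_monotone_in_external_force(self, fetal):
        # statics: scaling the external force up never decreases the maxima
        maxima = []
        for s in (1.0, 2.0, 4.0):
            res = run_kick(fetal, self.make_kick(fetal, force_scale=s))
            maxima.append((res.forces.group_max("knee"),
                           res.forces.group_max("hip")))
        for (k1, h1), (k2, h2) in zip(maxima, maxima[1:]):
            assert k2 >= k1 - 1e-9
            assert h2 >= h1 - 1e-9
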