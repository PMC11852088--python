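"""Musculoskeletal arm: muscle curves, geometry, rigid-body dynamics."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroarm.arm import (ArmModel, ArmParams, ArmState, MuscleParams,
                          activation_rate, force_length, force_velocity)

RNG = np.random.default_rng(42)


class TestMuscleCurves:
    def test_force_length_peak_and_value(self):
        assert force_length(1.0, 0.4) == pytest.approx(1.0)
        assert force_length(1.2, 0.4) == pytest.approx(np.exp(-0.25), abs=1e-12)

    @given(delta=st.floats(0.0, 0.8), width=st.floats(0.1, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_force_length_symmetric_bell(self, delta, width):
        lo = force_length(1.0 - delta, width)
        hi = force_length(1.0 + delta, width)
        assert lo == pytest.approx(hi, rel=1e-12)
        assert 0.0 < lo <= 1.0

    def test_force_length_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            force_length(0.0)

    def test_force_velocity_anchors(self):
        assert force_velocity(0.0) == pytest.approx(1.0)
        assert force_velocity(-1.0) == pytest.approx(0.0)
        assert force_velocity(-2.0) == pytest.approx(0.0)
        assert force_velocity(1e9) == pytest.approx(1.5, rel=1e-6)

    def test_force_velocity_monotone_continuous(self):
        v = np.linspace(-1.5, 3.0, 2001)
        fv = force_velocity(v)
        assert np.all(np.diff(fv) >= -1e-12)
        assert np.max(np.abs(np.diff(fv))) < 0.02  # no jumps at this sampling

    def test_activation_rate_examples(self):
        # step-up from rest and step-down from full activation
        assert activation_rate(np.array([0.0]), np.array([1.0]),
                               np.array([0.015]), np.array([0.05])
                               )[0] == pytest.approx(1 / (0.015 * 0.5))
        assert activation_rate(np.array([1.0]), np.array([0.0]),
                               np.array([0.015]), np.array([0.05])
                               )[0] == pytest.approx(-2.0 / 0.05)

    @given(a=st.floats(0.0, 1.0, allow_subnormal=False),
           e=st.floats(0.0, 1.0, allow_subnormal=False))
    @settings(deadline=None, max_examples=50)
    def test_activation_fixed_point_and_sign(self, a, e):
        rate = activation_rate(np.array([a]), np.array([e]),
                               np.array([0.015]), np.array([0.05]))[0]
        if e == a:
            assert rate == 0.0
        else:
            assert np.sign(rate) == np.sign(e - a)


class TestGeometry:
    def test_moment_arms_match_length_gradient(self, arm):
        for _ in range(30):
            q = RNG.uniform([0.2, 1.0], [1.5, 2.3])
            geom = arm.muscle_geometry(q)
            eps = 1e-6
            for j in range(2):
                qp, qm = q.copy(), q.copy()
                qp[j] += eps
                qm[j] -= eps
                grad = (arm.muscle_geometry(qp).lengths
                        - arm.muscle_geometry(qm).lengths) / (2 * eps)
                np.testing.assert_allclose(-grad, geom.moment_arms[:, j], atol=1e-6)

    def test_monoarticular_muscles_span_one_joint(self, arm):
        q = np.array([0.7, 1.6])
        geom = arm.muscle_geometry(q)
        names = [m.name for m in arm.muscles]
        sh = names.index("shoulder_flexor"), names.index("shoulder_extensor")
        el = names.index("elbow_flexor"), names.index("elbow_extensor")
        for i in sh:
            assert abs(geom.moment_arms[i, 1]) < 1e-12
        for i in el:
            assert abs(geom.moment_arms[i, 0]) < 1e-12

    def test_agonist_antagonist_arm_signs(self, arm):
        q = arm.reference_posture
        r = arm.muscle_geometry(q).moment_arms
        assert r[0, 0] > 0 > r[1, 0]          # shoulder pair
        assert r[2, 1] > 0 > r[3, 1]          # elbow pair
        assert r[4, 0] > 0 and r[4, 1] > 0    # biarticular flexor
        assert r[5, 0] < 0 and r[5, 1] < 0    # biarticular extensor

    def test_lengths_continuous(self, arm):
        q = np.array([0.6, 1.7])
        l0 = arm.muscle_geometry(q).lengths
        l1 = arm.muscle_geometry(q + 1e-9).lengths
        assert np.max(np.abs(l1 - l0)) < 1e-8


class TestKinematics:
    def test_forward_kinematics_conventions(self, arm):
        p = arm.params
        hand = arm.forward_kinematics(np.array([0.0, 0.0]))
        np.testing.assert_allclose(hand, p.shoulder + [p.l1 + p.l2, 0], atol=1e-12)
        hand = arm.forward_kinematics(np.array([np.pi / 2, 0.0]))
        np.testing.assert_allclose(hand, p.shoulder + [0, p.l1 + p.l2], atol=1e-12)

    def test_jacobian_matches_finite_difference(self, arm):
        for _ in range(10):
            q = RNG.uniform([0.2, 0.5], [1.5, 2.5])
            J = arm.hand_jacobian(q)
            eps = 1e-7
            for j in range(2):
                qp, qm = q.copy(), q.copy()
                qp[j] += eps
                qm[j] -= eps
                col = (arm.forward_kinematics(qp) - arm.forward_kinematics(qm)) / (2 * eps)
                np.testing.assert_allclose(col, J[:, j], atol=1e-6)

    def test_jacobian_singular_iff_elbow_straight(self, arm):
        assert abs(np.linalg.det(arm.hand_jacobian(np.array([0.5, 0.0])))) < 1e-12
        assert abs(np.linalg.det(arm.hand_jacobian(np.array([0.5, np.pi])))) < 1e-12
        assert abs(np.linalg.det(arm.hand_jacobian(np.array([0.5, 1.2])))) > 1e-3

    def test_velocity_matches_position_differences(self, arm):
        q = np.array([0.5, 1.5])
        dq = np.array([0.7, -0.4])
        dt = 1e-7
        _, vel = arm.forward_kinematics(q, dq)
        fd = (arm.forward_kinematics(q + dq * dt) - arm.forward_kinematics(q - dq * dt)) / (2 * dt)
        np.testing.assert_allclose(vel, fd, atol=1e-6)

    def test_inverse_kinematics_roundtrip_and_reachability(self, arm):
        for _ in range(50):
            q = RNG.uniform([0.1, 0.3], [1.6, 2.6])
            hand = arm.forward_kinematics(q)
            q_rt = arm.inverse_kinematics(hand, elbow_up=True)
            np.testing.assert_allclose(arm.forward_kinematics(q_rt), hand, atol=1e-9)
        with pytest.raises(ValueError, match="unreachable"):
            arm.inverse_kinematics(np.array([0.0, arm.params.l1 + arm.params.l2 + 1e-3]))


class TestMuscleForces:
    def test_zero_activation_zero_force(self, arm):
        state = ArmState(arm.reference_posture, np.zeros(2), np.zeros(6))
        np.testing.assert_array_equal(arm.muscle_forces(state), np.zeros(6))

    def test_isometric_at_optimal_length_gives_fmax(self, arm):
        # at the reference posture all l0 were set to the path lengths
        state = ArmState(arm.reference_posture, np.zeros(2), np.ones(6))
        np.testing.assert_allclose(arm.muscle_forces(state), arm.fmax, rtol=1e-12)

    def test_forces_nonnegative_and_monotone_in_activation(self, arm):
        q = np.array([0.8, 1.4])
        dq = np.array([1.0, -2.0])
        lo = arm.muscle_forces(ArmState(q, dq, np.full(6, 0.3)))
        hi = arm.muscle_forces(ArmState(q, dq, np.full(6, 0.6)))
        assert np.all(lo >= 0)
        assert np.all(hi >= lo)


def _symbolic_dynamics():
    """Independent Lagrangian derivation of the 2-link equations of motion."""
    t = sp.symbols("t")
    l1, m1, m2, d1, d2, I1, I2 = sp.symbols("l1 m1 m2 d1 d2 I1 I2", positive=True)
    q1, q2 = sp.Function("q1")(t), sp.Function("q2")(t)
    c1 = d1 * sp.Matrix([sp.cos(q1), sp.sin(q1)])
    elbow = l1 * sp.Matrix([sp.cos(q1), sp.sin(q1)])
    c2 = elbow + d2 * sp.Matrix([sp.cos(q1 + q2), sp.sin(q1 + q2)])
    v1, v2 = c1.diff(t), c2.diff(t)
    T = (m1 * (v1.T @ v1)[0] + m2 * (v2.T @ v2)[0]) / 2 \
        + I1 * sp.diff(q1, t) ** 2 / 2 + I2 * sp.diff(q1 + q2, t) ** 2 / 2
    qs = [q1, q2]
    lhs = []
    for qi in qs:
        dqi = sp.diff(qi, t)
        lhs.append(sp.diff(sp.diff(T, dqi), t) - sp.diff(T, qi))
    subs = {sp.Derivative(q1, (t, 2)): sp.Symbol("qdd1"),
            sp.Derivative(q2, (t, 2)): sp.Symbol("qdd2"),
            sp.Derivative(q1, t): sp.Symbol("dq1"),
            sp.Derivative(q2, t): sp.Symbol("dq2"),
            q1: sp.Symbol("q1"), q2: sp.Symbol("q2")}
    lhs = [sp.simplify(expr.subs(subs)) for expr in lhs]
    syms = (sp.Symbol("q1"), sp.Symbol("q2"), sp.Symbol("dq1"), sp.Symbol("dq2"),
            sp.Symbol("qdd1"), sp.Symbol("qdd2"), l1, m1, m2, d1, d2, I1, I2)
    return sp.lambdify(syms, lhs, "numpy")


class TestDynamics:
    def test_rest_without_forces_stays_at_rest(self, arm):
        state = ArmState(np.array([0.7, 1.5]), np.zeros(2), np.zeros(6))
        np.testing.assert_allclose(
            arm.arm_dynamics(state, np.zeros(6)), np.zeros(2), atol=1e-15)

    def test_matches_symbolic_lagrangian_oracle(self, arm):
        oracle = _symbolic_dynamics()
        p = arm.params
        for _ in range(100):
            q = RNG.uniform([0.1, 0.3], [1.6, 2.6])
            dq = RNG.normal(size=2) * 3
            tau = RNG.normal(size=2) * 5
            qdd = np.linalg.solve(arm.mass_matrix(q), tau - arm.coriolis(q, dq))
            resid = np.array(oracle(q[0], q[1], dq[0], dq[1], qdd[0], qdd[1],
                                    p.l1, p.m1, p.m2, p.d1, p.d2, p.I1, p.I2))
            np.testing.assert_allclose(resid, tau, atol=1e-9)

    def test_passive_energy_conservation(self, arm):
        # passive swing (no muscles, no gravity): kinetic energy is conserved
        q = np.array([0.8, 1.2])
        dq = np.array([1.0, -0.5])
        e0 = arm.kinetic_energy(q, dq)
        dt = 0.005
        for _ in range(200):  # 1 s at 5 ms, RK4
            def rates(y):
                st = ArmState(y[:2], y[2:], np.zeros(6))
                return np.concatenate([y[2:], arm.arm_dynamics(st, np.zeros(6))])
            y = np.concatenate([q, dq])
            k1 = rates(y)
            k2 = rates(y + 0.5 * dt * k1)
            k3 = rates(y + 0.5 * dt * k2)
            k4 = rates(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            q, dq = y[:2], y[2:]
        assert abs(arm.kinetic_energy(q, dq) - e0) < 1e-6

    def test_jacobian_transpose_virtual_work(self, arm):
        for _ in range(50):
            q = RNG.uniform([0.2, 0.5], [1.5, 2.5])
            dq = RNG.normal(size=2)
            force = RNG.normal(size=2) * 10
            J = arm.hand_jacobian(q)
            power_task = force @ (J @ dq)
            power_joint = (J.T @ force) @ dq
            assert power_task == pytest.approx(power_joint, rel=1e-12, abs=1e-12)


class TestValidation:
    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            ArmParams(l1=-0.1)
        with pytest.raises(ValueError):
            MuscleParams(name="m", origin_segment="torso", origin=[0, 0],
                         insertion_segment="upper", insertion=[0.1, 0],
                         l0=0.0, fmax=100.0)

    def test_requires_six_muscles(self, arm):
        with pytest.raises(ValueError, match="6 muscles"):
            ArmModel(arm.params, arm.muscles[:3])
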