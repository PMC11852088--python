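"""Robot dynamics, kinematics, curl field, and the hand/end-effector
coupling constraint."""

import numpy as np
import pytest
import sympy as sp

from neuroarm.arm import ArmState
from neuroarm.robot import (CoupledState, CurlFieldParams, RobotModel,
                            RobotParams, RobotState, coupled_accelerations,
                            curl_field_force)

RNG = np.random.default_rng(11)


@pytest.fixture(scope="module")
def robot():
    return RobotModel()


class TestRobotDynamics:
    def test_rest_equilibrium(self, robot):
        state = RobotState(np.array([0.5, 1.2]), np.zeros(2))
        np.testing.assert_allclose(
            robot.dynamics(state, np.zeros(2)), np.zeros(2), atol=1e-15)

    def test_matches_symbolic_lagrangian(self, robot):
        t = sp.symbols("t")
        l1s, m1s, m2s, d1s, d2s, I1s, I2s = sp.symbols(
            "l1 m1 m2 d1 d2 I1 I2", positive=True)
        q1, q2 = sp.Function("q1")(t), sp.Function("q2")(t)
        c1 = d1s * sp.Matrix([sp.cos(q1), sp.sin(q1)])
        c2 = l1s * sp.Matrix([sp.cos(q1), sp.sin(q1)]) \
            + d2s * sp.Matrix([sp.cos(q1 + q2), sp.sin(q1 + q2)])
        v1, v2 = c1.diff(t), c2.diff(t)
        T = (m1s * (v1.T @ v1)[0] + m2s * (v2.T @ v2)[0]) / 2 \
            + I1s * sp.diff(q1, t) ** 2 / 2 + I2s * sp.diff(q1 + q2, t) ** 2 / 2
        lhs = []
        for qi in (q1, q2):
            dqi = sp.diff(qi, t)
            lhs.append(sp.diff(sp.diff(T, dqi), t) - sp.diff(T, qi))
        subs = {sp.Derivative(q1, (t, 2)): sp.Symbol("qdd1"),
                sp.Derivative(q2, (t, 2)): sp.Symbol("qdd2"),
                sp.Derivative(q1, t): sp.Symbol("dq1"),
                sp.Derivative(q2, t): sp.Symbol("dq2"),
                q1: sp.Symbol("a1"), q2: sp.Symbol("a2")}
        fn = sp.lambdify((sp.Symbol("a1"), sp.Symbol("a2"), sp.Symbol("dq1"),
                          sp.Symbol("dq2"), sp.Symbol("qdd1"), sp.Symbol("qdd2"),
                          l1s, m1s, m2s, d1s, d2s, I1s, I2s),
                         [sp.simplify(x.subs(subs)) for x in lhs], "numpy")
        p = robot.params
        for _ in range(50):
            th = RNG.uniform([0.1, 0.3], [1.6, 2.6])
            dth = RNG.normal(size=2) * 3
            tau = RNG.normal(size=2) * 2
            thdd = robot.dynamics(RobotState(th, dth), tau)
            resid = np.array(fn(th[0], th[1], dth[0], dth[1], thdd[0], thdd[1],
                                p.l1, p.m1, p.m2, p.d1, p.d2, p.I1, p.I2))
            np.testing.assert_allclose(resid, tau, atol=1e-9)

    def test_passive_energy_conservation(self, robot):
        th = np.array([0.8, 1.0])
        dth = np.array([2.0, -1.0])
        e0 = robot.kinetic_energy(th, dth)
        dt = 0.005
        y = np.concatenate([th, dth])
        for _ in range(200):
            def rates(v):
                return np.concatenate(
                    [v[2:], robot.dynamics(RobotState(v[:2], v[2:]), np.zeros(2))])
            k1 = rates(y)
            k2 = rates(y + 0.5 * dt * k1)
            k3 = rates(y + 0.5 * dt * k2)
            k4 = rates(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert abs(robot.kinetic_energy(y[:2], y[2:]) - e0) < 1e-6

    def test_endpoint_force_enters_through_jacobian(self, robot):
        th = np.array([0.7, 1.3])
        state = RobotState(th, np.zeros(2))
        f = np.array([1.5, -2.0])
        direct = robot.dynamics(state, np.zeros(2), endpoint_force=f)
        via_torque = robot.dynamics(state, robot.jacobian(th).T @ f)
        np.testing.assert_allclose(direct, via_torque, atol=1e-14)


class TestRobotKinematics:
    def test_full_reach_configuration(self, robot):
        p = robot.params
        ee = robot.kinematics(np.array([0.0, 0.0]))
        np.testing.assert_allclose(ee, p.base + [p.l1 + p.l2, 0], atol=1e-12)

    def test_jacobian_finite_difference(self, robot):
        for _ in range(10):
            th = RNG.uniform([0.1, 0.4], [1.5, 2.4])
            J = robot.jacobian(th)
            eps = 1e-7
            for j in range(2):
                tp, tm = th.copy(), th.copy()
                tp[j] += eps
                tm[j] -= eps
                col = (robot.kinematics(tp) - robot.kinematics(tm)) / (2 * eps)
                np.testing.assert_allclose(col, J[:, j], atol=1e-6)

    def test_singularity_at_straight_elbow(self, robot):
        assert abs(np.linalg.det(robot.jacobian(np.array([0.3, 0.0])))) < 1e-12

    def test_inverse_kinematics_roundtrip(self, robot):
        for _ in range(100):
            th = RNG.uniform([-1.0, 0.2], [1.5, 2.8])
            point = robot.kinematics(th)
            th_rt = robot.inverse_kinematics(point, elbow_up=True)
            np.testing.assert_allclose(robot.kinematics(th_rt), point, atol=1e-9)

    def test_unreachable_point_raises(self, robot):
        p = robot.params
        far = p.base + np.array([p.l1 + p.l2 + 1e-3, 0.0])
        with pytest.raises(ValueError, match="unreachable"):
            robot.inverse_kinematics(far)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            RobotParams(m1=-1.0)


class TestCurlField:
    def test_zero_velocity_zero_force(self):
        f = curl_field_force(CurlFieldParams(b=3.0), np.zeros(2))
        np.testing.assert_array_equal(f, np.zeros(2))

    def test_clockwise_example(self):
        f = curl_field_force(CurlFieldParams(b=3.0), np.array([0.1, 0.0]))
        np.testing.assert_allclose(f, [0.0, -0.3], atol=1e-15)

    def test_always_perpendicular(self):
        params = CurlFieldParams(b=-3.0)
        for _ in range(50):
            v = RNG.normal(size=2)
            f = curl_field_force(params, v)
            assert abs(f @ v) < 1e-12


class TestCoupling:
    def _coupled_at_rest(self, arm, robot):
        start = np.array([0.0, 0.40])
        q = arm.inverse_kinematics(start)
        th = robot.inverse_kinematics(start)
        return CoupledState(ArmState(q, np.zeros(2), np.zeros(6)),
                            RobotState(th, np.zeros(2)))

    def test_rest_zero_inputs_zero_everything(self, arm, robot):
        coupled = self._coupled_at_rest(arm, robot)
        qdd, thdd, f = coupled_accelerations(arm, robot, coupled,
                                             np.zeros(6), np.zeros(2))
        np.testing.assert_allclose(qdd, np.zeros(2), atol=1e-10)
        np.testing.assert_allclose(thdd, np.zeros(2), atol=1e-10)
        np.testing.assert_allclose(f.on_human, np.zeros(2), atol=1e-10)

    def test_action_reaction_exact(self, arm, robot):
        coupled = self._coupled_at_rest(arm, robot)
        coupled.arm.act[:] = RNG.uniform(0, 0.3, 6)
        _, _, f = coupled_accelerations(arm, robot, coupled,
                                        arm.muscle_forces(coupled.arm),
                                        np.array([0.5, -0.2]))
        np.testing.assert_array_equal(f.on_robot, -f.on_human)

    def test_constraint_force_consistency_with_free_bodies(self, arm, robot):
        """Applying the returned interaction force to each free body alone
        reproduces the coupled accelerations."""
        coupled = self._coupled_at_rest(arm, robot)
        coupled.arm.dq[:] = [0.4, -0.6]
        # give the robot the matching end-effector velocity
        Jr = robot.jacobian(coupled.robot.theta)
        Jh = arm.hand_jacobian(coupled.arm.q)
        coupled.robot.dtheta[:] = np.linalg.solve(Jr, Jh @ coupled.arm.dq)
        coupled.arm.act[:] = RNG.uniform(0, 0.4, 6)
        forces = arm.muscle_forces(coupled.arm)
        torques = np.array([0.3, 0.1])
        qdd, thdd, f = coupled_accelerations(arm, robot, coupled, forces, torques)
        free_arm = arm.arm_dynamics(coupled.arm, forces, hand_force=f.on_human)
        free_robot = robot.dynamics(coupled.robot, torques,
                                    endpoint_force=f.on_robot)
        np.testing.assert_allclose(qdd, free_arm, atol=1e-9)
        np.testing.assert_allclose(thdd, free_robot, atol=1e-9)

    def test_constraint_drift_stays_small(self, arm, robot):
        """1 s of coupled passive motion keeps the hand/end-effector gap
        below 1e-6 m (Baumgarte-stabilized integration)."""
        coupled = self._coupled_at_rest(arm, robot)
        coupled.arm.act[:] = 0.05  # gentle muscle pull to get motion
        dt = 0.005
        max_gap = 0.0
        for _ in range(200):
            def rates(y):
                cs = CoupledState(ArmState(y[0:2], y[2:4], coupled.arm.act),
                                  RobotState(y[4:6], y[6:8]))
                qdd, thdd, _ = coupled_accelerations(
                    arm, robot, cs, arm.muscle_forces(cs.arm), np.zeros(2))
                return np.concatenate([y[2:4], qdd, y[6:8], thdd])
            y = np.concatenate([coupled.arm.q, coupled.arm.dq,
                                coupled.robot.theta, coupled.robot.dtheta])
            k1 = rates(y)
            k2 = rates(y + 0.5 * dt * k1)
            k3 = rates(y + 0.5 * dt * k2)
            k4 = rates(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            coupled.arm.q, coupled.arm.dq = y[0:2], y[2:4]
            coupled.robot.theta, coupled.robot.dtheta = y[4:6], y[6:8]
            gap = np.linalg.norm(arm.forward_kinematics(coupled.arm.q)
                                 - robot.kinematics(coupled.robot.theta))
            max_gap = max(max_gap, gap)
        assert max_gap < 1e-6

    def test_coupled_passive_energy_conservation(self, arm, robot):
        """Zero muscle forces, torques and field: total kinetic energy of the
        constrained pair is conserved."""
        coupled = self._coupled_at_rest(arm, robot)
        coupled.arm.dq[:] = [0.5, -0.3]
        Jr = robot.jacobian(coupled.robot.theta)
        Jh = arm.hand_jacobian(coupled.arm.q)
        coupled.robot.dtheta[:] = np.linalg.solve(Jr, Jh @ coupled.arm.dq)
        e0 = (arm.kinetic_energy(coupled.arm.q, coupled.arm.dq)
              + robot.kinetic_energy(coupled.robot.theta, coupled.robot.dtheta))
        dt = 0.005
        y = np.concatenate([coupled.arm.q, coupled.arm.dq,
                            coupled.robot.theta, coupled.robot.dtheta])
        for _ in range(200):
            def rates(v):
                cs = CoupledState(ArmState(v[0:2], v[2:4], np.zeros(6)),
                                  RobotState(v[4:6], v[6:8]))
                qdd, thdd, _ = coupled_accelerations(arm, robot, cs,
                                                     np.zeros(6), np.zeros(2))
                return np.concatenate([v[2:4], qdd, v[6:8], thdd])
            k1 = rates(y)
            k2 = rates(y + 0.5 * dt * k1)
            k3 = rates(y + 0.5 * dt * k2)
            k4 = rates(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        e1 = (arm.kinetic_energy(y[0:2], y[2:4])
              + robot.kinetic_energy(y[4:6], y[6:8]))
        assert abs(e1 - e0) < 1e-6
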