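"""Two-link planar robot, rigid hand/end-effector coupling, and the
velocity-dependent curl force field.

The human hand is attached to the robot's end-effector through a revolute
joint: the attachment transmits force but no torque, which is modeled as a
2-D position constraint between the hand and the end-effector.  The coupled
equations of motion are solved together with the acceleration-level
constraint (Lagrange multipliers), so the constraint force *is* the
interaction force, with action-reaction exact by construction.  Baumgarte
stabilization removes numerical drift of the position/velocity constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm import ArmModel, ArmState, MuscleGeometry

__all__ = [
    "RobotParams",
    "RobotState",
    "RobotModel",
    "CurlFieldParams",
    "InteractionForce",
    "curl_field_force",
    "coupled_accelerations",
]


@dataclass
class RobotParams:
    """Symmetric 2-link robot parameters (SI units)."""

    l1: float = 0.3
    l2: float = 0.3
    m1: float = 0.5
    m2: float = 0.5
    d1: float = 0.15
    d2: float = 0.15
    I1: float = 5e-3
    I2: float = 5e-3
    base: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.75]))

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        for name in ("l1", "l2", "m1", "m2", "d1", "d2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"robot parameter {name!r} must be positive")


@dataclass
class RobotState:
    theta: np.ndarray    # (2,) rad
    dtheta: np.ndarray   # (2,) rad/s

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.dtheta = np.asarray(self.dtheta, dtype=float)

    def copy(self) -> "RobotState":
        return RobotState(self.theta.copy(), self.dtheta.copy())


@dataclass
class CurlFieldParams:
    """Velocity-dependent curl field F = b [[0, 1], [-1, 0]] v."""

    b: float = 0.0   # N s/m; positive = clockwise, 0 disables

    @property
    def rotation(self) -> np.ndarray:
        return np.array([[0.0, 1.0], [-1.0, 0.0]])


@dataclass
class InteractionForce:
    """Constraint force at the revolute coupling."""

    on_human: np.ndarray   # (2,) N, applied at the hand

    @property
    def on_robot(self) -> np.ndarray:
        return -self.on_human


def curl_field_force(params: CurlFieldParams, velocity: np.ndarray) -> np.ndarray:
    """Perturbing force perpendicular to the hand velocity."""
    v = np.asarray(velocity, dtype=float)
    return params.b * (params.rotation @ v)


class RobotModel:
    """Kinematics and rigid-body dynamics of the 2-link robot."""

    def __init__(self, params: RobotParams | None = None):
        self.params = params if params is not None else RobotParams()

    def elbow_position(self, theta: np.ndarray) -> np.ndarray:
        p = self.params
        return p.base + p.l1 * np.array([np.cos(theta[0]), np.sin(theta[0])])

    def kinematics(self, theta: np.ndarray, dtheta: np.ndarray | None = None):
        """End-effector position (and velocity plus Jacobian if dtheta given)."""
        p = self.params
        t12 = theta[0] + theta[1]
        ee = self.elbow_position(theta) + p.l2 * np.array([np.cos(t12), np.sin(t12)])
        if dtheta is None:
            return ee
        J = self.jacobian(theta)
        return ee, J @ np.asarray(dtheta, dtype=float), J

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        p = self.params
        s1, c1 = np.sin(theta[0]), np.cos(theta[0])
        s12, c12 = np.sin(theta[0] + theta[1]), np.cos(theta[0] + theta[1])
        return np.array([
            [-p.l1 * s1 - p.l2 * s12, -p.l2 * s12],
            [p.l1 * c1 + p.l2 * c12, p.l2 * c12],
        ])

    def jacobian_dot(self, theta: np.ndarray, dtheta: np.ndarray) -> np.ndarray:
        p = self.params
        d1, d12 = dtheta[0], dtheta[0] + dtheta[1]
        c1, s1 = np.cos(theta[0]), np.sin(theta[0])
        c12, s12 = np.cos(theta[0] + theta[1]), np.sin(theta[0] + theta[1])
        return np.array([
            [-p.l1 * c1 * d1 - p.l2 * c12 * d12, -p.l2 * c12 * d12],
            [-p.l1 * s1 * d1 - p.l2 * s12 * d12, -p.l2 * s12 * d12],
        ])

    def inverse_kinematics(self, point: np.ndarray, elbow_up: bool = True) -> np.ndarray:
        p = self.params
        rel = np.asarray(point, dtype=float) - p.base
        r2 = float(rel @ rel)
        c2 = (r2 - p.l1 ** 2 - p.l2 ** 2) / (2 * p.l1 * p.l2)
        if c2 > 1.0 + 1e-12 or c2 < -1.0 - 1e-12:
            r = np.sqrt(r2)
            dist = max(r - (p.l1 + p.l2), abs(p.l1 - p.l2) - r)
            raise ValueError(
                f"end-effector point {point} unreachable "
                f"(distance to workspace boundary {dist:.3f} m)")
        c2 = np.clip(c2, -1.0, 1.0)
        t2 = np.arccos(c2) if elbow_up else -np.arccos(c2)
        t1 = np.arctan2(rel[1], rel[0]) - np.arctan2(
            p.l2 * np.sin(t2), p.l1 + p.l2 * np.cos(t2))
        return np.array([t1, t2])

    def mass_matrix(self, theta: np.ndarray) -> np.ndarray:
        p = self.params
        c2 = np.cos(theta[1])
        a = p.I1 + p.I2 + p.m1 * p.d1 ** 2 + p.m2 * (
            p.l1 ** 2 + p.d2 ** 2 + 2 * p.l1 * p.d2 * c2)
        b = p.I2 + p.m2 * (p.d2 ** 2 + p.l1 * p.d2 * c2)
        c = p.I2 + p.m2 * p.d2 ** 2
        return np.array([[a, b], [b, c]])

    def coriolis(self, theta: np.ndarray, dtheta: np.ndarray) -> np.ndarray:
        p = self.params
        h = p.m2 * p.l1 * p.d2 * np.sin(theta[1])
        return np.array([
            -h * dtheta[1] ** 2 - 2 * h * dtheta[0] * dtheta[1],
            h * dtheta[0] ** 2,
        ])

    def dynamics(self, state: RobotState, torques: np.ndarray,
                 endpoint_force: np.ndarray | None = None) -> np.ndarray:
        """Joint accelerations; endpoint force enters through J^T."""
        tau = np.asarray(torques, dtype=float).copy()
        if endpoint_force is not None:
            tau += self.jacobian(state.theta).T @ np.asarray(endpoint_force, dtype=float)
        rhs = tau - self.coriolis(state.theta, state.dtheta)
        return np.linalg.solve(self.mass_matrix(state.theta), rhs)

    def kinetic_energy(self, theta: np.ndarray, dtheta: np.ndarray) -> float:
        return 0.5 * float(dtheta @ self.mass_matrix(theta) @ dtheta)


@dataclass
class CoupledState:
    """Human arm state plus robot state, constrained at the hand."""

    arm: ArmState
    robot: RobotState

    def copy(self) -> "CoupledState":
        return CoupledState(self.arm.copy(), self.robot.copy())


# Baumgarte stabilization rates (1/s) for the coupling constraint
BAUMGARTE_ALPHA = 20.0
BAUMGARTE_BETA = 20.0


def coupled_accelerations(arm: ArmModel, robot: RobotModel, coupled: CoupledState,
                          muscle_forces: np.ndarray, robot_torques: np.ndarray,
                          field: CurlFieldParams | None = None,
                          geom: MuscleGeometry | None = None):
    """Accelerations of the constrained human+robot system.

    Solves the two free-body equations together with the acceleration-level
    constraint (hand acceleration = end-effector acceleration, Baumgarte
    stabilized) for (q", theta", interaction force).  The curl field, when
    present, acts on the hand.
    """
    st, rs = coupled.arm, coupled.robot
    if geom is None:
        geom = arm.muscle_geometry(st.q, st.dq)
    Jh = arm.hand_jacobian(st.q)
    Jr = robot.jacobian(rs.theta)
    Mh = arm.mass_matrix(st.q)
    Mr = robot.mass_matrix(rs.theta)

    tau_h = geom.moment_arms.T @ np.asarray(muscle_forces, dtype=float)
    hand, hand_vel = arm.forward_kinematics(st.q, st.dq)
    if field is not None and field.b != 0.0:
        tau_h = tau_h + Jh.T @ curl_field_force(field, hand_vel)
    rhs_h = tau_h - arm.coriolis(st.q, st.dq)
    rhs_r = np.asarray(robot_torques, dtype=float) - robot.coriolis(rs.theta, rs.dtheta)

    ee, ee_vel, _ = robot.kinematics(rs.theta, rs.dtheta)
    gap = hand - ee
    gap_rate = hand_vel - ee_vel
    bias = (robot.jacobian_dot(rs.theta, rs.dtheta) @ rs.dtheta
            - arm.hand_jacobian_dot(st.q, st.dq) @ st.dq
            - 2.0 * BAUMGARTE_ALPHA * gap_rate
            - BAUMGARTE_BETA ** 2 * gap)

    # KKT system in (qdd, thdd, F_int); F_int acts on the hand, -F_int on
    # the robot end-effector
    kkt = np.zeros((6, 6))
    kkt[0:2, 0:2] = Mh
    kkt[0:2, 4:6] = -Jh.T
    kkt[2:4, 2:4] = Mr
    kkt[2:4, 4:6] = Jr.T
    kkt[4:6, 0:2] = Jh
    kkt[4:6, 2:4] = -Jr
    rhs = np.concatenate([rhs_h, rhs_r, bias])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("coupled system singular (both chains at a "
                           "kinematic singularity?)") from exc
    qdd, thdd, f_int = sol[0:2], sol[2:4], sol[4:6]
    return qdd, thdd, InteractionForce(on_human=f_int)
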