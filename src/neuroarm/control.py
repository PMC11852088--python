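"""Robot-side controllers.

The human-aware controller is a receding-horizon (NMPC) scheme: at every
control step it rolls the *whole* hierarchical human model forward over a
short prediction horizon under candidate robot torque profiles, scores each
candidate by the user's predicted neuromuscular effort (mean squared neural
excitation), and applies the first step of the best profile.  Torques over
the horizon are parameterized per joint by a 2nd-order polynomial in the
step index, so the decision vector is 6 coefficients.

The baseline is an end-effector impedance controller rendering a
spring-damper toward a time-advanced reference trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .engine import HolisticSimulator, SimState, SimulationResult
from .robot import RobotModel, RobotState

__all__ = [
    "NMPCConfig",
    "TorqueProfile",
    "ImpedanceParams",
    "ReferenceTrajectory",
    "evaluate_torque_profile",
    "rollout_objective",
    "nmpc_step",
    "impedance_torques",
    "shift_reference",
    "reference_from_result",
]

logger = logging.getLogger(__name__)


@dataclass
class NMPCConfig:
    """Human-aware controller settings.

    Coefficient bounds keep |T| <= beta0_bound + 2 * higher_order_bound over
    the horizon (an unconstrained effort objective with free torques is
    ill-posed); they are wide relative to the torques the task needs.
    """

    horizon: int = 50            # prediction horizon Np (steps)
    dt: float = 0.005            # control step (s)
    beta0_bound: float = 20.0    # N m
    higher_order_bound: float = 10.0   # max |beta1 k| and |beta2 k^2| over horizon
    tol: float = 1e-6            # optimizer tolerance on the effort objective
    max_evals: int = 40          # objective-evaluation budget per step
    warm_start: bool = True

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("prediction horizon must be >= 1")

    def bounds(self) -> list[tuple[float, float]]:
        np_ = self.horizon
        b0 = self.beta0_bound
        b1 = self.higher_order_bound / max(np_ - 1, 1)
        b2 = self.higher_order_bound / max(np_ - 1, 1) ** 2
        per_joint = [(-b0, b0), (-b1, b1), (-b2, b2)]
        return per_joint * 2


@dataclass
class TorqueProfile:
    """Per-joint polynomial torque profile T_j(k) = b0 + b1 k + b2 k^2."""

    beta: np.ndarray = field(default_factory=lambda: np.zeros((2, 3)))

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).reshape(2, 3)

    def evaluate(self, k: int) -> np.ndarray:
        return self.beta[:, 0] + self.beta[:, 1] * k + self.beta[:, 2] * k ** 2

    def shifted(self) -> "TorqueProfile":
        """The same torque sequence re-indexed one step later (T'(k) = T(k+1))."""
        b = self.beta
        return TorqueProfile(np.stack([
            b[:, 0] + b[:, 1] + b[:, 2],
            b[:, 1] + 2 * b[:, 2],
            b[:, 2],
        ], axis=1))


def evaluate_torque_profile(profile: TorqueProfile, k: int) -> np.ndarray:
    """Torque pair at step ``k`` within the horizon."""
    if k < 0:
        raise IndexError("step index within the horizon must be >= 0")
    return profile.evaluate(k)


def rollout_objective(sim: HolisticSimulator, snapshot: SimState,
                      profile: TorqueProfile, config: NMPCConfig,
                      use_fast: bool = True) -> float:
    """Predicted user effort: the holistic model is simulated forward
    ``horizon`` steps (noise-free) under the profile's torques, and the mean
    squared neural excitation over the horizon is returned.

    The human controller inside the rollout uses its precomputed gain
    schedules at the global step indices, held at their terminal values past
    the movement horizon.  The snapshot is not mutated.  ``use_fast`` selects
    the compiled rollout kernel (numerically identical to the reference
    stepping; asserted by the test suite).
    """
    if use_fast and snapshot.robot is not None and not sim.frozen_basis:
        from ._fastsim import rollout_effort

        b = snapshot.belief
        return float(rollout_effort(
            snapshot.arm.q, snapshot.arm.dq, snapshot.robot.theta,
            snapshot.robot.dtheta, snapshot.arm.act, snapshot.a_abs,
            b.xhat, b.xhat_delayed, b.meas_buffer, b.ctrl_buffer, b.head,
            snapshot.k, config.horizon, profile.beta,
            *sim.kernel_args()))
    state = snapshot.copy()
    saved_rng = sim.rng
    sim.rng = None            # predictions are deterministic
    try:
        total = 0.0
        for j in range(config.horizon):
            rec: dict = {}
            state = sim.step(state, torques=profile.evaluate(j), record=rec)
            e = rec["exc"]
            total += float(e @ e)
    finally:
        sim.rng = saved_rng
    return total / config.horizon


def nmpc_step(sim: HolisticSimulator, snapshot: SimState, config: NMPCConfig,
              warm_start: TorqueProfile | None = None) -> TorqueProfile:
    """One receding-horizon optimization of the 6 torque coefficients.

    Candidate starts are the zero profile and the one-step-shifted previous
    solution; a bounded quasi-Newton search with finite-difference gradients
    refines the better one.  The returned profile is never worse than either
    start.
    """
    bounds = config.bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = {"x": None, "J": np.inf}

    def objective(x: np.ndarray) -> float:
        J = rollout_objective(sim, snapshot, TorqueProfile(x.reshape(2, 3)), config)
        if J < best["J"]:
            best["J"], best["x"] = J, x.copy()
        return J

    starts = [np.zeros(6)]
    if warm_start is not None and config.warm_start:
        starts.insert(0, np.clip(warm_start.shifted().beta.ravel(), lo, hi))
    start_J = [objective(x) for x in starts]
    x0 = starts[int(np.argmin(start_J))]
    if best["J"] > config.tol:
        try:
            optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxfun": config.max_evals, "ftol": config.tol,
                         "eps": 1e-3})
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("NMPC optimizer failed (%s); using best evaluated "
                           "profile", exc)
    return TorqueProfile(best["x"].reshape(2, 3))


@dataclass
class ImpedanceParams:
    """End-effector spring-damper toward a time-advanced reference."""

    kp: float = 50.0        # N/m
    kd: float = 10.0        # N s/m
    time_shift: float = 0.050   # s, reference advance

    def __post_init__(self) -> None:
        if self.kp < 0 or self.kd < 0:
            raise ValueError("impedance gains must be non-negative")


@dataclass
class ReferenceTrajectory:
    """Uniformly sampled hand reference (positions and velocities)."""

    time: np.ndarray       # (N,)
    pos: np.ndarray        # (N, 2)
    vel: np.ndarray        # (N, 2)

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.pos) == len(self.vel)):
            raise ValueError("reference series must share their length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("reference time must be strictly increasing")

    def sample(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Sample by index; beyond the end the last sample is held with
        zero velocity (the target)."""
        if k >= len(self.time):
            return self.pos[-1], np.zeros(2)
        return self.pos[max(k, 0)], self.vel[max(k, 0)]


def reference_from_result(result: SimulationResult) -> ReferenceTrajectory:
    """The hand trajectory of a (scenario A) run as a tracking reference."""
    return ReferenceTrajectory(time=result.time.copy(),
                               pos=result.hand_pos.copy(),
                               vel=result.hand_vel.copy())


def shift_reference(traj: ReferenceTrajectory, shift_steps: int) -> ReferenceTrajectory:
    """Advance the reference ``shift_steps`` samples; the tail holds the
    final position (the target) with zero velocity."""
    if shift_steps < 0:
        raise ValueError("shift must be non-negative")
    if shift_steps == 0:
        return ReferenceTrajectory(traj.time.copy(), traj.pos.copy(), traj.vel.copy())
    n = len(traj.time)
    pos = np.vstack([traj.pos[shift_steps:], np.tile(traj.pos[-1], (min(shift_steps, n), 1))])
    vel = np.vstack([traj.vel[shift_steps:], np.zeros((min(shift_steps, n), 2))])
    return ReferenceTrajectory(traj.time.copy(), pos[:n], vel[:n])


def impedance_torques(robot: RobotModel, state: RobotState,
                      ref_pos: np.ndarray, ref_vel: np.ndarray,
                      params: ImpedanceParams) -> np.ndarray:
    """Joint torques rendering the end-effector spring-damper force."""
    ee, ee_vel, J = robot.kinematics(state.theta, state.dtheta)
    f = params.kp * (np.asarray(ref_pos) - ee) + params.kd * (np.asarray(ref_vel) - ee_vel)
    return J.T @ f
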