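"""Closed-loop orchestration of the sensorimotor hierarchy.

One simulator tick (``HolisticSimulator.step``) runs, in fixed order:

1. read the hand kinematics from the musculoskeletal plant;
2. compute the abstract command ``u`` from the current belief;
3. expand ``u`` to neural excitations (velocity compensation, non-negative
   decomposition onto the synergy basis, synergy recombination);
4. obtain robot torques from the active robot controller (if any);
5. update the belief with the delayed sensory measurement;
6. integrate the plant (arm, or arm+robot coupled, plus the curl field)
   one RK4 step at the control clock.

The measurement's kinematic channels come from the plant's forward
kinematics; the abstract-activation channels are the internal model's own
propagated activations (a self-consistent readout, since only hand position
and velocity are sensed from the body).

Scenarios: ``center_out`` / ``curl`` reproduce unconstrained reaching to 8
targets on a 12 cm circle (optionally in a velocity-dependent curl field);
``A`` is an uncoupled 25 cm reach, ``B`` the same reach pulling a passive
robot, ``C`` with the human-aware predictive controller, ``D`` with a
time-advanced impedance controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .arm import ArmModel, ArmState, activation_rate, default_arm, force_velocity
from .ofc import (BeliefState, InternalModelParams, OFCSolution, PlantModel,
                  build_cost_schedule, build_internal_model, estimate_state,
                  make_belief, solve_ofc)
from .robot import (CoupledState, CurlFieldParams, RobotModel, RobotState,
                    coupled_accelerations, curl_field_force)
from .synergies import (SynergySet, compensate_velocity, decompose_command,
                        expand_to_excitations, learn_synergies, task_basis)

__all__ = [
    "ScenarioConfig",
    "SimState",
    "SimulationResult",
    "MovementMetrics",
    "HolisticSimulator",
    "simulate_scenario",
    "run_center_out",
    "movement_metrics",
    "is_single_peaked",
]

DEFAULT_START = np.array([0.0, 0.40])   # hand start, anterior of the shoulder (m)


@dataclass
class ScenarioConfig:
    """Definition of one simulated experiment."""

    scenario: str = "A"                  # center_out | curl | A | B | C | D
    target: np.ndarray | None = None     # world hand target (m); default per scenario
    start: np.ndarray = dfield(default_factory=lambda: DEFAULT_START.copy())
    field_b: float = 0.0                 # curl gain (N s/m)
    seed: int | None = None              # noise seed; None = noise-free
    noise: bool = False
    params: InternalModelParams = dfield(default_factory=InternalModelParams)
    nmpc: "object | None" = None         # NMPCConfig for scenario C
    impedance: "object | None" = None    # ImpedanceParams for scenario D
    reference: "object | None" = None    # ReferenceTrajectory for scenario D
    synergy_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("center_out", "curl", "A", "B", "C", "D"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        self.start = np.asarray(self.start, dtype=float)
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)


@dataclass
class SimState:
    """Full state of the closed loop at one tick."""

    arm: ArmState
    belief: BeliefState
    a_abs: np.ndarray                 # internal model's propagated activations
    robot: RobotState | None = None
    k: int = 0

    def copy(self) -> "SimState":
        return SimState(self.arm.copy(), self.belief.copy(), self.a_abs.copy(),
                        self.robot.copy() if self.robot is not None else None,
                        self.k)


@dataclass
class SimulationResult:
    """Per-step time series of one scenario run (row i = end of step i)."""

    time: np.ndarray
    hand_pos: np.ndarray
    hand_vel: np.ndarray
    q: np.ndarray
    dq: np.ndarray
    act: np.ndarray
    exc: np.ndarray
    u_abstract: np.ndarray
    xhat: np.ndarray
    theta: np.ndarray            # NaN when uncoupled
    dtheta: np.ndarray
    torques: np.ndarray
    f_interaction: np.ndarray
    effort_inst: np.ndarray      # |e_k|^2
    start: np.ndarray = None
    target: np.ndarray = None
    scenario: str = ""
    dt: float = 0.005
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.time)

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.hand_vel, axis=1)

    @property
    def effort(self) -> float:
        """Mean squared excitation over the movement."""
        return float(np.mean(self.effort_inst))


@dataclass
class MovementMetrics:
    terminal_error: float        # m
    straightness: float          # max lateral deviation / reach distance
    peak_speed: float            # m/s
    peak_time_fraction: float    # argmax(speed) / duration, first maximum
    effort: float                # mean |e|^2
    co_contraction: float        # mean over pairs/time of min(agonist, antagonist)
    mean_agonist: float          # mean over pairs/time of max(agonist, antagonist)
    lateral_area: float          # signed area between path and straight line (m^2)
    max_lateral_dev: float       # m


class HolisticSimulator:
    """The assembled hierarchy for one reach, ready to step or roll out."""

    def __init__(self, config: ScenarioConfig, arm: ArmModel | None = None,
                 synergies: SynergySet | None = None,
                 robot: RobotModel | None = None,
                 solution: OFCSolution | None = None,
                 frozen_basis: bool = False):
        self.config = config
        self.params = config.params
        self.arm = arm if arm is not None else default_arm()
        self.synergies = (synergies if synergies is not None
                          else learn_synergies(self.arm, seed=config.synergy_seed))
        coupled = config.scenario in ("B", "C", "D")
        self.robot = robot if robot is not None else (RobotModel() if coupled else None)
        if not coupled:
            self.robot = robot  # keep None unless explicitly provided
        self.field = CurlFieldParams(b=config.field_b)
        self.start = config.start
        self.target = (config.target if config.target is not None
                       else config.start + np.array([-0.25, 0.0]))
        self.frozen_basis = frozen_basis
        self.model: PlantModel = build_internal_model(
            self.params, self.target - self.start)
        self.cost = build_cost_schedule(self.params)
        self.solution = (solution if solution is not None
                         else solve_ofc(self.model, self.cost, self.params))
        self.rng = (np.random.default_rng(config.seed)
                    if config.noise and config.seed is not None else None)
        self._act_lo = np.zeros(self.arm.n_muscles)
        self._act_hi = np.ones(self.arm.n_muscles)
        self._kernel_args = None

    def kernel_args(self) -> tuple:
        """Cached constant arguments of the compiled rollout kernel."""
        if self._kernel_args is None:
            from ._fastsim import pack_kernel_args
            self._kernel_args = pack_kernel_args(self)
        return self._kernel_args

    # ---------------- initialization ----------------

    def initial_state(self) -> SimState:
        q0 = self.arm.inverse_kinematics(self.start, elbow_up=True)
        arm_state = ArmState(q0, np.zeros(2), np.zeros(self.arm.n_muscles))
        x0 = np.zeros(6)
        x0[:2] = self.start - self.target
        belief = make_belief(self.model, x0)
        robot_state = None
        if self.robot is not None:
            th0 = self.robot.inverse_kinematics(self.start, elbow_up=True)
            robot_state = RobotState(th0, np.zeros(2))
        return SimState(arm=arm_state, belief=belief, a_abs=np.zeros(2),
                        robot=robot_state, k=0)

    # ---------------- one tick ----------------

    def measurement(self, state: SimState) -> np.ndarray:
        hand, vel = self.arm.forward_kinematics(state.arm.q, state.arm.dq)
        y = np.empty(6)
        y[0:2] = hand - self.target
        y[2:4] = vel
        y[4:6] = state.a_abs
        if self.rng is not None:
            y = y + self.rng.multivariate_normal(
                np.zeros(6), self.params.sensory_noise)
        return y

    def excitations(self, state: SimState, u: np.ndarray):
        """Mid-level expansion of the abstract command at the current state."""
        f_task = compensate_velocity(u, state.arm, self.arm, self.params.fmax)
        basis = (self.synergies.basis if self.frozen_basis
                 else task_basis(self.synergies, self.arm, state.arm.q))
        C, _ = decompose_command(f_task, basis)
        e, _ = expand_to_excitations(self.synergies, C)
        return e, C

    def step(self, state: SimState, torques: np.ndarray | None = None,
             record: dict | None = None) -> SimState:
        """Advance the closed loop one control step (returns a new SimState)."""
        k = state.k
        kg = min(k, self.params.n_steps - 1)
        y = self.measurement(state)
        u = self.solution.L[kg] @ state.belief.xhat
        e, C = self.excitations(state, u)
        if self.robot is not None and torques is None:
            torques = np.zeros(2)
        belief = estimate_state(
            state.belief, u, y, self.model, self.solution, kg,
            rng=self.rng,
            estimation_noise_cov=(self.params.estimation_noise
                                  if self.rng is not None else None))
        new = state.copy()
        new.belief = belief
        f_int = self._integrate(new, e, torques)
        tau = self.params.tau
        new.a_abs = state.a_abs + self.params.dt * (u - state.a_abs) / tau
        new.k = k + 1
        if record is not None:
            hand, vel = self.arm.forward_kinematics(new.arm.q, new.arm.dq)
            record["hand_pos"] = hand
            record["hand_vel"] = vel
            record["u"] = u
            record["exc"] = e
            record["xhat"] = belief.xhat
            record["torques"] = torques if torques is not None else np.zeros(2)
            record["f_int"] = f_int
        return new

    # ---------------- plant integration ----------------

    def _arm_rates(self, q, dq, act, e):
        geom = self.arm.muscle_geometry(q, dq)
        fl = np.exp(-(((geom.lengths / self.arm.l0 - 1.0) / self.arm.width) ** 2))
        fv = force_velocity(geom.velocities / (self.arm.vmax * self.arm.l0))
        forces = act * fl * fv * self.arm.fmax
        tau = geom.moment_arms.T @ forces
        if self.field.b != 0.0:
            J = self.arm.hand_jacobian(q)
            tau = tau + J.T @ curl_field_force(self.field, J @ dq)
        qdd = np.linalg.solve(self.arm.mass_matrix(q),
                              tau - self.arm.coriolis(q, dq))
        dact = activation_rate(act, e, self.arm.tau_act, self.arm.tau_deact)
        return qdd, dact

    def _coupled_rates(self, q, dq, th, dth, act, e, torques):
        arm_state = ArmState(q, dq, act)
        geom = self.arm.muscle_geometry(q, dq)
        fl = np.exp(-(((geom.lengths / self.arm.l0 - 1.0) / self.arm.width) ** 2))
        fv = force_velocity(geom.velocities / (self.arm.vmax * self.arm.l0))
        forces = act * fl * fv * self.arm.fmax
        coupled = CoupledState(arm_state, RobotState(th, dth))
        qdd, thdd, f_int = coupled_accelerations(
            self.arm, self.robot, coupled, forces, torques,
            field=self.field, geom=geom)
        dact = activation_rate(act, e, self.arm.tau_act, self.arm.tau_deact)
        return qdd, thdd, dact, f_int

    def _integrate(self, state: SimState, e: np.ndarray,
                   torques: np.ndarray | None) -> np.ndarray:
        """Fixed-step RK4 over one control period; excitations and torques
        held constant.  Returns the interaction force at the step start."""
        dt = self.params.dt
        a = state.arm
        if state.robot is None:
            def rates(y):
                q, dq, act = y[0:2], y[2:4], y[4:10]
                qdd, dact = self._arm_rates(q, dq, act, e)
                return np.concatenate([dq, qdd, dact])
            y0 = np.concatenate([a.q, a.dq, a.act])
            k1 = rates(y0)
            k2 = rates(y0 + 0.5 * dt * k1)
            k3 = rates(y0 + 0.5 * dt * k2)
            k4 = rates(y0 + dt * k3)
            y1 = y0 + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            a.q, a.dq = y1[0:2], y1[2:4]
            a.act = np.clip(y1[4:10], self._act_lo, self._act_hi)
            return np.zeros(2)
        r = state.robot
        f_first = None

        def rates(y):
            nonlocal f_first
            q, dq, th, dth, act = y[0:2], y[2:4], y[4:6], y[6:8], y[8:14]
            qdd, thdd, dact, f_int = self._coupled_rates(q, dq, th, dth, act, e, torques)
            if f_first is None:
                f_first = f_int.on_human
            return np.concatenate([dq, qdd, dth, thdd, dact])

        y0 = np.concatenate([a.q, a.dq, r.theta, r.dtheta, a.act])
        k1 = rates(y0)
        k2 = rates(y0 + 0.5 * dt * k1)
        k3 = rates(y0 + 0.5 * dt * k2)
        k4 = rates(y0 + dt * k3)
        y1 = y0 + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        a.q, a.dq = y1[0:2], y1[2:4]
        r.theta, r.dtheta = y1[4:6], y1[6:8]
        a.act = np.clip(y1[8:14], self._act_lo, self._act_hi)
        return f_first

    # ---------------- full rollouts ----------------

    def run(self, n_steps: int | None = None,
            controller=None) -> SimulationResult:
        """Roll the closed loop for ``n_steps`` (default the horizon N).

        ``controller(sim, state) -> torques`` supplies robot torques each
        tick; None means zero torques (or no robot).
        """
        n = n_steps if n_steps is not None else self.params.n_steps
        state = self.initial_state()
        coupled = self.robot is not None
        cols = {
            "hand_pos": np.zeros((n, 2)), "hand_vel": np.zeros((n, 2)),
            "q": np.zeros((n, 2)), "dq": np.zeros((n, 2)),
            "act": np.zeros((n, 6)), "exc": np.zeros((n, 6)),
            "u": np.zeros((n, 2)), "xhat": np.zeros((n, 6)),
            "theta": np.full((n, 2), np.nan), "dtheta": np.full((n, 2), np.nan),
            "torques": np.zeros((n, 2)), "f_int": np.zeros((n, 2)),
        }
        for k in range(n):
            torques = controller(self, state) if controller is not None else None
            rec: dict = {}
            state = self.step(state, torques=torques, record=rec)
            cols["hand_pos"][k] = rec["hand_pos"]
            cols["hand_vel"][k] = rec["hand_vel"]
            cols["q"][k] = state.arm.q
            cols["dq"][k] = state.arm.dq
            cols["act"][k] = state.arm.act
            cols["exc"][k] = rec["exc"]
            cols["u"][k] = rec["u"]
            cols["xhat"][k] = rec["xhat"]
            cols["torques"][k] = rec["torques"]
            cols["f_int"][k] = rec["f_int"]
            if coupled:
                cols["theta"][k] = state.robot.theta
                cols["dtheta"][k] = state.robot.dtheta
        dt = self.params.dt
        return SimulationResult(
            time=dt * np.arange(1, n + 1),
            hand_pos=cols["hand_pos"], hand_vel=cols["hand_vel"],
            q=cols["q"], dq=cols["dq"], act=cols["act"], exc=cols["exc"],
            u_abstract=cols["u"], xhat=cols["xhat"],
            theta=cols["theta"], dtheta=cols["dtheta"],
            torques=cols["torques"], f_interaction=cols["f_int"],
            effort_inst=np.sum(cols["exc"] ** 2, axis=1),
            start=self.start.copy(), target=self.target.copy(),
            scenario=self.config.scenario, dt=dt, seed=self.config.seed)


def simulate_scenario(config: ScenarioConfig, arm: ArmModel | None = None,
                      synergies: SynergySet | None = None,
                      robot: RobotModel | None = None) -> SimulationResult:
    """Run one of the interaction scenarios A-D (or a plain reach).

    A: uncoupled reach.  B: coupled, passive robot.  C: coupled, human-aware
    predictive control.  D: coupled, impedance control toward the
    time-advanced scenario-A reference (``config.reference`` required).
    """
    from . import control

    sim = HolisticSimulator(config, arm=arm, synergies=synergies, robot=robot)
    if config.scenario in ("A", "center_out", "curl"):
        return sim.run()
    if config.scenario == "B":
        return sim.run()
    if config.scenario == "C":
        nmpc_cfg = config.nmpc if config.nmpc is not None else control.NMPCConfig()
        warm: dict = {"profile": None}

        def controller(s, state):
            prof = control.nmpc_step(s, state, nmpc_cfg, warm_start=warm["profile"])
            warm["profile"] = prof
            return prof.evaluate(0)

        return sim.run(controller=controller)
    # scenario D
    if config.reference is None:
        raise ValueError(
            "scenario D needs the scenario-A reference trajectory: run "
            "scenario A first and pass its trajectory as config.reference")
    imp = config.impedance if config.impedance is not None else control.ImpedanceParams()
    shift_steps = int(round(imp.time_shift / config.params.dt))
    ref = control.shift_reference(config.reference, shift_steps)

    def controller(s, state):
        pos, vel = ref.sample(state.k)
        return control.impedance_torques(s.robot, state.robot, pos, vel, imp)

    return sim.run(controller=controller)


def run_center_out(config: ScenarioConfig | None = None,
                   arm: ArmModel | None = None,
                   synergies: SynergySet | None = None,
                   n_targets: int = 8, radius: float = 0.12) -> list[SimulationResult]:
    """Reaches from the center start to targets equally spaced on a circle."""
    if config is None:
        config = ScenarioConfig(scenario="center_out")
    if arm is None:
        arm = default_arm()
    if synergies is None:
        synergies = learn_synergies(arm, seed=config.synergy_seed)
    results = []
    angles = 2 * np.pi * np.arange(n_targets) / n_targets
    for ang in angles:
        target = config.start + radius * np.array([np.cos(ang), np.sin(ang)])
        cfg_i = ScenarioConfig(
            scenario=config.scenario, target=target, start=config.start.copy(),
            field_b=config.field_b, seed=config.seed, noise=config.noise,
            params=config.params, synergy_seed=config.synergy_seed)
        sim = HolisticSimulator(cfg_i, arm=arm, synergies=synergies)
        results.append(sim.run())
    return results


# ---------------- metrics ----------------

# agonist/antagonist pairs of the 6-muscle fixture (flexor index, extensor index)
MUSCLE_PAIRS = ((0, 1), (2, 3), (4, 5))


def is_single_peaked(speed: np.ndarray, tol_frac: float = 0.01) -> bool:
    """True if the profile rises to a single maximum then falls, ignoring
    fluctuations smaller than ``tol_frac`` of the peak."""
    speed = np.asarray(speed, dtype=float)
    peak = speed.max()
    if peak <= 0:
        return True
    tol = tol_frac * peak
    i = int(np.argmax(speed))
    rising = np.all(np.diff(speed[:i + 1]) >= -tol)
    falling = np.all(np.diff(speed[i:]) <= tol)
    return bool(rising and falling)


def movement_metrics(result: SimulationResult) -> MovementMetrics:
    """Quantify the canonical reaching features of one run."""
    if result.n_steps == 0:
        raise ValueError("empty simulation result")
    start, target = result.start, result.target
    line = target - start
    dist = float(np.linalg.norm(line))
    d_hat = line / dist if dist > 0 else np.array([1.0, 0.0])
    lat_hat = np.array([-d_hat[1], d_hat[0]])
    rel = result.hand_pos - start
    longi = rel @ d_hat
    lat = rel @ lat_hat
    speed = result.speed
    peak_idx = int(np.argmax(speed))
    area = float(np.sum(0.5 * (lat[1:] + lat[:-1]) * np.diff(longi)))
    exc = result.exc
    # per-pair min/max, averaged over pairs and time
    mins = np.stack([np.minimum(exc[:, i], exc[:, j]) for i, j in MUSCLE_PAIRS])
    maxs = np.stack([np.maximum(exc[:, i], exc[:, j]) for i, j in MUSCLE_PAIRS])
    return MovementMetrics(
        terminal_error=float(np.linalg.norm(result.hand_pos[-1] - target)),
        straightness=float(np.max(np.abs(lat)) / dist) if dist > 0 else 0.0,
        peak_speed=float(speed[peak_idx]),
        peak_time_fraction=float((peak_idx + 1) / result.n_steps),
        effort=result.effort,
        co_contraction=float(np.mean(mins)),
        mean_agonist=float(np.mean(maxs)),
        lateral_area=area,
        max_lateral_dev=float(np.max(np.abs(lat))),
    )
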