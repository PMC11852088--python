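"""High-level controller: stochastic optimal feedback control on an
abstract internal model.

The "brain" of the hierarchy plans reaches on a deliberately simple internal
model: a 2-D point mass driven by two abstract muscles that can push and
pull, with first-order activation dynamics.  The state is

    X = [x, y, xdot, ydot, a_x, a_y]

with positions expressed *relative to the target*, so that the quadratic
state cost penalizes deviation from target-at-rest.  Motor noise is
signal-dependent: each command channel injects noise through the input
matrix with a standard deviation proportional to the command magnitude.
Because of this multiplicative noise the optimal feedback gains and the
Kalman gains are coupled and must be found by alternating the two
recursions until the gain schedules stop changing (the classical iterative
LQG treatment of signal-dependent noise).

Sensory feedback is a full (6-channel) readout of the state, delayed by an
integer number of time steps.  The belief keeps a ring buffer of raw
measurements and applied commands; a Kalman filter runs on the delayed
timeline and the current-time estimate is its forward prediction through
the buffered commands.  With zero delay and zero multiplicative noise the
solution collapses exactly to the textbook finite-horizon LQG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InternalModelParams",
    "PlantModel",
    "CostSchedule",
    "OFCSolution",
    "BeliefState",
    "build_internal_model",
    "build_cost_schedule",
    "solve_ofc",
    "control_command",
    "make_belief",
    "estimate_state",
    "simulate_internal",
]

_NX, _NU = 6, 2


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(mat)) < -1e-12:
        raise ValueError(f"{name} must be positive semi-definite")
    return mat


@dataclass
class InternalModelParams:
    """Parameters of the abstract point-mass internal model.

    Defaults are the simulation values used throughout the package: a 3 kg
    point mass, 30 ms activation time constant, 1000 N abstract force scale,
    5 ms control clock, a 221-step horizon whose last 21 steps are the dwell
    phase, and a 50 ms sensory delay.
    """

    mass: float = 3.0            # kg
    tau: float = 0.030           # s
    fmax: float = 1000.0         # N
    dt: float = 0.005            # s
    n_steps: int = 221           # horizon length N
    dwell: int = 21              # trailing steps with nonzero state cost
    delay: float = 0.050         # sensory delay d (s)
    process_noise: np.ndarray = field(
        default_factory=lambda: np.eye(_NX) * 2e-7)   # additive state noise cov
    sensory_noise: np.ndarray = field(
        default_factory=lambda: np.eye(_NX) * 1e-6)   # measurement noise cov
    estimation_noise: np.ndarray = field(
        default_factory=lambda: np.eye(_NU) * 1e-9)   # internal estimation noise cov
    mult_noise_scale: np.ndarray = field(
        default_factory=lambda: np.eye(_NU) * 0.2)    # signal-dependent scale C

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau <= 0 or self.mass <= 0:
            raise ValueError("dt, tau and mass must be strictly positive")
        if self.fmax <= 0:
            raise ValueError("fmax must be strictly positive")
        if not (self.n_steps > self.dwell >= 1):
            raise ValueError("need N > D >= 1")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        ratio = self.delay / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("delay must be an integer multiple of dt")
        self.process_noise = _check_psd(self.process_noise, "process_noise")
        self.sensory_noise = _check_psd(self.sensory_noise, "sensory_noise")
        self.estimation_noise = _check_psd(self.estimation_noise, "estimation_noise")
        self.mult_noise_scale = np.asarray(self.mult_noise_scale, dtype=float)

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.dt))


@dataclass
class PlantModel:
    """Discretized internal model with its target."""

    A: np.ndarray            # (6, 6)
    B: np.ndarray            # (6, 2)
    H: np.ndarray            # (6, 6) identity readout
    mult_scales: np.ndarray  # per-channel signal-dependent noise scales (2,)
    target: np.ndarray       # task-space target point (m)
    delay_steps: int

    @property
    def n_states(self) -> int:
        return self.A.shape[0]


@dataclass
class CostSchedule:
    """Per-step state penalties and the constant control penalty."""

    Q: np.ndarray   # (N, 6, 6); zero before the dwell phase, identity within
    R: np.ndarray   # (2, 2)


@dataclass
class OFCSolution:
    """Converged gain schedules; the control law is u_k = L[k] @ xhat_k."""

    L: np.ndarray          # (N, 2, 6) feedback gains
    K: np.ndarray          # (N, 6, 6) Kalman gains (delayed-timeline filter)
    K_eff: np.ndarray      # (N, 6, 6) current-time correction gains A^nd K
    iterations: int
    residual: float


def build_internal_model(params: InternalModelParams,
                         target: np.ndarray) -> PlantModel:
    """Forward-Euler discretization of the point-mass/abstract-muscle model.

    Continuous dynamics: m x" = a Fmax (per axis), tau a' = u - a.  The
    position states are target-relative, so the caller shifts measurements by
    ``target`` before feeding them to the filter.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (2,) or not np.all(np.isfinite(target)):
        raise ValueError("target must be a finite 2-vector")
    dt, tau = params.dt, params.tau
    gain = params.fmax / params.mass
    A = np.eye(_NX)
    A[0, 2] = A[1, 3] = dt
    A[2, 4] = A[3, 5] = dt * gain
    A[4, 4] = A[5, 5] = 1.0 - dt / tau
    B = np.zeros((_NX, _NU))
    B[4, 0] = B[5, 1] = dt / tau
    scales = np.diag(params.mult_noise_scale).astype(float)
    return PlantModel(A=A, B=B, H=np.eye(_NX), mult_scales=scales,
                      target=target, delay_steps=params.delay_steps)


def build_cost_schedule(params: InternalModelParams) -> CostSchedule:
    """Zero state cost during transport, identity during the dwell phase."""
    n, d = params.n_steps, params.dwell
    if d >= n:
        raise ValueError("dwell must be shorter than the horizon")
    Q = np.zeros((n, _NX, _NX))
    Q[n - d:] = np.eye(_NX)
    return CostSchedule(Q=Q, R=np.eye(_NU))


def _control_pass(model: PlantModel, cost: CostSchedule,
                  K_eff: np.ndarray) -> np.ndarray:
    """Backward recursion for the feedback gains given the filter gains.

    Carries two cost-to-go matrices: S_x for the true state and S_e for the
    estimation error; the signal-dependent noise couples the two into the
    control Riccati step.
    """
    A, B, H = model.A, model.B, model.H
    n = cost.Q.shape[0]
    Bsc = B * model.mult_scales[np.newaxis, :]      # columns scaled by c_i
    S_x = cost.Q[-1].copy()
    S_e = np.zeros_like(S_x)
    L = np.zeros((n, _NU, _NX))
    for k in range(n - 1, -1, -1):
        S_sum = S_x + S_e
        G = cost.R + B.T @ S_x @ B + np.diag(
            np.einsum("ij,jk,ki->i", Bsc.T, S_sum, Bsc))
        Lk = np.linalg.solve(G, B.T @ S_x @ A)      # u = -Lk x
        Qk = cost.Q[k - 1] if k > 0 else np.zeros_like(S_x)
        closed = A - K_eff[k] @ H
        S_e = A.T @ S_x @ B @ Lk + closed.T @ S_e @ closed
        S_x = Qk + A.T @ S_x @ (A - B @ Lk)
        S_x = 0.5 * (S_x + S_x.T)
        L[k] = -Lk                                  # stored so u = L[k] xhat
    return L


def _filter_pass(model: PlantModel, params: InternalModelParams,
                 L: np.ndarray, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward covariance recursion for the Kalman gains given the controller."""
    A, B, H = model.A, model.B, model.H
    n = L.shape[0]
    Om_xi = params.process_noise
    Om_om = params.sensory_noise
    Om_eta = B @ params.estimation_noise @ B.T
    Bsc = B * model.mult_scales[np.newaxis, :]
    A_nd = np.linalg.matrix_power(A, model.delay_steps)
    sig_e = np.zeros((_NX, _NX))
    sig_h = np.outer(x0, x0)
    sig_he = np.zeros((_NX, _NX))
    K = np.zeros((n, _NX, _NX))
    for k in range(n):
        Kk = A @ sig_e @ H.T @ np.linalg.inv(H @ sig_e @ H.T + Om_om)
        K[k] = Kk
        Lk = -L[k]                                   # recursion convention u = -L x
        closed = A - B @ Lk
        # signal-dependent injection: cov of sum_i eps_i c_i u_i b_i
        u_cov = Lk @ sig_h @ Lk.T
        mult = Bsc @ np.diag(np.diag(u_cov)) @ Bsc.T
        KH = Kk @ H
        new_e = Om_xi + Om_eta + (A - KH) @ sig_e @ A.T + mult
        new_h = (Om_eta + KH @ sig_e @ A.T + closed @ sig_h @ closed.T
                 + closed @ sig_he @ KH.T + KH @ sig_he.T @ closed.T)
        new_he = closed @ sig_he @ (A - KH).T - Om_eta
        sig_e = 0.5 * (new_e + new_e.T)
        sig_h = 0.5 * (new_h + new_h.T)
        sig_he = new_he
    # current-time correction gain: the innovation available at step k is
    # n_d steps old, so its filter gain (index k - n_d) is propagated
    # forward through A^nd before correcting the current-time estimate
    nd = model.delay_steps
    K_eff = np.empty_like(K)
    for k in range(n):
        K_eff[k] = A_nd @ K[max(k - nd, 0)]
    return K, K_eff


def solve_ofc(model: PlantModel, cost: CostSchedule,
              params: InternalModelParams, x0: np.ndarray | None = None,
              tol: float = 1e-9, max_iter: int = 500) -> OFCSolution:
    """Alternate controller and filter recursions until the gains converge.

    ``x0`` is the initial (target-relative) state used to seed the belief
    covariance in the filter pass; it defaults to the at-rest state whose
    position is the negated target displacement.
    """
    n = cost.Q.shape[0]
    if x0 is None:
        x0 = np.zeros(_NX)
        x0[:2] = -model.target
    K_eff = np.zeros((n, _NX, _NX))
    K = np.zeros((n, _NX, _NX))
    L = _control_pass(model, cost, K_eff)
    residual = np.inf
    for it in range(1, max_iter + 1):
        K_new, K_eff_new = _filter_pass(model, params, L, x0)
        L_new = _control_pass(model, cost, K_eff_new)
        residual = max(np.max(np.abs(L_new - L)), np.max(np.abs(K_new - K)))
        L, K, K_eff = L_new, K_new, K_eff_new
        if residual < tol:
            return OFCSolution(L=L, K=K, K_eff=K_eff, iterations=it,
                               residual=float(residual))
    raise RuntimeError(
        f"OFC gain iteration did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})")


def control_command(solution: OFCSolution, xhat: np.ndarray, k: int) -> np.ndarray:
    """The optimal abstract command u_k = L_k xhat_k (no clipping)."""
    if not 0 <= k < solution.L.shape[0]:
        raise IndexError(f"step {k} outside the gain schedule")
    return solution.L[k] @ xhat


@dataclass
class BeliefState:
    """Estimated internal state plus delay bookkeeping.

    ``xhat`` is the current-time estimate ("the perceived motion");
    ``xhat_delayed`` is the filtered estimate on the delayed timeline, from
    which ``xhat`` is a forward prediction through the buffered commands.
    """

    xhat: np.ndarray                   # (6,)
    xhat_delayed: np.ndarray           # (6,)
    meas_buffer: np.ndarray            # (n_d, 6) raw measurement ring buffer
    ctrl_buffer: np.ndarray            # (n_d, 2) applied-command ring buffer
    cov: np.ndarray                    # delayed-timeline error covariance
    head: int = 0                      # ring index of the oldest entry

    def copy(self) -> "BeliefState":
        return BeliefState(self.xhat.copy(), self.xhat_delayed.copy(),
                           self.meas_buffer.copy(), self.ctrl_buffer.copy(),
                           self.cov.copy(), self.head)


def make_belief(model: PlantModel, x0: np.ndarray) -> BeliefState:
    """Belief for a movement starting at rest at state ``x0``.

    The arm is assumed stationary before movement onset, so the measurement
    buffer is pre-filled with the initial state.
    """
    nd = model.delay_steps
    x0 = np.asarray(x0, dtype=float)
    return BeliefState(
        xhat=x0.copy(), xhat_delayed=x0.copy(),
        meas_buffer=np.tile(x0, (nd, 1)) if nd else np.zeros((0, _NX)),
        ctrl_buffer=np.zeros((nd, _NU)),
        cov=np.zeros((_NX, _NX)),
    )


def estimate_state(belief: BeliefState, u: np.ndarray, measurement: np.ndarray,
                   model: PlantModel, solution: OFCSolution, k: int,
                   rng: np.random.Generator | None = None,
                   estimation_noise_cov: np.ndarray | None = None) -> BeliefState:
    """One filter step: push the raw measurement, correct with the delayed
    innovation, and propagate the current-time estimate.

    The innovation is formed against the buffer's oldest measurement (age
    ``n_d`` steps) on the delayed timeline; the current-time estimate is
    advanced as ``A xhat + B u`` plus the delay-propagated correction
    ``A^nd K_k (Y_old - H xhat_delayed)``.
    """
    measurement = np.asarray(measurement, dtype=float)
    if measurement.shape != (_NX,):
        raise ValueError("measurement must be a 6-vector")
    A, B, H = model.A, model.B, model.H
    nd = model.delay_steps
    n = solution.K.shape[0]
    k = min(k, n - 1)           # hold terminal gains past the horizon
    out = belief.copy()
    if nd == 0:
        innov = measurement - H @ out.xhat
        gain = solution.K[k]
        out.xhat = A @ out.xhat + B @ u + gain @ innov
        out.xhat_delayed = out.xhat
    else:
        h = out.head
        y_old = out.meas_buffer[h]
        u_old = out.ctrl_buffer[h]
        innov = y_old - H @ out.xhat_delayed
        j = max(k - nd, 0)
        out.xhat_delayed = A @ out.xhat_delayed + B @ u_old + solution.K[j] @ innov
        out.xhat = A @ out.xhat + B @ u + solution.K_eff[k] @ innov
        out.meas_buffer[h] = measurement
        out.ctrl_buffer[h] = u
        out.head = (h + 1) % nd
    if rng is not None and estimation_noise_cov is not None:
        eta = rng.multivariate_normal(np.zeros(_NU), estimation_noise_cov)
        out.xhat = out.xhat + B @ eta
    if not np.all(np.isfinite(out.xhat)):
        raise FloatingPointError("belief diverged (non-finite estimate)")
    return out


def simulate_internal(model: PlantModel, solution: OFCSolution,
                      params: InternalModelParams,
                      seed: int | None = None) -> dict[str, np.ndarray]:
    """Standalone rollout of the internal model under its own controller.

    With ``seed`` given, process/sensory/estimation noise are drawn from the
    configured Gaussians; without a seed the rollout is noise-free.  Returns
    target-relative state, estimate and command histories.
    """
    n = params.n_steps
    rng = np.random.default_rng(seed) if seed is not None else None
    x = np.zeros(_NX)
    x[:2] = -model.target
    belief = make_belief(model, x)
    X = np.zeros((n + 1, _NX))
    Xhat = np.zeros((n + 1, _NX))
    U = np.zeros((n, _NU))
    X[0], Xhat[0] = x, belief.xhat
    scales = model.mult_scales
    for k in range(n):
        u = control_command(solution, belief.xhat, k)
        y = model.H @ x
        if rng is not None:
            y = y + rng.multivariate_normal(np.zeros(_NX), params.sensory_noise)
        belief = estimate_state(
            belief, u, y, model, solution, k,
            rng=rng,
            estimation_noise_cov=params.estimation_noise if rng is not None else None)
        x = model.A @ x + model.B @ u
        if rng is not None:
            mult = model.B @ (scales * np.abs(u) * rng.standard_normal(_NU))
            x = x + mult + rng.multivariate_normal(np.zeros(_NX), params.process_noise)
        X[k + 1], Xhat[k + 1], U[k] = x, belief.xhat, u
    return {"X": X, "Xhat": Xhat, "U": U}
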