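"""Two-link, six-muscle planar musculoskeletal arm.

The plant is a planar upper arm / forearm linkage moving in a horizontal
workspace (no gravity torques), actuated by six Hill-type muscles routed as
straight lines between origin and insertion points:

* mono-articular shoulder flexor / extensor,
* mono-articular elbow flexor / extensor,
* bi-articular flexor / extensor.

Muscle force is ``F = a * fl * fv * Fmax`` (pull-only), with a Gaussian
force-length curve, a Hill force-velocity curve and first-order nonlinear
activation dynamics driving ``a`` toward the neural excitation ``e``.
Tendon and other series compliances are neglected.

All angles are in radians: ``q[0]`` is the shoulder angle measured from the
world +x axis, ``q[1]`` the elbow angle relative to the upper arm,
counterclockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ArmParams",
    "MuscleParams",
    "ArmState",
    "MuscleGeometry",
    "ArmModel",
    "force_length",
    "force_velocity",
    "activation_rate",
    "load_arm_fixture",
    "default_arm",
]

_SEGMENTS = ("torso", "upper", "fore")


@dataclass
class ArmParams:
    """Rigid-body parameters of the 2-link arm (SI units)."""

    l1: float = 0.30          # upper-arm length (m)
    l2: float = 0.33          # forearm(+hand) length (m)
    m1: float = 1.9           # upper-arm mass (kg)
    m2: float = 1.1           # forearm mass (kg)
    d1: float = 0.13          # shoulder -> upper-arm COM (m)
    d2: float = 0.16          # elbow -> forearm COM (m)
    I1: float = 0.014         # inertia about COM (kg m^2)
    I2: float = 0.012
    shoulder: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.shoulder = np.asarray(self.shoulder, dtype=float)
        for name in ("l1", "l2", "m1", "m2", "d1", "d2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"arm parameter {name!r} must be positive")


@dataclass
class MuscleParams:
    """Parameters of one straight-line Hill-type muscle."""

    name: str
    origin_segment: str       # 'torso' | 'upper' | 'fore'
    origin: np.ndarray        # point in the parent-segment frame (m)
    insertion_segment: str
    insertion: np.ndarray
    l0: float                 # optimal fiber length (m)
    fmax: float               # max isometric force (N)
    width: float = 0.4        # force-length width (unitless)
    vmax: float = 10.0        # max shortening velocity (l0/s)
    tau_act: float = 0.015    # activation time constant (s)
    tau_deact: float = 0.050  # deactivation time constant (s)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        if self.origin_segment not in _SEGMENTS or self.insertion_segment not in _SEGMENTS:
            raise ValueError("muscle attachment segment must be torso/upper/fore")
        for name in ("l0", "fmax", "width", "vmax", "tau_act", "tau_deact"):
            if getattr(self, name) <= 0:
                raise ValueError(f"muscle parameter {name!r} must be positive")


@dataclass
class ArmState:
    """Joint angles/velocities plus the six muscle activations."""

    q: np.ndarray             # (2,) rad
    dq: np.ndarray            # (2,) rad/s
    act: np.ndarray           # (6,) in [0, 1]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.dq = np.asarray(self.dq, dtype=float)
        self.act = np.asarray(self.act, dtype=float)

    def copy(self) -> "ArmState":
        return ArmState(self.q.copy(), self.dq.copy(), self.act.copy())


@dataclass
class MuscleGeometry:
    """Muscle lengths, lengthening velocities and the moment-arm matrix."""

    lengths: np.ndarray       # (6,) m
    velocities: np.ndarray    # (6,) m/s, positive = lengthening
    moment_arms: np.ndarray   # (6, 2) m; r_ij = -d(length_i)/d(q_j)


def force_length(l_norm: np.ndarray | float, width: float = 0.4) -> np.ndarray | float:
    """Gaussian active force-length curve, peak 1 at optimal length."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("normalized muscle length must be positive")
    out = np.exp(-(((l_norm - 1.0) / width) ** 2))
    return float(out) if out.ndim == 0 else out


_FV_PLATEAU = 1.5     # eccentric force plateau
_FV_SHORT_K = 0.25    # curvature of the shortening branch (a/F0 in Hill's law)
_FV_LEN_GAMMA = 0.2   # lengthening-branch saturation rate


def force_velocity(v_norm: np.ndarray | float) -> np.ndarray | float:
    """Hill force-velocity curve on normalized velocity (positive = lengthening).

    Shortening branch is the classic hyperbola with fv(-1) = 0, fv(0) = 1;
    the lengthening branch rises continuously and saturates at 1.5.
    """
    v = np.asarray(v_norm, dtype=float)
    v_short = np.clip(v, -1.0, 0.0)
    short = (1.0 + v_short) / (1.0 - v_short / _FV_SHORT_K)
    lengthen = 1.0 + (_FV_PLATEAU - 1.0) * v / (v + _FV_LEN_GAMMA)
    out = np.where(v < 0.0, np.where(v <= -1.0, 0.0, short), lengthen)
    return float(out) if out.ndim == 0 else out


def activation_rate(a: np.ndarray, e: np.ndarray, tau_act: np.ndarray,
                    tau_deact: np.ndarray) -> np.ndarray:
    """Nonlinear first-order activation dynamics da/dt.

    Activation speeds up with the activation level itself (the 0.5 + 1.5 a
    factor); deactivation slows down correspondingly.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    gain = 0.5 + 1.5 * a
    up = (e - a) / (tau_act * gain)
    down = (e - a) * gain / tau_deact
    return np.where(e > a, up, down)


class ArmModel:
    """The 2-link 6-muscle arm: kinematics, muscle paths, and dynamics."""

    def __init__(self, params: ArmParams, muscles: list[MuscleParams]):
        if len(muscles) != 6:
            raise ValueError("the arm model expects exactly 6 muscles")
        self.params = params
        self.muscles = muscles
        self.n_muscles = len(muscles)
        self.fmax = np.array([m.fmax for m in muscles])
        self.l0 = np.array([m.l0 for m in muscles])
        self.width = np.array([m.width for m in muscles])
        self.vmax = np.array([m.vmax for m in muscles])
        self.tau_act = np.array([m.tau_act for m in muscles])
        self.tau_deact = np.array([m.tau_deact for m in muscles])
        # vectorized attachment tables: rows 0..5 are origins, 6..11 insertions
        codes = {s: i for i, s in enumerate(_SEGMENTS)}
        seg = np.array([codes[m.origin_segment] for m in muscles]
                       + [codes[m.insertion_segment] for m in muscles])
        self._att_pts = np.array([m.origin for m in muscles]
                                 + [m.insertion for m in muscles])
        self._m_torso = (seg == 0)[:, None].astype(float)
        self._m_upper = (seg == 1)[:, None].astype(float)
        self._m_fore = (seg == 2)[:, None].astype(float)
        self._m_not_torso = 1.0 - self._m_torso

    # ---------------- kinematics ----------------

    def elbow_position(self, q: np.ndarray) -> np.ndarray:
        p = self.params
        return p.shoulder + p.l1 * np.array([np.cos(q[0]), np.sin(q[0])])

    def forward_kinematics(self, q: np.ndarray, dq: np.ndarray | None = None):
        """Hand (forearm endpoint) position, and velocity if dq is given."""
        p = self.params
        q12 = q[0] + q[1]
        hand = self.elbow_position(q) + p.l2 * np.array([np.cos(q12), np.sin(q12)])
        if dq is None:
            return hand
        vel = self.hand_jacobian(q) @ np.asarray(dq, dtype=float)
        return hand, vel

    def hand_jacobian(self, q: np.ndarray) -> np.ndarray:
        p = self.params
        s1, c1 = np.sin(q[0]), np.cos(q[0])
        s12, c12 = np.sin(q[0] + q[1]), np.cos(q[0] + q[1])
        return np.array([
            [-p.l1 * s1 - p.l2 * s12, -p.l2 * s12],
            [p.l1 * c1 + p.l2 * c12, p.l2 * c12],
        ])

    def hand_jacobian_dot(self, q: np.ndarray, dq: np.ndarray) -> np.ndarray:
        p = self.params
        dq1, dq12 = dq[0], dq[0] + dq[1]
        c1, s1 = np.cos(q[0]), np.sin(q[0])
        c12, s12 = np.cos(q[0] + q[1]), np.sin(q[0] + q[1])
        return np.array([
            [-p.l1 * c1 * dq1 - p.l2 * c12 * dq12, -p.l2 * c12 * dq12],
            [-p.l1 * s1 * dq1 - p.l2 * s12 * dq12, -p.l2 * s12 * dq12],
        ])

    def inverse_kinematics(self, hand: np.ndarray, elbow_up: bool = True) -> np.ndarray:
        """Closed-form IK; ``elbow_up`` selects the counterclockwise branch."""
        p = self.params
        rel = np.asarray(hand, dtype=float) - p.shoulder
        r2 = float(rel @ rel)
        c2 = (r2 - p.l1 ** 2 - p.l2 ** 2) / (2 * p.l1 * p.l2)
        if c2 > 1.0 + 1e-12 or c2 < -1.0 - 1e-12:
            raise ValueError(
                f"hand point {hand} unreachable (distance {np.sqrt(r2):.3f} m, "
                f"workspace [{abs(p.l1 - p.l2):.3f}, {p.l1 + p.l2:.3f}] m)")
        c2 = np.clip(c2, -1.0, 1.0)
        q2 = np.arccos(c2) if elbow_up else -np.arccos(c2)
        q1 = np.arctan2(rel[1], rel[0]) - np.arctan2(
            p.l2 * np.sin(q2), p.l1 + p.l2 * np.cos(q2))
        return np.array([q1, q2])

    # ---------------- muscle geometry ----------------

    def muscle_geometry(self, q: np.ndarray, dq: np.ndarray | None = None) -> MuscleGeometry:
        """Lengths, lengthening velocities, moment arms of all six paths.

        Straight-line paths; moment arms are the exact analytic length
        gradients r_ij = -d(length_i)/d(q_j).
        """
        p = self.params
        c1, s1 = np.cos(q[0]), np.sin(q[0])
        c12, s12 = np.cos(q[0] + q[1]), np.sin(q[0] + q[1])
        pts = self._att_pts
        # rotated attachment points in both moving frames
        rot1 = np.empty_like(pts)
        rot1[:, 0] = pts[:, 0] * c1 - pts[:, 1] * s1
        rot1[:, 1] = pts[:, 0] * s1 + pts[:, 1] * c1
        rot12 = np.empty_like(pts)
        rot12[:, 0] = pts[:, 0] * c12 - pts[:, 1] * s12
        rot12[:, 1] = pts[:, 0] * s12 + pts[:, 1] * c12
        elbow_rel = np.array([p.l1 * c1, p.l1 * s1])
        rel = (self._m_torso * pts + self._m_upper * rot1
               + self._m_fore * (elbow_rel + rot12))      # w - shoulder
        # dq-derivatives of world points (perp of the relevant lever)
        d1 = np.empty_like(rel)
        d1[:, 0], d1[:, 1] = -rel[:, 1], rel[:, 0]
        d1 *= self._m_not_torso
        rel_el = rel - elbow_rel
        d2 = np.empty_like(rel)
        d2[:, 0], d2[:, 1] = -rel_el[:, 1], rel_el[:, 0]
        d2 *= self._m_fore
        n = self.n_muscles
        vec = rel[n:] - rel[:n]
        lengths = np.sqrt(vec[:, 0] ** 2 + vec[:, 1] ** 2)
        if np.any(lengths < 1e-9):
            bad = self.muscles[int(np.argmin(lengths))].name
            raise ValueError(f"degenerate (zero-length) path for muscle {bad!r}")
        u = vec / lengths[:, None]
        g1 = d1[n:] - d1[:n]
        g2 = d2[n:] - d2[:n]
        arms = np.empty((n, 2))
        arms[:, 0] = -(u[:, 0] * g1[:, 0] + u[:, 1] * g1[:, 1])
        arms[:, 1] = -(u[:, 0] * g2[:, 0] + u[:, 1] * g2[:, 1])
        if dq is None:
            velocities = np.zeros(n)
        else:
            velocities = -(arms[:, 0] * dq[0] + arms[:, 1] * dq[1])
        return MuscleGeometry(lengths, velocities, arms)

    # ---------------- muscle mechanics ----------------

    def muscle_forces(self, state: ArmState, geom: MuscleGeometry | None = None) -> np.ndarray:
        if geom is None:
            geom = self.muscle_geometry(state.q, state.dq)
        fl = force_length(geom.lengths / self.l0, self.width[0]) if np.all(
            self.width == self.width[0]) else np.array(
            [force_length(geom.lengths[i] / self.l0[i], self.width[i])
             for i in range(self.n_muscles)])
        fv = force_velocity(geom.velocities / (self.vmax * self.l0))
        return state.act * fl * fv * self.fmax

    def isometric_gain(self, q: np.ndarray) -> np.ndarray:
        """Map activations -> static hand force: ``F_hand = G @ a`` (2x6).

        Isometric (fv = 1) statics at posture ``q``: hand force
        J^-T R^T diag(fl * Fmax) a.
        """
        geom = self.muscle_geometry(q)
        fl = np.exp(-(((geom.lengths / self.l0 - 1.0) / self.width) ** 2))
        J = self.hand_jacobian(q)
        torque_per_act = geom.moment_arms.T * (fl * self.fmax)  # (2, 6)
        return np.linalg.solve(J.T, torque_per_act)

    # ---------------- rigid-body dynamics ----------------

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        p = self.params
        c2 = np.cos(q[1])
        a = p.I1 + p.I2 + p.m1 * p.d1 ** 2 + p.m2 * (p.l1 ** 2 + p.d2 ** 2 + 2 * p.l1 * p.d2 * c2)
        b = p.I2 + p.m2 * (p.d2 ** 2 + p.l1 * p.d2 * c2)
        c = p.I2 + p.m2 * p.d2 ** 2
        return np.array([[a, b], [b, c]])

    def coriolis(self, q: np.ndarray, dq: np.ndarray) -> np.ndarray:
        """Velocity-product torques C(q, dq) dq."""
        p = self.params
        h = p.m2 * p.l1 * p.d2 * np.sin(q[1])
        return np.array([
            -h * dq[1] ** 2 - 2 * h * dq[0] * dq[1],
            h * dq[0] ** 2,
        ])

    def arm_dynamics(self, state: ArmState, muscle_forces: np.ndarray,
                     hand_force: np.ndarray | None = None,
                     geom: MuscleGeometry | None = None) -> np.ndarray:
        """Joint accelerations under muscle forces and an external hand force."""
        if geom is None:
            geom = self.muscle_geometry(state.q, state.dq)
        tau = geom.moment_arms.T @ np.asarray(muscle_forces, dtype=float)
        if hand_force is not None:
            tau = tau + self.hand_jacobian(state.q).T @ np.asarray(hand_force, dtype=float)
        rhs = tau - self.coriolis(state.q, state.dq)
        return np.linalg.solve(self.mass_matrix(state.q), rhs)

    def kinetic_energy(self, q: np.ndarray, dq: np.ndarray) -> float:
        return 0.5 * float(dq @ self.mass_matrix(q) @ dq)


# ---------------- fixture loading ----------------

def load_arm_fixture(path: str | Path) -> ArmModel:
    """Build an :class:`ArmModel` from a YAML fixture file.

    A muscle ``l0`` given as the string ``auto`` is replaced by the muscle's
    path length at the fixture's ``reference_posture`` (optimal length at the
    reference posture).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    arm_cfg = cfg["arm"]
    params = ArmParams(
        l1=arm_cfg["l1"], l2=arm_cfg["l2"], m1=arm_cfg["m1"], m2=arm_cfg["m2"],
        d1=arm_cfg["d1"], d2=arm_cfg["d2"], I1=arm_cfg["I1"], I2=arm_cfg["I2"],
        shoulder=np.asarray(arm_cfg.get("shoulder", [0.0, 0.0]), dtype=float),
    )
    q_ref = np.asarray(cfg["reference_posture"], dtype=float)
    muscles = []
    for mc in cfg["muscles"]:
        muscles.append(MuscleParams(
            name=mc["name"],
            origin_segment=mc["origin_segment"],
            origin=np.asarray(mc["origin"], dtype=float),
            insertion_segment=mc["insertion_segment"],
            insertion=np.asarray(mc["insertion"], dtype=float),
            l0=1.0 if mc["l0"] == "auto" else float(mc["l0"]),
            fmax=float(mc["fmax"]),
            width=float(mc.get("width", 0.4)),
            vmax=float(mc.get("vmax", 10.0)),
            tau_act=float(mc.get("tau_act", 0.015)),
            tau_deact=float(mc.get("tau_deact", 0.050)),
        ))
    model = ArmModel(params, muscles)
    geom = model.muscle_geometry(q_ref)
    for i, mc in enumerate(cfg["muscles"]):
        if mc["l0"] == "auto":
            muscles[i].l0 = float(geom.lengths[i])
    model.l0 = np.array([m.l0 for m in muscles])
    model.reference_posture = q_ref
    return model


def default_arm() -> ArmModel:
    """The bundled arm fixture (see ``data/arm_fixture.yaml``)."""
    from importlib.resources import files
    return load_arm_fixture(files("neuroarm.data") / "arm_fixture.yaml")
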