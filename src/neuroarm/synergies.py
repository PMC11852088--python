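"""Mid-level dimension expansion with muscle synergies.

The high-level controller commands forces in a 2-D task space; physiological
muscles are six pull-only actuators.  The bridge is a small set of fixed
non-negative co-activation patterns (synergies).  Offline, optimal static
muscle activations are computed for hand forces spanning the circle of
directions (minimum-norm load sharing, a non-negative QP), and non-negative
matrix factorization compresses them into 4 synergies.  Each synergy, pushed
through the arm's isometric statics, produces a hand-force basis vector;
online, the commanded task force is decomposed onto that basis with
non-negative least squares and the coefficients re-expand through the
synergy matrix into neural excitations.

Velocity-dependent (Coriolis/centrifugal) accelerations of the physical arm
are not represented in the point-mass internal model, so the commanded force
is corrected by the task-space equivalent of the arm's velocity-product
torques before decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize
from sklearn.decomposition import NMF

from .arm import ArmModel, ArmState

__all__ = [
    "SynergySet",
    "optimal_static_activations",
    "max_feasible_force",
    "learn_synergies",
    "task_basis",
    "compensate_velocity",
    "decompose_command",
    "expand_to_excitations",
    "save_synergies",
    "load_synergies",
]

logger = logging.getLogger(__name__)


@dataclass
class SynergySet:
    """Non-negative synergy matrix and its task-space force basis.

    ``S[i, j]`` is muscle i's weight in synergy j (each column normalized to
    unit maximum); ``basis[:, j]`` is the hand force (N) produced by unit
    activation of synergy j at the reference posture.
    """

    S: np.ndarray               # (6, n_syn), entries >= 0
    basis: np.ndarray           # (2, n_syn) reference-posture force basis
    reference_posture: np.ndarray   # (2,) rad

    @property
    def n_synergies(self) -> int:
        return self.S.shape[1]


def max_feasible_force(arm: ArmModel, posture: np.ndarray,
                       direction: np.ndarray) -> float:
    """Largest static hand-force magnitude achievable along ``direction``
    with activations in [0, 1] (isometric)."""
    G = arm.isometric_gain(posture)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # maximize s subject to G a = s d, 0 <= a <= 1
    c = np.zeros(arm.n_muscles + 1)
    c[-1] = -1.0
    A_eq = np.hstack([G, -d[:, None]])
    res = optimize.linprog(c, A_eq=A_eq, b_eq=np.zeros(2),
                           bounds=[(0, 1)] * arm.n_muscles + [(0, None)],
                           method="highs")
    if not res.success:
        raise RuntimeError(f"feasible-force LP failed: {res.message}")
    return float(res.x[-1])


def optimal_static_activations(arm: ArmModel, posture: np.ndarray,
                               hand_force: np.ndarray,
                               tol: float = 1e-9) -> np.ndarray:
    """Minimum-norm static load sharing: min ||a||^2 subject to the
    isometric statics producing ``hand_force``, with 0 <= a <= 1.
    """
    G = arm.isometric_gain(posture)
    f = np.asarray(hand_force, dtype=float)
    if np.allclose(f, 0.0):
        return np.zeros(arm.n_muscles)
    n = arm.n_muscles
    res = optimize.minimize(
        lambda a: float(a @ a), x0=np.full(n, 0.1),
        jac=lambda a: 2.0 * a,
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda a: G @ a - f,
                      "jac": lambda a: G}],
        method="SLSQP", options={"maxiter": 200, "ftol": 1e-14})
    a = np.clip(res.x, 0.0, 1.0)
    err = np.linalg.norm(G @ a - f)
    if err > 1e-6:
        mag = max_feasible_force(arm, posture, f)
        raise ValueError(
            f"requested hand force {f} infeasible at this posture "
            f"(max achievable along that direction: {mag:.1f} N)")
    return a


def learn_synergies(arm: ArmModel, reference_posture: np.ndarray | None = None,
                    n_directions: int = 16, n_synergies: int = 4,
                    seed: int = 0, force_fraction: float = 0.25) -> SynergySet:
    """Offline synergy extraction: optimal static activations over equally
    spaced force directions, compressed by non-negative matrix factorization.

    Forces are sampled at ``force_fraction`` of the per-direction maximum
    feasible magnitude.  Deterministic for a given seed.
    """
    if reference_posture is None:
        reference_posture = arm.reference_posture
    if n_directions < n_synergies:
        raise ValueError("need at least as many directions as synergies")
    posture = np.asarray(reference_posture, dtype=float)
    angles = 2 * np.pi * np.arange(n_directions) / n_directions
    acts = np.empty((arm.n_muscles, n_directions))
    for j, ang in enumerate(angles):
        d = np.array([np.cos(ang), np.sin(ang)])
        mag = force_fraction * max_feasible_force(arm, posture, d)
        acts[:, j] = optimal_static_activations(arm, posture, mag * d)
    nmf = NMF(n_components=n_synergies, init="nndsvda", max_iter=5000,
              tol=1e-10, random_state=seed)
    W = nmf.fit_transform(acts)          # (6, n_syn)
    peaks = W.max(axis=0)
    if np.any(peaks <= 0):
        raise RuntimeError("NMF produced an empty synergy; "
                           "reduce n_synergies or add directions")
    S = W / peaks                        # unit-max columns
    G = arm.isometric_gain(posture)
    basis = G @ S
    return SynergySet(S=S, basis=basis, reference_posture=posture)


def task_basis(synergies: SynergySet, arm: ArmModel,
               posture: np.ndarray) -> np.ndarray:
    """Recompute the synergy force basis at the current posture.

    The stored basis is a fixed motor memory at the reference posture; this
    refreshes it through the muscle geometry so decomposition stays accurate
    away from the reference.
    """
    J = arm.hand_jacobian(posture)
    if abs(np.linalg.det(J)) < 1e-10:
        raise ValueError("singular arm Jacobian; basis undefined at this posture")
    return arm.isometric_gain(posture) @ synergies.S


def compensate_velocity(u: np.ndarray, state: ArmState, arm: ArmModel,
                        fmax_abstract: float = 1000.0) -> np.ndarray:
    """Task-force command with velocity-product compensation.

    The desired hand force is the abstract command scaled to newtons plus
    the task-space equivalent of the arm's Coriolis/centrifugal torques
    (exactly zero at zero joint velocity).  Falls back to the uncompensated
    command near kinematic singularities.
    """
    u = np.asarray(u, dtype=float)
    base = u * fmax_abstract
    J = arm.hand_jacobian(state.q)
    det = np.linalg.det(J)
    if abs(det) < 1e-8:
        logger.warning("singular Jacobian; skipping velocity compensation")
        return base
    c = arm.coriolis(state.q, state.dq)
    return base + np.linalg.solve(J.T, c)


def decompose_command(task_force: np.ndarray, basis: np.ndarray):
    """Non-negative least squares onto the synergy force basis.

    Returns ``(C, residual)`` with ``C >= 0`` minimizing ``||basis C - f||``.
    """
    C, res = optimize.nnls(basis, np.asarray(task_force, dtype=float))
    return C, float(res)


def expand_to_excitations(synergies: SynergySet, C: np.ndarray):
    """Neural excitations e = clip(S C, 0, 1); also returns pre-clip values."""
    C = np.asarray(C, dtype=float)
    if np.any(C < -1e-12):
        raise ValueError("synergy coefficients must be non-negative")
    raw = synergies.S @ C
    return np.clip(raw, 0.0, 1.0), raw


# ---------------- serialization ----------------

def save_synergies(synergies: SynergySet, path: str | Path) -> None:
    """Plain-text export: metadata block, then S (muscles x synergies) and
    the reference basis (2 x synergies), whitespace-delimited."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# neuroarm synergy set\n")
        fh.write(f"# n_muscles {synergies.S.shape[0]} n_synergies "
                 f"{synergies.n_synergies}\n")
        fh.write("# reference_posture_rad "
                 + " ".join(f"{v:.17g}" for v in synergies.reference_posture) + "\n")
        fh.write("# S rows = muscles, columns = synergies\n")
        for row in synergies.S:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
        fh.write("# basis rows = task-space x,y (N per unit synergy)\n")
        for row in synergies.basis:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_synergies(path: str | Path) -> SynergySet:
    path = Path(path)
    posture = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# reference_posture_rad"):
                posture = np.array([float(v) for v in line.split()[2:]])
            elif line and not line.startswith("#"):
                rows.append([float(v) for v in line.split()])
    if posture is None or len(rows) < 3:
        raise ValueError(f"malformed synergy file {path}")
    mat = np.array(rows)
    return SynergySet(S=mat[:-2], basis=mat[-2:], reference_posture=posture)
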