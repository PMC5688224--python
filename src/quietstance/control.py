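"""Control laws mapping body-in-space estimates to descending commands.

One-dimensional feedback terms are formed from the sensed head velocity /
acceleration and trunk orientation,

    f_p = -alpha_pdot * p_dot_hat - alpha_pddot * p_ddot_hat,
    f_o = -alpha_o * o_hat,

with the acceleration gain slaved to the velocity gain through a damping
ratio: ``alpha_pddot = 2 zeta sqrt(alpha_pdot)``.  Four hypotheses distribute
this low-dimensional feedback over the three joints:

A.  Ankle strategy with proximal co-contraction: ``lambda_dot = (f_p, 0, 0)``,
    knee/hip stiffened by raising their co-contraction to 0.15 rad.
B.  Ankle strategy with local proximal feedback: joint-level PD control of
    knee and hip around a reference posture; the ankle adds ``f_p``.
C.  Ankle strategy with multi-joint coordination: ``f_p`` enters only through
    the ankle column of the head Jacobian; trunk-orientation feedback is
    distributed through an augmented Jacobian constrained to leave the CoM
    unchanged; the joint-level feedback is then passed through
    ``lambda_dot = R^-1 A^-1 M F`` compensating activation sensitivity,
    muscle distribution and inertia.
D.  Distributed strategy: as C, but ``f_p`` is spread over all joints by the
    minimum-norm pseudo-inverse of the full head Jacobian.

Schemes A and B cannot stabilise stance in the presence of the neural delays,
so they default to running with both sensory delays removed, mirroring the
protocol under which they are compared to C and D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .biomechanics import TaskKinematics
from .muscle import MuscleParams, activation_and_sensitivity

SCHEMES = ("A", "B", "C", "D")

#: co-contraction applied at knee and hip under scheme A (rad), raising the
#: proximal reflex stiffness several-fold. Note: with this plant the
#: stiffened proximal loops sit beyond their oscillatory stability limit
#: (the calcium-kinetics filter lag turns the stiff reflex into a several-Hz
#: saturation-bounded limit cycle), so scheme A stands but does not sway
#: quietly; see docs/methods.md. Override via RunConfig.scheme_a_rho to
#: explore other levels (<= 0.04 rad is oscillation-free).
SCHEME_A_PROXIMAL_RHO = 0.15

#: clamp floor for |R_jj| relative to its value in the resting co-contracted
#: state, guarding the R^-1 in the coordination transform against the
#: measure-zero case of both reflex brackets cutting off
R_EPSILON_REL = 1e-6


@dataclass
class ControlGains:
    """Feedback gains. ``alpha_pddot`` is always derived from ``alpha_pdot``
    and ``zeta``, never set independently.

    The scheme-B local gains and reference posture are not part of the
    published parameter set; the defaults were fixed by a coarse stability
    search and are marked as such in the documentation.
    """

    alpha_pdot: float = 12.0    # head-velocity gain
    zeta: float = 0.5           # damping ratio
    alpha_o: float = 40.0       # trunk-orientation gain
    alpha_theta: float = 3.0    # scheme B local position gain (non-published)
    alpha_theta_dot: float = 1.0  # scheme B local velocity gain (non-published)
    theta_ref: np.ndarray = field(
        default_factory=lambda: np.array([-0.1, 0.2, -0.2]))
    o_ref: float | None = None  # rad; None = trunk orientation of theta_ref,
                                # so the loop's fixed point is the reference
                                # posture (0 restores absolute-vertical
                                # regulation)
    scheme: str = "D"

    def __post_init__(self):
        self.theta_ref = np.asarray(self.theta_ref, dtype=float)
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")

    @property
    def alpha_pddot(self) -> float:
        return 2.0 * self.zeta * math.sqrt(self.alpha_pdot)


@dataclass
class JointFeedback:
    """Task feedback mapped to joint level (schemes C/D)."""

    F_p: np.ndarray
    F_o: np.ndarray

    @property
    def F(self) -> np.ndarray:
        return self.F_p + self.F_o


def task_feedback(p_dot_hat: float, p_ddot_hat: float, o_hat: float,
                  gains: ControlGains) -> tuple[float, float]:
    """Body-in-space feedback terms (f_p, f_o).

    The orientation term regulates the sensed trunk orientation toward the
    reference orientation (by default the trunk orientation of the reference
    posture, making the reference posture the loop's fixed point).
    """
    f_p = -gains.alpha_pdot * p_dot_hat - gains.alpha_pddot * p_ddot_hat
    o_ref = gains.o_ref
    if o_ref is None:
        o_ref = -float(np.sum(gains.theta_ref))   # trunk orientation at ref
    f_o = -gains.alpha_o * (o_hat - o_ref)
    return f_p, f_o


def scheme_A_command(ankle_rate: float) -> np.ndarray:
    """Ankle-only command: ``lambda_dot = (f_p|ankle, 0, 0)``.

    ``ankle_rate`` is the task feedback already mapped to ankle threshold-rate
    units; the knee and hip thresholds are held constant (their stability
    comes from raised co-contraction).
    """
    return np.array([ankle_rate, 0.0, 0.0])


def scheme_B_command(ankle_rate: float, theta_hat, theta_dot,
                     gains: ControlGains) -> np.ndarray:
    """Local PD on every joint (true velocity, as modeled), ankle adds the
    mapped task feedback on top of its local term."""
    lam_dot = (-gains.alpha_theta * (np.asarray(theta_hat) - gains.theta_ref)
               - gains.alpha_theta_dot * np.asarray(theta_dot))
    lam_dot[0] += ankle_rate
    return lam_dot


def ankle_task_command(f_p: float, task: TaskKinematics, theta_hat,
                       theta_dot_hat, lam, lam_dot_prev, M,
                       params: MuscleParams) -> float:
    """Map the body-in-space feedback ``f_p`` to an ankle threshold rate.

    Uses the same inverse-model calibration as the coordinated schemes
    (``R^-1 A^-1 M`` applied to the ankle-restricted Jacobian pseudo-inverse),
    which converts the task-space feedback (head units) into threshold-rate
    units consistently; the raw identification ``lambda_dot_1 = f_p`` is not
    unit-consistent and overdrives the reflex loop by more than an order of
    magnitude.
    """
    fb = scheme_C_joint_feedback(f_p, 0.0, task)
    _, R_diag = activation_and_sensitivity(theta_hat, theta_dot_hat, lam,
                                           lam_dot_prev, params)
    return float(coordination_transform(fb.F, R_diag, M, params)[0])


def _orientation_feedback(f_o: float, task: TaskKinematics,
                          cond_limit: float = 1e12) -> np.ndarray:
    """Joint-level trunk-orientation feedback satisfying ``J_o F_o = f_o``
    while leaving the CoM unchanged (``J_c F_o = 0``), via the pseudo-inverse
    of the augmented Jacobian stacking J_o over J_c."""
    J_aug = np.vstack([task.J_o, task.J_c])
    if np.linalg.cond(J_aug) > cond_limit:
        raise ValueError("augmented orientation/CoM Jacobian is singular")
    return np.linalg.pinv(J_aug, rcond=1e-12) @ np.array([f_o, 0.0])


def scheme_C_joint_feedback(f_p: float, f_o: float,
                            task: TaskKinematics) -> JointFeedback:
    """Ankle-strategy coordination: f_p through the reduced (ankle-only) head
    Jacobian, f_o through the CoM-constrained augmented Jacobian."""
    J_p1 = task.J_p[0]
    if J_p1 == 0.0:
        raise ValueError("reduced head Jacobian is degenerate (J_p[0] = 0)")
    F_p = np.array([f_p / J_p1, 0.0, 0.0])
    return JointFeedback(F_p=F_p, F_o=_orientation_feedback(f_o, task))


def scheme_D_joint_feedback(f_p: float, f_o: float,
                            task: TaskKinematics) -> JointFeedback:
    """Distributed coordination: minimum-norm F_p over all joints with
    ``J_p F_p = f_p``; orientation feedback as in scheme C."""
    nrm2 = float(task.J_p @ task.J_p)
    if nrm2 <= 0.0:
        raise ValueError("head Jacobian is degenerate")
    F_p = task.J_p * (f_p / nrm2)       # J_p^+ f_p for a 1x3 row
    return JointFeedback(F_p=F_p, F_o=_orientation_feedback(f_o, task))


def activation_sensitivity(theta_hat, theta_dot_hat, lam, lam_dot,
                           params: MuscleParams) -> np.ndarray:
    """Diagonal of R = dE/d lambda (3x3 diagonal returned as 3-vector)."""
    _, R = activation_and_sensitivity(theta_hat, theta_dot_hat, lam, lam_dot,
                                      params)
    return R


def resting_sensitivity(params: MuscleParams) -> np.ndarray:
    """|R| in the resting co-contracted state (theta = lambda), used as the
    reference scale for the epsilon clamp."""
    return activation_sensitivity(np.zeros(3), np.zeros(3), np.zeros(3),
                                  np.zeros(3), params)


def coordination_transform(F, R_diag, M, params: MuscleParams,
                           eta_lambda_dot=0.0,
                           R_floor: np.ndarray | None = None) -> np.ndarray:
    """Descending command ``lambda_dot = R^-1 A^-1 M F + eta`` with the
    near-singular R clamped at a small fraction of its resting value."""
    R = np.asarray(R_diag, dtype=float).copy()
    floor = (R_EPSILON_REL * resting_sensitivity(params)
             if R_floor is None else R_floor)
    small = np.abs(R) < floor
    if np.any(small):
        R[small] = np.where(R[small] >= 0.0, floor[small], -floor[small])
    return (np.linalg.solve(params.A, np.asarray(M) @ np.asarray(F)) / R
            + np.asarray(eta_lambda_dot))


def descending_command(scheme: str, f_p: float, f_o: float,
                       task: TaskKinematics, theta_hat, theta_dot,
                       theta_dot_hat, lam, lam_dot_prev, M,
                       gains: ControlGains, params: MuscleParams,
                       eta_lambda_dot=0.0) -> np.ndarray:
    """Dispatch to the configured scheme; returns lambda_dot (rad/s).

    Descending-pathway processing noise is added to the commanded components
    of every scheme (all three for B/C/D, the ankle alone for A, whose
    proximal thresholds are held constant).
    """
    eta = np.asarray(eta_lambda_dot) * np.ones(3)
    if scheme in ("A", "B"):
        ankle_rate = ankle_task_command(f_p, task, theta_hat, theta_dot_hat,
                                        lam, lam_dot_prev, M, params)
        if scheme == "A":
            out = scheme_A_command(ankle_rate)
            out[0] += eta[0]
            return out
        return scheme_B_command(ankle_rate, theta_hat, theta_dot, gains) + eta
    if scheme == "C":
        fb = scheme_C_joint_feedback(f_p, f_o, task)
    elif scheme == "D":
        fb = scheme_D_joint_feedback(f_p, f_o, task)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    E_net, R_diag = activation_and_sensitivity(theta_hat, theta_dot_hat, lam,
                                               lam_dot_prev, params)
    return coordination_transform(fb.F, R_diag, M, params, eta)
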