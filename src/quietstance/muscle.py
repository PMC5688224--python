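"""Lumped agonist-antagonist muscle model with threshold (lambda) control.

Each joint is actuated by a single opposing muscle pair whose motoneuron pools
are driven by the tonic stretch reflex: activation grows exponentially with the
amount by which the (delayed, noisy) joint angle exceeds the reflex threshold
``lambda``, with a velocity contribution weighted by ``mu``.  Descending
commands act exclusively by moving the thresholds (equilibrium-point control);
``rho`` co-contracts the pair, raising stiffness without net torque.

Activation saturates smoothly toward ``E_max`` through a hyperbolic branch
above a crossover (75% of ``E_max``), value- and slope-continuous with the
exponential branch.  Net activation maps to steady-state joint torques through
the muscle distribution matrix ``A`` (off-diagonals = biarticular coupling),
low-pass filtered by critically damped second-order calcium kinetics
(time constant ``tau_m``).  Passive tissue contributes double-exponential
elastic torques (Riener-Edrich coefficient set, shipped as a YAML asset) and
linear viscous damping ``-B theta_dot``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

_RAD2DEG = 180.0 / math.pi

# Muscle distribution matrix: net activation -> steady-state torque (N m).
# Off-diagonal entries couple joints spanned by biarticular muscles
# (gastrocnemius, hamstrings, rectus femoris).
A_MATRIX = np.array([
    [10.94, 1.10, 0.00],
    [0.00, 7.43, 1.20],
    [0.00, 0.94, 9.10],
])

# Viscous damping matrix (N m s/rad), proportional to A row-wise: damping is
# distributed across joints the same way stiffness is.
B_MATRIX = np.array([
    [25.00, 2.51, 0.00],
    [0.00, 16.98, 2.74],
    [0.00, 2.15, 20.80],
])


@dataclass
class MuscleParams:
    """Reflex and torque-generation parameters (defaults: published set)."""

    alpha_E: float = 12.0        # 1/rad, reflex form parameter
    mu: float = 0.1              # s, reflex velocity gain
    rho: np.ndarray = field(default_factory=lambda: np.full(3, 0.01))  # rad
    tau_m: float = 0.015         # s, calcium-kinetics time constant
    E_max: float = 10.0          # activation ceiling
    crossover: float = 0.75      # saturation crossover as fraction of E_max
    sigma_m: float = 0.01        # SD of multiplicative motor noise (mean 1)
    A: np.ndarray = field(default_factory=lambda: A_MATRIX.copy())
    B: np.ndarray = field(default_factory=lambda: B_MATRIX.copy())

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.tau_m <= 0 or self.E_max <= 0:
            raise ValueError("tau_m and E_max must be positive")
        # Hyperbolic saturation branch E~ = c1/(E + c2) + c3 for E above the
        # crossover E* = crossover * E_max, determined by: asymptote E_max,
        # value and slope continuity at E*.
        e_star = self.crossover * self.E_max
        self.c2 = self.E_max - 2.0 * e_star
        self.c1 = -((self.E_max - e_star) ** 2)
        self.c3 = self.E_max
        self.e_star = e_star


@dataclass
class MuscleState:
    """Reflex thresholds and filtered active torque state."""

    lam: np.ndarray          # rad
    T_act: np.ndarray        # N m
    T_act_dot: np.ndarray    # N m / s


def _saturate(E_raw: np.ndarray, p: MuscleParams) -> np.ndarray:
    """Smooth ceiling: exponential branch below the crossover, hyperbolic
    branch (value- and slope-continuous, asymptote E_max) above it."""
    out = np.asarray(E_raw, dtype=float).copy()
    hi = out > p.e_star
    if np.any(hi):
        out[hi] = p.c1 / (out[hi] + p.c2) + p.c3
    return out


def motoneuron_activation(theta_hat, theta_dot_hat, lam, lam_dot,
                          p: MuscleParams):
    """Agonist/antagonist motoneuron pool activations per joint.

    The stretch-reflex drive is exp of the half-linear bracket of
    ``alpha_E (theta_hat - lambda +/- rho + mu (theta_dot_hat - lambda_dot))``
    minus one, so activation is zero when the sensed angle is below threshold
    and grows exponentially above it, saturating toward ``E_max``.
    """
    x = np.asarray(theta_hat) - np.asarray(lam) \
        + p.mu * (np.asarray(theta_dot_hat) - np.asarray(lam_dot))
    arg_ag = np.clip(p.alpha_E * (x + p.rho), None, 30.0)
    arg_an = np.clip(-p.alpha_E * (x - p.rho), None, 30.0)
    E_ag = np.expm1(np.maximum(arg_ag, 0.0))
    E_an = np.expm1(np.maximum(arg_an, 0.0))
    return _saturate(E_ag, p), _saturate(E_an, p)


def net_activation(E_ag, E_an, eta_m) -> np.ndarray:
    """Signed net pool activation ``(-E_AG + E_AN) * eta_m`` (multiplicative
    motor noise, mean 1, applied to the net)."""
    return (-np.asarray(E_ag) + np.asarray(E_an)) * np.asarray(eta_m)


def net_activation_per_pool(E_ag, E_an, eta_ag, eta_an) -> np.ndarray:
    """Net activation with signal-dependent noise attached to each
    motoneuron pool: ``-E_AG eta_AG + E_AN eta_AN``.

    This is the form the simulator integrates: multiplicative motor noise
    scales each pool's output, so co-contracted muscle pairs fluctuate even
    when their net drive is zero.  Wherever one pool is silent it reduces to
    the net-multiplicative law."""
    return (-np.asarray(E_ag) * np.asarray(eta_ag)
            + np.asarray(E_an) * np.asarray(eta_an))


def activation_and_sensitivity(theta_hat, theta_dot_hat, lam, lam_dot,
                               p: MuscleParams):
    """Net activation (noise-free) and its derivative w.r.t. lambda.

    The derivative is analytic through both the exponential and the hyperbolic
    saturation branch; it is diagonal by construction (each joint's threshold
    only drives its own pair), returned as a 3-vector of R_jj > 0 wherever
    either bracket is active.
    """
    x = np.asarray(theta_hat) - np.asarray(lam) \
        + p.mu * (np.asarray(theta_dot_hat) - np.asarray(lam_dot))
    # exponent clamp guards overflow deep in the (flat) saturated branch
    arg_ag = np.clip(p.alpha_E * (x + p.rho), None, 30.0)
    arg_an = np.clip(-p.alpha_E * (x - p.rho), None, 30.0)
    E_ag_raw = np.expm1(np.maximum(arg_ag, 0.0))
    E_an_raw = np.expm1(np.maximum(arg_an, 0.0))
    # d(raw)/d lambda, with the bracket gating the derivative
    dag = np.where(arg_ag > 0.0, -p.alpha_E * (E_ag_raw + 1.0), 0.0)
    dan = np.where(arg_an > 0.0, p.alpha_E * (E_an_raw + 1.0), 0.0)
    # chain through the saturation branch where active
    sat_ag = np.where(E_ag_raw > p.e_star, -p.c1 / (E_ag_raw + p.c2) ** 2, 1.0)
    sat_an = np.where(E_an_raw > p.e_star, -p.c1 / (E_an_raw + p.c2) ** 2, 1.0)
    E_net = -_saturate(E_ag_raw, p) + _saturate(E_an_raw, p)
    R_diag = -sat_ag * dag + sat_an * dan
    return E_net, R_diag


def steady_state_torque(E, p: MuscleParams) -> np.ndarray:
    """Steady-state active torque ``A @ E`` (N m)."""
    return p.A @ np.asarray(E)


def torque_filter_step(state: MuscleState, T_target, dt: float,
                       p: MuscleParams) -> MuscleState:
    """One Euler step of the critically damped second-order calcium-kinetics
    filter ``tau_m^2 T.. + 2 tau_m T. + T = T_target`` (unit DC gain)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = state.T_act
    Td = state.T_act_dot
    Tdd = (np.asarray(T_target) - T - 2.0 * p.tau_m * Td) / p.tau_m ** 2
    return MuscleState(lam=state.lam, T_act=T + dt * Td, T_act_dot=Td + dt * Tdd)


# --- passive torques ----------------------------------------------------------

@dataclass
class PassiveElasticParams:
    """Double-exponential passive torque coefficients per joint.

    Angles in degrees (anatomical convention: ankle dorsiflexion+, knee
    flexion+, hip flexion+), torques in N m, as in the source model; the
    mapping to the model joint convention is applied in
    :func:`passive_elastic_torque`.
    """

    coefficients: dict

    @classmethod
    def published(cls) -> "PassiveElasticParams":
        with resources.files("quietstance.data").joinpath(
                "passive_elastic.yaml").open() as fh:
            return cls(coefficients=yaml.safe_load(fh))

    def referenced(self, theta_ref, target_torque=None) -> "PassiveElasticParams":
        """Re-reference the constant offsets so the passive field exerts
        ``target_torque`` (default zero) at ``theta_ref``.

        The exponential terms — the stiffness structure of the field — are
        kept as transcribed; only the additive constants move.  The constants
        are the least transferable part of a passive-moment model (they
        depend on the measurement posture and population), whereas the slopes
        carry the joint-coupling physiology.  Passing the gravitational
        torque vector at the stance posture as ``target_torque`` makes the
        passive field balance gravity there, which puts every reflex pair at
        its co-contracted zero-net-activation operating point.
        """
        import copy

        raw = passive_elastic_torque(theta_ref, self)
        target = np.zeros(3) if target_torque is None else np.asarray(target_torque)
        coeff = copy.deepcopy(self.coefficients)
        for j, name in enumerate(_JOINTS):
            # undo the torque-sign mapping to adjust the source-side offset
            coeff[name]["offset"] += float((target[j] - raw[j]) / _TORQUE_SIGN[j])
        return PassiveElasticParams(coefficients=coeff)


# model theta (posterior+) -> anatomical degrees; the source convention is
# ankle plantarflexion+, knee flexion+, hip flexion+, with the moment positive
# in the positive-angle direction (each passive curve then has a negative,
# restoring slope around upright: plantarflexor moment grows with
# dorsiflexion, the knee hard stop resists hyperextension, hip extensor
# moment grows with flexion). Plantarflexion and knee flexion are positive
# model rotations, hip flexion is negative.
_ANAT_SIGN = np.array([1.0, 1.0, -1.0])
# torque conjugate to the angle map: T_model_j = sign_j * M_source_j
_TORQUE_SIGN = _ANAT_SIGN
_JOINTS = ("ankle", "knee", "hip")


def _eval_exp(term: dict, ang_deg: np.ndarray) -> float:
    return math.exp(term["const"]
                    + term["ankle"] * ang_deg[0]
                    + term["knee"] * ang_deg[1]
                    + term["hip"] * ang_deg[2])


def passive_elastic_torque(theta, params: PassiveElasticParams) -> np.ndarray:
    """Passive elastic joint torques (N m) at posture ``theta`` (rad).

    Sums two exponentials plus an offset per joint; the knee adds a hard-stop
    exponential that resists hyperextension.  Cross-joint coefficients couple
    the biarticular passive structures.
    """
    ang = _ANAT_SIGN * np.asarray(theta, dtype=float) * _RAD2DEG
    out = np.empty(3)
    for j, name in enumerate(_JOINTS):
        cj = params.coefficients[name]
        t = _eval_exp(cj["exp1"], ang) - _eval_exp(cj["exp2"], ang) + cj["offset"]
        if "hardstop" in cj:
            hs = cj["hardstop"]
            t += math.exp(hs["const"] + hs["knee"] * ang[1])
        out[j] = t
    return _TORQUE_SIGN * out


def viscous_torque(theta_dot, p: MuscleParams) -> np.ndarray:
    """Linear damping ``-B theta_dot`` (N m)."""
    return -p.B @ np.asarray(theta_dot)


def total_torque(T_act, T_ela, T_vis) -> np.ndarray:
    """Total muscle-tendon torque: active + passive elastic + viscous."""
    return np.asarray(T_act) + np.asarray(T_ela) + np.asarray(T_vis)


# --- threshold initialisation -------------------------------------------------

def invert_net_activation(E_req: float, theta_j: float, rho_j: float,
                          p: MuscleParams) -> float:
    """Threshold lambda_j producing net activation ``E_req`` at rest at angle
    ``theta_j`` (exact inverse of the monotone force-length relation).

    Three branches: both brackets active (|E| small, asinh), or one pool silent
    (log); required activations beyond the saturation crossover invert the
    hyperbolic branch first.  |E_req| >= E_max is unreachable.
    """
    a = p.alpha_E
    if abs(E_req) >= p.E_max:
        raise ValueError(
            f"required net activation {E_req:.3f} exceeds ceiling E_max={p.E_max}")
    if abs(E_req) > p.e_star:
        # dominant pool is in the hyperbolic branch; invert it to the raw
        # (pre-saturation) activation, the silent pool contributes 0
        raw = p.c1 / (abs(E_req) - p.c3) - p.c2
        mag = math.log1p(raw) / a
        return theta_j - math.copysign(1.0, E_req) * rho_j \
            + math.copysign(mag, E_req)
    both_limit = math.expm1(2.0 * a * rho_j)
    if abs(E_req) > both_limit:
        # one pool below threshold: E = sign * (exp(a(rho + |u|)) - 1)
        mag = math.log1p(abs(E_req)) / a
        return theta_j - math.copysign(1.0, E_req) * rho_j \
            + math.copysign(mag, E_req)
    # both pools active: E = -2 exp(a rho) sinh(a u), u = theta - lambda
    u = -math.asinh(0.5 * E_req * math.exp(-a * rho_j)) / a
    return theta_j - u


def initial_lambda(theta0, muscle_params: MuscleParams,
                   passive_params: PassiveElasticParams,
                   gravity_torque) -> np.ndarray:
    """Reflex thresholds that balance the body exactly at rest.

    Solves ``A E + T_ela(theta0) = N(theta0)`` for the required net
    activations (velocities zero, so no viscous torque), then inverts the
    activation law per joint.
    """
    theta0 = np.asarray(theta0, dtype=float)
    T_ela = passive_elastic_torque(theta0, passive_params)
    E_req = np.linalg.solve(muscle_params.A, np.asarray(gravity_torque) - T_ela)
    return np.array([
        invert_net_activation(E_req[j], theta0[j], muscle_params.rho[j],
                              muscle_params)
        for j in range(3)
    ])
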