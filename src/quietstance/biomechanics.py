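"""Rigid-body model of the standing body: a three-link inverted pendulum in the
sagittal plane.

The body is reduced to three segments — shank, thigh and HAT (head-arms-trunk) —
connected by revolute joints at the ankle (1), knee (2) and hip (3), standing on
a fixed base (the feet).  Joint angles ``theta`` are *relative* rotations about
the medial–lateral axis; ``theta = 0`` is the fully vertical configuration.

Sign convention
---------------
Positive joint rotation moves the distal segment *posteriorly*; anterior task
coordinates (head position ``p``, whole-body CoM ``c``) are measured positive
forward, so ``x = -l sin(phi)`` for a segment at absolute angle ``phi``.  With
this convention the standard slightly-flexed initial posture
``theta = (-0.1, 0.2, -0.2)`` rad places the whole-body centre of mass about
3 cm anterior of the ankle joint, which pins the convention to the physiology
(forward lean of the shank, flexed knee and hip).

Anthropometry follows Winter's proportionality tables (segment mass, length,
CoM location and radius of gyration as fixed fractions of body height ``h`` and
mass ``m``); the feet belong to the fixed base and are excluded, so the modeled
segment masses sum to 97.1% of body mass.

Dynamics ``M(theta) theta_dd + C(theta, theta_d) theta_d + N(theta) = T`` are
evaluated in closed form: the inertia matrix of a planar serial chain is
assembled in absolute segment angles (where it has the classic
``h_jk cos(phi_j - phi_k)`` structure), transformed to relative coordinates,
and the Coriolis matrix is built from Christoffel symbols so that
``Mdot - 2C`` is exactly skew-symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GRAVITY = 9.81  # m/s^2

# --- Winter anthropometric proportionality coefficients -----------------------
# (Winter, "Biomechanics and Motor Control of Human Movement", Table 4.1)
# lengths as fractions of body height h; masses as fractions of body mass m;
# CoM location and radius of gyration as fractions of the segment length.
_SHANK_LEN = 0.246        # ankle (lateral malleolus) to knee axis
_THIGH_LEN = 0.245        # knee to hip (greater trochanter)
_HAT_CHAIN_LEN = 0.470    # hip to vertex: chain length of the HAT link
_HAT_REF_LEN = 0.288      # greater trochanter to glenohumeral joint (Winter's
                          # HAT reference length for CoM / gyration fractions)
_ANKLE_HEIGHT = 0.039

_SHANK_MASS = 2 * 0.0465  # both legs lumped
_THIGH_MASS = 2 * 0.100
_HAT_MASS = 0.678         # head + arms + trunk

_SHANK_COM_PROX = 0.433   # from the knee (anatomically proximal) end
_THIGH_COM_PROX = 0.433   # from the hip end
_HAT_COM = 0.626          # from the hip, fraction of the trochanter-GH length
_SHANK_ROG = 0.302        # radius of gyration about CoM / segment length
_THIGH_ROG = 0.323
_HAT_ROG = 0.496          # fraction of the trochanter-GH length

MODELED_MASS_FRACTION = _SHANK_MASS + _THIGH_MASS + _HAT_MASS  # 0.971


@dataclass(frozen=True)
class SegmentParams:
    """Anthropometric parameters of the three-link chain.

    Arrays are ordered (shank, thigh, HAT).  ``com_distal`` is the CoM distance
    from the *lower* joint of each segment (ankle, knee, hip respectively);
    ``head_distance`` locates the head point along the HAT segment above the
    hip.
    """

    height: float
    mass: float
    lengths: np.ndarray        # m, hinge-to-hinge (HAT: hip to vertex)
    masses: np.ndarray         # kg
    com_distal: np.ndarray     # m, CoM distance from the lower joint
    inertias: np.ndarray       # kg m^2, about segment CoM
    head_distance: float       # m along HAT from the hip
    ankle_height: float        # m

    # derived chain constants, precomputed once (see _chain_constants)
    _h: np.ndarray = field(default=None, repr=False, compare=False)
    _gcoef: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def __post_init__(self):
        if np.any(self.lengths <= 0) or np.any(self.masses <= 0):
            raise ValueError("segment lengths and masses must be positive")
        h, g = _chain_constants(self.lengths, self.masses, self.com_distal,
                                self.inertias)
        object.__setattr__(self, "_h", h)
        object.__setattr__(self, "_gcoef", g)


def build_anthropometry(height: float, mass: float) -> SegmentParams:
    """Build segment parameters from body height (m) and mass (kg).

    Raises ``ValueError`` outside the anthropometric validity range
    (1.0-2.2 m, 30-150 kg).  Scaling is exact: masses and inertias are linear
    in body mass, lengths linear in height.
    """
    if not (1.0 <= height <= 2.2):
        raise ValueError(f"body height {height} m outside supported range [1.0, 2.2] m")
    if not (30.0 <= mass <= 150.0):
        raise ValueError(f"body mass {mass} kg outside supported range [30, 150] kg")

    lengths = np.array([_SHANK_LEN, _THIGH_LEN, _HAT_CHAIN_LEN]) * height
    masses = np.array([_SHANK_MASS, _THIGH_MASS, _HAT_MASS]) * mass
    com_distal = np.array([
        (1.0 - _SHANK_COM_PROX) * lengths[0],   # from the ankle
        (1.0 - _THIGH_COM_PROX) * lengths[1],   # from the knee
        _HAT_COM * _HAT_REF_LEN * height,       # from the hip
    ])
    rog = np.array([
        _SHANK_ROG * lengths[0],
        _THIGH_ROG * lengths[1],
        _HAT_ROG * _HAT_REF_LEN * height,
    ])
    inertias = masses * rog ** 2
    return SegmentParams(
        height=height,
        mass=mass,
        lengths=lengths,
        masses=masses,
        com_distal=com_distal,
        inertias=inertias,
        head_distance=lengths[2],          # head point at the vertex end of HAT
        ankle_height=_ANKLE_HEIGHT * height,
    )


@dataclass
class BodyState:
    """Mechanical state: joint angles and velocities (ankle, knee, hip)."""

    theta: np.ndarray       # rad
    theta_dot: np.ndarray   # rad/s

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.theta_dot = np.asarray(self.theta_dot, dtype=float)
        if self.theta.shape != (3,) or self.theta_dot.shape != (3,):
            raise ValueError("BodyState requires 3-vectors")
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.theta_dot))):
            raise ValueError("BodyState requires finite values")


@dataclass
class DynamicsMatrices:
    M: np.ndarray      # 3x3 inertia, kg m^2
    Cmat: np.ndarray   # 3x3 Coriolis/centrifugal, kg m^2/s
    N: np.ndarray      # 3-vector gravitational torques, N m


@dataclass
class TaskKinematics:
    """Task-space variables and their Jacobians w.r.t. joint angles.

    p : anterior-posterior head position (m, relative to the ankle)
    o : trunk orientation about the medial-lateral axis (rad, anterior lean
        positive, i.e. the negated absolute HAT angle)
    c : anterior-posterior whole-body CoM position relative to the ankle (m)
    """

    p: float
    o: float
    c: float
    J_p: np.ndarray
    J_o: np.ndarray
    J_c: np.ndarray
    p_dot: float
    Jdot_p: np.ndarray
    p_ddot: float | None = None


# lower-triangular ones: phi = L @ theta (absolute from relative angles)
_L = np.tril(np.ones((3, 3)))


def _chain_constants(lengths, masses, com_distal, inertias):
    """Coupling matrix h and gravity coefficients for the absolute-angle form.

    In absolute segment angles phi the planar-chain inertia matrix is
    M_abs[j,k] = h[j,k] cos(phi_j - phi_k) and the potential energy is
    sum_j gcoef[j] cos(phi_j) (+ const), with
      h[j,j]   = m_j r_j^2 + I_j + l_j^2 sum_{i>j} m_i
      h[j,k]   = l_j (m_k r_k + l_k sum_{i>k} m_i)     (j < k)
      gcoef[j] = g (m_j r_j + l_j sum_{i>j} m_i)
    """
    l, m, r, I = lengths, masses, com_distal, inertias
    h = np.zeros((3, 3))
    gc = np.zeros(3)
    for j in range(3):
        tail = m[j + 1:].sum()
        h[j, j] = m[j] * r[j] ** 2 + I[j] + l[j] ** 2 * tail
        gc[j] = GRAVITY * (m[j] * r[j] + l[j] * tail)
        for k in range(j + 1, 3):
            h[j, k] = h[k, j] = l[j] * (m[k] * r[k] + l[k] * m[k + 1:].sum())
    return h, gc


def dynamics_matrices(state: BodyState, params: SegmentParams) -> DynamicsMatrices:
    """Inertia, Coriolis and gravity terms of Lagrangian dynamics in relative
    joint coordinates.  ``Cmat`` is built from Christoffel symbols, so
    ``x^T (Mdot - 2 Cmat) x = 0`` identically."""
    theta = state.theta
    theta_dot = state.theta_dot
    h = params._h
    gc = params._gcoef

    phi = _L @ theta
    # pairwise angle differences: phi_j - phi_k
    dphi = phi[:, None] - phi[None, :]
    cdp = np.cos(dphi)
    sdp = np.sin(dphi)

    M_abs = h * cdp
    M = _L.T @ M_abs @ _L

    # dM_abs/dphi_l [l, j, k] = -h_jk sin(phi_j - phi_k) (delta_jl - delta_kl)
    hs = h * sdp
    dM_abs = np.zeros((3, 3, 3))
    for l in range(3):
        dM_abs[l, l, :] -= hs[l, :]
        dM_abs[l, :, l] += hs[:, l]
    # chain rule to relative coordinates: dM/dtheta_c = L^T (sum_l dM_abs_l L[l,c]) L
    dM = np.einsum("ja,ljk,kb,lc->cab", _L, dM_abs, _L, _L)

    # Christoffel symbols: C[i,j] = 1/2 sum_k (dM[k,i,j] + dM[j,i,k] - dM[i,j,k]) qd_k
    Cmat = 0.5 * (
        np.einsum("kij,k->ij", dM, theta_dot)
        + np.einsum("jik,k->ij", dM, theta_dot)
        - np.einsum("ijk,k->ij", dM, theta_dot)
    )

    N_abs = -gc * np.sin(phi)
    N = _L.T @ N_abs
    return DynamicsMatrices(M=M, Cmat=Cmat, N=N)


def potential_energy(state: BodyState, params: SegmentParams) -> float:
    """Gravitational potential energy (up to the constant ankle-height term)."""
    phi = _L @ state.theta
    return float(np.sum(params._gcoef * np.cos(phi)))


def kinetic_energy(state: BodyState, params: SegmentParams) -> float:
    dyn = dynamics_matrices(state, params)
    return 0.5 * float(state.theta_dot @ dyn.M @ state.theta_dot)


def _task_coefficients(params: SegmentParams):
    """Length coefficients of p and c in terms of sin(phi_j)."""
    l = params.lengths
    p_coef = np.array([l[0], l[1], params.head_distance])
    c_coef = params._gcoef / GRAVITY / params.total_mass
    return p_coef, c_coef


def forward_task_kinematics(
    state: BodyState,
    params: SegmentParams,
    theta_ddot: np.ndarray | None = None,
) -> TaskKinematics:
    """Head position ``p``, trunk orientation ``o`` and CoM position ``c``
    with their 1x3 Jacobians, plus head velocity and (given ``theta_ddot``)
    head acceleration.

    Anterior positions are ``-sum(coef * sin(phi))``; the trunk orientation is
    the negated absolute HAT angle so that an anterior trunk lean is positive,
    consistent with ``p`` and ``c``.
    """
    theta = state.theta
    theta_dot = state.theta_dot
    phi = _L @ theta
    s, c_ = np.sin(phi), np.cos(phi)
    p_coef, c_coef = _task_coefficients(params)

    p = -float(p_coef @ s)
    c = -float(c_coef @ s)
    o = -float(phi[2])

    # d phi_j / d theta_a = 1 for j >= a  =>  J[a] = -sum_{j>=a} coef_j cos(phi_j)
    J_p = np.array([-(p_coef * c_)[a:].sum() for a in range(3)])
    J_c = np.array([-(c_coef * c_)[a:].sum() for a in range(3)])
    J_o = np.array([-1.0, -1.0, -1.0])

    phi_dot = _L @ theta_dot
    Jdot_p = np.array([(p_coef * s * phi_dot)[a:].sum() for a in range(3)])
    p_dot = float(J_p @ theta_dot)
    p_ddot = None
    if theta_ddot is not None:
        p_ddot = float(J_p @ np.asarray(theta_ddot) + Jdot_p @ theta_dot)
    return TaskKinematics(p=p, o=o, c=c, J_p=J_p, J_o=J_o, J_c=J_c,
                          p_dot=p_dot, Jdot_p=Jdot_p, p_ddot=p_ddot)


def com_anterior_offset(theta, params: SegmentParams) -> float:
    """Anterior-posterior CoM offset from the ankle joint (m) at posture theta."""
    state = BodyState(theta=np.asarray(theta, float), theta_dot=np.zeros(3))
    return forward_task_kinematics(state, params).c
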