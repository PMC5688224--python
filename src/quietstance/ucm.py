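"""Uncontrolled-manifold (UCM) variance decomposition of joint sway.

For a task variable (CoM position, head position or trunk orientation) with
1x3 Jacobian J at the mean posture, joint-space variance is split into the
component parallel to the UCM (the null space of J: joint motion that leaves
the task variable unchanged) and orthogonal to it:

    V_par  = tr(E_par^T  Sigma E_par)  / k_par,    k_par  = 2
    V_perp = tr(E_perp^T Sigma E_perp) / k_perp,   k_perp = 1

with the projection bases from an SVD of J and Sigma the sample covariance of
the joint angles.  V_par > V_perp diagnoses that sway predominantly moves the
body *around* the task variable rather than moving it — the signature of task-
level coordination.

The module also provides the decorrelation surrogate (independent permutation
of each joint's samples, destroying covariation while preserving marginal
variances exactly) used to separate covariation effects from marginal-variance
effects, and shape/magnitude descriptors of the per-joint variance vector
(Euclidean norm; stereographic projection of the normalized vector about the
equal-variance pole).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomechanics import BodyState, SegmentParams, forward_task_kinematics

TASKS = ("com", "head", "orientation")

K_PAR = 2
K_PERP = 1


@dataclass
class Episode:
    """One analysis window of joint angles."""

    theta: np.ndarray        # (n, 3) rad
    t_start: float           # s, within the source series
    trial_index: int
    window_index: int


@dataclass
class UCMResult:
    task: str
    J: np.ndarray            # 1x3 task Jacobian at the mean posture
    Sigma: np.ndarray        # 3x3 sample covariance (rad^2)
    V_par: float             # rad^2 per dimension
    V_perp: float
    k_par: int = K_PAR
    k_perp: int = K_PERP

    @property
    def log_V_par(self) -> float:
        return float(np.log(self.V_par))

    @property
    def log_V_perp(self) -> float:
        return float(np.log(self.V_perp))


def partition_episodes(trajectory, episode_length: float = 30.0,
                       start_offset: float = 10.0,
                       max_episodes: int = 8) -> list[Episode]:
    """Cut a joint-angle series into contiguous non-overlapping analysis
    windows, the first starting ``start_offset`` after the series start.

    At most ``max_episodes`` windows are taken per series (the empirical
    protocol takes 8 windows of 30 s from each 5-min trial).  A series too
    short for a single full window yields an empty list.

    ``trajectory`` is either a simulator Trajectory or a tuple ``(t, theta)``
    with ``t`` in seconds and ``theta`` of shape (n, 3).
    """
    if hasattr(trajectory, "theta"):
        t = trajectory.t
        theta = trajectory.theta
        trial_index = getattr(trajectory, "trial_index", 0)
    else:
        t, theta = trajectory
        t = np.asarray(t, dtype=float)
        theta = np.asarray(theta, dtype=float)
        trial_index = 0
    if len(t) < 2:
        return []
    dt = t[1] - t[0]
    n_win = int(round(episode_length / dt))
    k_start = int(round(start_offset / dt))
    episodes = []
    w = 0
    while (w < max_episodes
           and k_start + (w + 1) * n_win <= len(t)):
        k0 = k_start + w * n_win
        episodes.append(Episode(theta=theta[k0:k0 + n_win],
                                t_start=float(t[k0]),
                                trial_index=trial_index, window_index=w))
        w += 1
    if not episodes:
        import warnings
        warnings.warn("series too short for a single episode; returning []",
                      stacklevel=2)
    return episodes


def task_jacobian(task: str, theta_mean, params: SegmentParams) -> np.ndarray:
    """1x3 Jacobian of the named task variable at a (mean) posture."""
    state = BodyState(np.asarray(theta_mean, dtype=float), np.zeros(3))
    tk = forward_task_kinematics(state, params)
    if task == "com":
        return tk.J_c
    if task == "head":
        return tk.J_p
    if task == "orientation":
        return tk.J_o
    raise ValueError(f"task must be one of {TASKS}, got {task!r}")


def ucm_decompose(joint_series, task: str,
                  params: SegmentParams) -> UCMResult:
    """Decompose the sample covariance of a joint-angle series into variance
    parallel and orthogonal to the UCM of ``task``.

    The Jacobian is linearized at the series-mean posture.  The invariant
    ``k_par V_par + k_perp V_perp = tr(Sigma)`` holds to rounding error.
    """
    theta = np.asarray(joint_series, dtype=float)
    if theta.ndim != 2 or theta.shape[1] != 3:
        raise ValueError("joint_series must have shape (n, 3)")
    if theta.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    J = np.atleast_2d(task_jacobian(task, theta.mean(axis=0), params))
    if np.allclose(J, 0.0):
        raise ValueError("degenerate (zero) task Jacobian")
    Sigma = np.cov(theta, rowvar=False)

    # SVD of J: right singular vectors split R^3 into the row space of J
    # (orthogonal to the UCM, 1-D) and its null space (the UCM, 2-D)
    _, s, Vt = np.linalg.svd(J)
    rank = int(np.sum(s > s[0] * 1e-12))
    E_perp = Vt[:rank].T            # 3 x 1
    E_par = Vt[rank:].T             # 3 x 2
    V_perp = float(np.trace(E_perp.T @ Sigma @ E_perp)) / K_PERP
    V_par = float(np.trace(E_par.T @ Sigma @ E_par)) / K_PAR
    return UCMResult(task=task, J=J[0], Sigma=Sigma, V_par=V_par,
                     V_perp=V_perp)


def decorrelate(joint_series, seed=None) -> np.ndarray:
    """Permutation surrogate: each joint's samples independently shuffled in
    time.  Marginal variances are preserved exactly; cross-correlations are
    destroyed in expectation."""
    theta = np.asarray(joint_series, dtype=float)
    rng = np.random.default_rng(seed)
    if theta.shape[0] < 2:
        return theta.copy()
    out = np.empty_like(theta)
    for j in range(theta.shape[1]):
        out[:, j] = theta[rng.permutation(theta.shape[0]), j]
    return out


# --- variance shape / magnitude descriptors ----------------------------------

# stereographic pole: the equal-variance direction, so that (v, v, v) maps to
# the origin of the shape plane
_POLE = np.ones(3) / np.sqrt(3.0)
_E1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
_E2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)


def variance_shape_magnitude(variances) -> tuple[float, np.ndarray]:
    """Magnitude (Euclidean norm) and shape (stereographic projection of the
    normalized variance vector about the equal-variance pole) of a per-joint
    variance 3-vector."""
    v = np.asarray(variances, dtype=float)
    if np.any(v < 0):
        raise ValueError("variances must be nonnegative")
    mag = float(np.linalg.norm(v))
    if mag == 0.0:
        raise ValueError("variance vector is zero")
    u = v / mag
    denom = 1.0 + float(u @ _POLE)
    shape = np.array([float(u @ _E1), float(u @ _E2)]) / denom
    return mag, shape


def shape_to_unit_vector(shape) -> np.ndarray:
    """Inverse stereographic map: shape coordinates back to the unit sphere."""
    s = np.asarray(shape, dtype=float)
    r2 = float(s @ s)
    return (2.0 * s[0] * _E1 + 2.0 * s[1] * _E2 + (1.0 - r2) * _POLE) / (1.0 + r2)


def boxcox_normalize(values):
    """Box-Cox transform with maximum-likelihood exponent (strictly positive
    input); returns (transformed, lambda)."""
    from scipy import stats

    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    transformed, lmbda = stats.boxcox(values)
    return transformed, float(lmbda)


# --- file I/O ----------------------------------------------------------------

def load_joint_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited text file with columns time_s, ankle_rad, knee_rad,
    hip_rad (header optional); returns (t, theta)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 4:
        raise ValueError("expected columns: time_s, ankle_rad, knee_rad, hip_rad")
    arr = df.to_numpy(dtype=float)
    return arr[:, 0], arr[:, 1:4]


def episode_table(results: list[UCMResult], episodes: list[Episode]) -> pd.DataFrame:
    """Tidy per-episode results table."""
    rows = []
    for res, ep in zip(results, episodes):
        rows.append(dict(trial=ep.trial_index, window=ep.window_index,
                         t_start=ep.t_start, task=res.task,
                         V_par=res.V_par, V_perp=res.V_perp,
                         log_V_par=res.log_V_par, log_V_perp=res.log_V_perp))
    return pd.DataFrame(rows)
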