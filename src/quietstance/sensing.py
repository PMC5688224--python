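"""Delayed, noise-corrupted sensory estimates.

Two sensory pathways feed the controller: proprioception (joint angles and
velocities, spinal reflex delay ``d_reflex`` = 30 ms) and body-in-space
estimates formed in the brain (head velocity and acceleration, trunk
orientation; delay ``d_brain`` = 120 ms).  All channels are corrupted by
time-correlated Ornstein-Uhlenbeck (OU) noise

    d eta = -alpha_eta * eta * dt + sigma * dW,

where ``sigma`` scales the variance of the white-noise drive (correlation
time ``1/alpha_eta``; stationary standard deviation
``sigma / sqrt(2 alpha_eta)``).  With the published magnitudes and
``alpha_eta = 5/s`` this convention reproduces both stable 35-s standing and
joint-variance levels of order 1e-5 rad^2 per degree of freedom; reading
``sigma`` as the stationary SD instead makes the model sway an order of
magnitude too much and fall.

Eyes-open (EO) vs eyes-closed (EC) differ only in the magnitudes of the three
body-in-space noise channels: removing vision degrades the accuracy of the
state estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# body-in-space noise magnitudes (head velocity m/s, head acceleration m/s^2,
# trunk orientation rad) per sensory condition
BODY_NOISE_SIGMAS = {
    "EO": {"p_dot": 0.007, "p_ddot": 0.030, "o": 0.025},
    "EC": {"p_dot": 0.010, "p_ddot": 0.032, "o": 0.032},
}


@dataclass
class NoiseChannel:
    """One OU noise stream with its own RNG."""

    sigma: float                 # stationary SD, channel units
    alpha: float = 5.0           # 1/s, inverse correlation time
    eta: float = 0.0             # current state
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))


def ou_step(channel: NoiseChannel, dt: float) -> NoiseChannel:
    """One Euler-Maruyama update of the OU channel (in place; returns it)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    channel.eta += (-channel.alpha * channel.eta * dt
                    + np.sqrt(dt) * channel.sigma
                    * channel.rng.standard_normal())
    return channel


def ou_stationary_sd(sigma: float, alpha: float) -> float:
    """Stationary standard deviation of the OU process under this scaling."""
    return sigma / np.sqrt(2.0 * alpha)


def ou_path(n: int, dt: float, sigma: float, alpha: float,
            rng: np.random.Generator, eta0: float = 0.0) -> np.ndarray:
    """Vectorised OU sample path of length ``n`` (the per-step recursion
    ``eta[k+1] = (1 - alpha dt) eta[k] + sqrt(2 alpha dt) sigma xi[k]``
    unrolled with a linear filter; identical to ``ou_step`` iterated)."""
    from scipy.signal import lfilter

    if sigma == 0.0:
        a_dec = 1.0 - alpha * dt
        return eta0 * a_dec ** np.arange(n)
    xi = rng.standard_normal(n)
    drive = np.sqrt(dt) * sigma * xi
    # eta[k] = (1 - alpha dt) eta[k-1] + drive[k-1], eta[0] = eta0
    out = np.empty(n)
    out[0] = eta0
    if n > 1:
        out[1:] = lfilter([1.0], [1.0, -(1.0 - alpha * dt)], drive[:-1],
                          zi=[(1.0 - alpha * dt) * eta0])[0]
    return out


@dataclass
class DelayBuffer:
    """Ring buffer realising a pure transport delay of ``delay`` seconds.

    The delay must be an integer multiple of ``dt`` (delays are exact at the
    simulation step).  Reads before the buffer has filled return the priming
    value: all signals are assumed constant for t < 0.
    """

    delay: float
    dt: float
    initial: float = 0.0

    def __post_init__(self):
        steps = self.delay / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"delay {self.delay} s is not an integer multiple of dt={self.dt} s")
        self.steps = int(round(steps))
        self._buf = np.full(max(self.steps, 1), float(self.initial))
        self._idx = 0
        self._count = 0

    def push(self, value: float) -> float:
        """Append the current value; return the value delayed by ``delay``."""
        if self.steps == 0:
            return float(value)
        delayed = (self._buf[self._idx] if self._count >= self.steps
                   else self._buf[self._idx])
        self._buf[self._idx] = value
        self._idx = (self._idx + 1) % self.steps
        self._count += 1
        return float(delayed)


@dataclass
class SensoryState:
    """Bundle of delay buffers and OU channels for one simulated trial."""

    d_reflex: float
    d_brain: float
    dt: float
    alpha_eta: float
    condition: str
    sigma_theta: float
    sigma_theta_dot: float
    sigma_lambda_dot: float
    channels: dict = field(default_factory=dict)
    buffers: dict = field(default_factory=dict)

    @classmethod
    def create(cls, dt, rng: np.random.Generator, condition: str = "EO",
               d_reflex: float = 0.030, d_brain: float = 0.120,
               alpha_eta: float = 5.0, sigma_theta: float = 0.002,
               sigma_theta_dot: float = 0.005, sigma_lambda_dot: float = 0.001,
               initial: dict | None = None) -> "SensoryState":
        """Build all channels/buffers; each noise channel draws from an
        independent RNG substream spawned from ``rng`` so that streams are
        mutually independent and bitwise reproducible."""
        if condition not in BODY_NOISE_SIGMAS:
            raise ValueError(f"condition must be EO or EC, got {condition!r}")
        body = BODY_NOISE_SIGMAS[condition]
        init = initial or {}
        self = cls(d_reflex=d_reflex, d_brain=d_brain, dt=dt,
                   alpha_eta=alpha_eta, condition=condition,
                   sigma_theta=sigma_theta, sigma_theta_dot=sigma_theta_dot,
                   sigma_lambda_dot=sigma_lambda_dot)
        specs = [("theta0", sigma_theta), ("theta1", sigma_theta),
                 ("theta2", sigma_theta),
                 ("theta_dot0", sigma_theta_dot), ("theta_dot1", sigma_theta_dot),
                 ("theta_dot2", sigma_theta_dot),
                 ("p_dot", body["p_dot"]), ("p_ddot", body["p_ddot"]),
                 ("o", body["o"]),
                 ("lambda_dot0", sigma_lambda_dot),
                 ("lambda_dot1", sigma_lambda_dot),
                 ("lambda_dot2", sigma_lambda_dot)]
        streams = rng.spawn(len(specs))
        for (name, sigma), sub in zip(specs, streams):
            self.channels[name] = NoiseChannel(sigma=sigma, alpha=alpha_eta,
                                               rng=sub)
        for j in range(3):
            self.buffers[f"theta{j}"] = DelayBuffer(
                d_reflex, dt, initial=init.get("theta", np.zeros(3))[j])
            self.buffers[f"theta_dot{j}"] = DelayBuffer(
                d_reflex, dt, initial=init.get("theta_dot", np.zeros(3))[j])
        for name in ("p_dot", "p_ddot", "o"):
            self.buffers[name] = DelayBuffer(d_brain, dt,
                                             initial=init.get(name, 0.0))
        return self

    def advance_noise(self):
        for ch in self.channels.values():
            ou_step(ch, self.dt)

    def proprioceptive_estimate(self, theta, theta_dot):
        """Push true kinematics, return delayed + noisy joint estimates."""
        th_hat = np.empty(3)
        thd_hat = np.empty(3)
        for j in range(3):
            th_hat[j] = (self.buffers[f"theta{j}"].push(theta[j])
                         + self.channels[f"theta{j}"].eta)
            thd_hat[j] = (self.buffers[f"theta_dot{j}"].push(theta_dot[j])
                          + self.channels[f"theta_dot{j}"].eta)
        return th_hat, thd_hat

    def body_in_space_estimate(self, p_dot, p_ddot, o):
        """Push true body-in-space kinematics, return delayed + noisy
        estimates of head velocity, head acceleration and trunk orientation."""
        return (self.buffers["p_dot"].push(p_dot) + self.channels["p_dot"].eta,
                self.buffers["p_ddot"].push(p_ddot) + self.channels["p_ddot"].eta,
                self.buffers["o"].push(o) + self.channels["o"].eta)

    def lambda_dot_noise(self) -> np.ndarray:
        """Current descending-command OU noise (3-vector)."""
        return np.array([self.channels[f"lambda_dot{j}"].eta for j in range(3)])
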