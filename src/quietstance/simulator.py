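"""Closed-loop stochastic simulation of quiet upright stance.

A trial integrates the full sensorimotor loop — delayed noisy sensing, one of
the four control schemes, spinal reflex activation, muscle torque generation
and three-link pendulum dynamics — with the stochastic Euler method at a fixed
2 ms step.  The body starts in the slightly flexed reference posture with the
reflex thresholds chosen so that active plus passive torques exactly cancel
gravity; the first seconds of each trial are discarded to wash out the primed
initial conditions.

Feedback-ablation experiments sever the loop in two ways: ``outer_cut`` sets
the descending command to zero (spinal reflexes intact), ``all_cut`` freezes
the motoneural activation at its initial value apart from motor noise.  Both
lead to falls, with characteristically different geometry: toppling (whole
body rotating the same way about the ankle) versus folding (joints moving in
opposite directions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _core, biomechanics, control, muscle
from .biomechanics import BodyState, SegmentParams, build_anthropometry, dynamics_matrices
from .control import ControlGains
from .muscle import MuscleParams, PassiveElasticParams
from .sensing import BODY_NOISE_SIGMAS, ou_path

ABLATION_MODES = ("none", "outer_cut", "all_cut")

# fixed order of the per-trial noise substreams
_NOISE_STREAMS = ("theta0", "theta1", "theta2",
                  "theta_dot0", "theta_dot1", "theta_dot2",
                  "p_dot", "p_ddot", "o",
                  "lambda_dot0", "lambda_dot1", "lambda_dot2",
                  "m_ag0", "m_ag1", "m_ag2", "m_an0", "m_an1", "m_an2")


@dataclass
class RunConfig:
    """Complete specification of a simulation experiment.

    Every published parameter is present with its default and can be
    overridden.  ``remove_delays_for_AB`` reflects the protocol that the
    non-coordinating schemes A and B run without neural delays (they cannot
    stand with them); set it False to restore the delays.
    """

    dt: float = 0.002            # s, Euler step
    duration: float = 35.0       # s per trial
    discard: float = 5.0         # s discarded at trial start
    n_trials: int = 48
    seed: int = 12345
    scheme: str = "D"
    condition: str = "EO"
    ablation: str = "none"
    height: float = 1.80         # m
    mass: float = 80.0           # kg
    theta0: np.ndarray = field(
        default_factory=lambda: np.array([-0.1, 0.2, -0.2]))
    d_reflex: float = 0.030      # s
    d_brain: float = 0.120       # s
    remove_delays_for_AB: bool = True
    alpha_eta: float = 5.0       # 1/s, OU inverse correlation time
    sigma_theta: float = 0.002
    sigma_theta_dot: float = 0.005
    sigma_lambda_dot: float = 0.001
    # body-in-space noise magnitudes; None = use the EO/EC condition values
    sigma_p_dot: float | None = None
    sigma_p_ddot: float | None = None
    sigma_o: float | None = None
    muscle: MuscleParams = field(default_factory=MuscleParams)
    gains: ControlGains = field(default_factory=ControlGains)
    deadband: float = 0.01       # rad, fall-direction classification
    fall_limit: float = 1.5      # rad, trial abort threshold
    # reference the passive-elastic offsets at theta0 so the passive field
    # carries `passive_load_share` of the gravitational torque there and the
    # muscles the rest — see docs/methods.md
    passive_reference: bool = True
    passive_load_share: float = 1.0
    # scheme-A proximal co-contraction level; None = library default
    scheme_a_rho: float | None = None

    def __post_init__(self):
        self.theta0 = np.asarray(self.theta0, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.ablation not in ABLATION_MODES:
            raise ValueError(f"ablation must be one of {ABLATION_MODES}")
        if self.scheme not in control.SCHEMES:
            raise ValueError(f"scheme must be one of {control.SCHEMES}")
        if self.condition not in BODY_NOISE_SIGMAS:
            raise ValueError("condition must be 'EO' or 'EC'")
        if self.ablation == "none" and self.duration <= self.discard:
            raise ValueError("duration must exceed the discard interval")

    @property
    def effective_d_reflex(self) -> float:
        if self.scheme in ("A", "B") and self.remove_delays_for_AB:
            return 0.0
        return self.d_reflex

    @property
    def effective_d_brain(self) -> float:
        if self.scheme in ("A", "B") and self.remove_delays_for_AB:
            return 0.0
        return self.d_brain

    @property
    def effective_rho(self) -> np.ndarray:
        """Scheme A stiffens knee and hip by raising their co-contraction."""
        rho = self.muscle.rho.copy()
        if self.scheme == "A" and self.ablation == "none":
            level = (self.scheme_a_rho if self.scheme_a_rho is not None
                     else control.SCHEME_A_PROXIMAL_RHO)
            rho[1] = rho[2] = level
        return rho

    def config_hash(self) -> str:
        """Stable short hash over all scalar/array fields, for provenance."""
        payload = {}
        for k, v in vars(self).items():
            if isinstance(v, np.ndarray):
                payload[k] = v.tolist()
            elif isinstance(v, (MuscleParams, ControlGains)):
                payload[k] = {kk: (vv.tolist() if isinstance(vv, np.ndarray)
                                   else vv)
                              for kk, vv in vars(v).items()}
            else:
                payload[k] = v
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Trajectory:
    """Stored time series of one trial (after the discard interval)."""

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    lam: np.ndarray
    E: np.ndarray
    T_act: np.ndarray
    T_ela: np.ndarray
    T_vis: np.ndarray
    p: np.ndarray
    o: np.ndarray
    c: np.ndarray
    p_dot: np.ndarray
    trial_index: int
    seed: int
    config_hash: str
    fall_time: float | None = None   # s, None if the trial stayed upright

    @property
    def T(self) -> np.ndarray:
        """Total muscle-tendon torque (exactly the sum of stored components)."""
        return self.T_act + self.T_ela + self.T_vis

    @property
    def fell(self) -> bool:
        return self.fall_time is not None


def _setup(config: RunConfig):
    """Precompute everything the kernel needs from the configuration."""
    params = build_anthropometry(config.height, config.mass)
    mp = config.muscle
    rho = config.effective_rho
    passive = PassiveElasticParams.published()
    if config.passive_reference:
        dyn_ref = dynamics_matrices(BodyState(config.theta0, np.zeros(3)), params)
        passive = passive.referenced(
            config.theta0,
            target_torque=config.passive_load_share * dyn_ref.N)

    # initial thresholds balancing gravity exactly at theta0
    dyn0 = dynamics_matrices(BodyState(config.theta0, np.zeros(3)), params)
    mp_eff = MuscleParams(alpha_E=mp.alpha_E, mu=mp.mu, rho=rho,
                          tau_m=mp.tau_m, E_max=mp.E_max,
                          crossover=mp.crossover, sigma_m=mp.sigma_m,
                          A=mp.A, B=mp.B)
    lam0 = muscle.initial_lambda(config.theta0, mp_eff, passive, dyn0.N)
    T_ela0 = muscle.passive_elastic_torque(config.theta0, passive)
    E_init = np.linalg.solve(mp.A, dyn0.N - T_ela0)
    T_act0 = mp.A @ E_init
    E_ag0, E_an0 = muscle.motoneuron_activation(
        config.theta0, np.zeros(3), lam0, np.zeros(3), mp_eff)

    pe = passive.coefficients
    pe1 = np.array([[pe[j]["exp1"][k] for k in ("const", "ankle", "knee", "hip")]
                    for j in ("ankle", "knee", "hip")])
    pe2 = np.array([[pe[j]["exp2"][k] for k in ("const", "ankle", "knee", "hip")]
                    for j in ("ankle", "knee", "hip")])
    pe_off = np.array([pe[j]["offset"] for j in ("ankle", "knee", "hip")])
    pe_hs = np.array([pe["knee"]["hardstop"]["const"],
                      pe["knee"]["hardstop"]["knee"]])

    p_coef = np.array([params.lengths[0], params.lengths[1],
                       params.head_distance])
    c_coef = params._gcoef / biomechanics.GRAVITY / params.total_mass

    R_floor = control.R_EPSILON_REL * 2.0 * mp.alpha_E * np.exp(mp.alpha_E * rho)

    return dict(
        params=params, mp=mp_eff, passive=passive, lam0=lam0, E_init=E_init,
        E_ag0=np.asarray(E_ag0), E_an0=np.asarray(E_an0),
        T_act0=T_act0, pe1=pe1, pe2=pe2, pe_off=pe_off, pe_hs=pe_hs,
        p_coef=p_coef, c_coef=c_coef, R_floor=R_floor,
        Ainv=np.linalg.inv(mp.A),
        anat_sign=np.array([1.0, 1.0, -1.0]),
    )


def _noise_paths(config: RunConfig, trial_ss: np.random.SeedSequence, n: int):
    """Pregenerate all noise sample paths for one trial, one independent RNG
    substream per channel (order fixed by ``_NOISE_STREAMS``)."""
    streams = {name: np.random.default_rng(ss)
               for name, ss in zip(_NOISE_STREAMS, trial_ss.spawn(len(_NOISE_STREAMS)))}
    body = dict(BODY_NOISE_SIGMAS[config.condition])
    for key, override in (("p_dot", config.sigma_p_dot),
                          ("p_ddot", config.sigma_p_ddot),
                          ("o", config.sigma_o)):
        if override is not None:
            body[key] = override
    a = config.alpha_eta
    dt = config.dt

    def ou(name, sigma):
        return ou_path(n, dt, sigma, a, streams[name])

    eta_th = np.column_stack([ou(f"theta{j}", config.sigma_theta)
                              for j in range(3)])
    eta_thd = np.column_stack([ou(f"theta_dot{j}", config.sigma_theta_dot)
                               for j in range(3)])
    eta_pd = ou("p_dot", body["p_dot"])
    eta_pdd = ou("p_ddot", body["p_ddot"])
    eta_o = ou("o", body["o"])
    eta_ld = np.column_stack([ou(f"lambda_dot{j}", config.sigma_lambda_dot)
                              for j in range(3)])
    # multiplicative motor noise, one stream per motoneuron pool: per-step
    # iid Gaussian, mean 1, clipped at 0
    def pool(name):
        return np.column_stack([
            np.maximum(1.0 + config.muscle.sigma_m
                       * streams[f"{name}{j}"].standard_normal(n), 0.0)
            for j in range(3)])

    return (eta_th, eta_thd, eta_pd, eta_pdd, eta_o, eta_ld,
            pool("m_ag"), pool("m_an"))


def run_trial(config: RunConfig, trial_index: int = 0,
              _setup_cache: dict | None = None) -> Trajectory:
    """Simulate one trial; the trajectory is reproducibly determined by
    (config.seed, trial_index).  The stored series start after the discard
    interval (or at t = 0 for ablation runs, which use ``discard`` as given,
    typically 0)."""
    su = _setup_cache if _setup_cache is not None else _setup(config)
    n = int(round(config.duration / config.dt))
    dr = int(round(config.effective_d_reflex / config.dt))
    db = int(round(config.effective_d_brain / config.dt))

    master = np.random.SeedSequence(config.seed)
    trial_ss = master.spawn(config.n_trials if trial_index < config.n_trials
                            else trial_index + 1)[trial_index]
    noise = _noise_paths(config, trial_ss, n)

    out = {name: np.empty((n, 3)) for name in
           ("theta", "theta_dot", "lam", "E", "T_act", "T_ela", "T_vis")}
    out_s = {name: np.empty(n) for name in ("p", "o", "c", "p_dot", "p_ddot")}

    mp = su["mp"]
    gains = config.gains
    n_done = _core.trial_kernel(
        n, config.dt, dr, db,
        su["params"]._h, su["params"]._gcoef, su["p_coef"], su["c_coef"],
        mp.A, su["Ainv"], mp.B,
        su["pe1"], su["pe2"], su["pe_off"], su["pe_hs"], su["anat_sign"],
        mp.alpha_E, mp.mu, mp.rho, mp.tau_m, mp.E_max, mp.e_star,
        mp.c1, mp.c2, mp.c3,
        gains.alpha_pdot, gains.alpha_pddot, gains.alpha_o,
        (gains.o_ref if gains.o_ref is not None
         else -float(np.sum(gains.theta_ref))),
        gains.alpha_theta, gains.alpha_theta_dot, gains.theta_ref,
        _core.SCHEME_CODE[config.scheme], _core.ABLATION_CODE[config.ablation],
        su["R_floor"],
        config.theta0, su["lam0"], su["E_ag0"], su["E_an0"], su["T_act0"],
        *noise,
        config.fall_limit,
        out["theta"], out["theta_dot"], out["lam"], out["E"],
        out["T_act"], out["T_ela"], out["T_vis"],
        out_s["p"], out_s["o"], out_s["c"], out_s["p_dot"], out_s["p_ddot"],
    )

    fall_time = None if n_done == n else n_done * config.dt
    k0 = min(int(round(config.discard / config.dt)), n_done)
    t = np.arange(k0, n_done) * config.dt
    return Trajectory(
        t=t,
        theta=out["theta"][k0:n_done], theta_dot=out["theta_dot"][k0:n_done],
        lam=out["lam"][k0:n_done], E=out["E"][k0:n_done],
        T_act=out["T_act"][k0:n_done], T_ela=out["T_ela"][k0:n_done],
        T_vis=out["T_vis"][k0:n_done],
        p=out_s["p"][k0:n_done], o=out_s["o"][k0:n_done],
        c=out_s["c"][k0:n_done], p_dot=out_s["p_dot"][k0:n_done],
        trial_index=trial_index, seed=config.seed,
        config_hash=config.config_hash(), fall_time=fall_time,
    )


class ReferenceLoop:
    """Readable, step-at-a-time composition of the sensorimotor loop.

    Mirrors the compiled trial kernel operation for operation (same update
    order, same delay priming), built from the public module functions.  It
    exists as the reference semantics of one Euler step — ``step()`` advances
    sensing -> control -> threshold integration -> reflex activation ->
    torque generation -> rigid-body dynamics -> state integration — and as
    the oracle against which the compiled kernel is verified.  Noise
    sequences are injected explicitly so both paths can consume identical
    samples.
    """

    def __init__(self, config: RunConfig, setup: dict | None = None):
        from .control import descending_command

        self.config = config
        self.su = setup if setup is not None else _setup(config)
        self.dt = config.dt
        self.dr = int(round(config.effective_d_reflex / config.dt))
        self.db = int(round(config.effective_d_brain / config.dt))
        self.mp = self.su["mp"]
        self.params = self.su["params"]
        self.gains = config.gains
        self.o_ref = (config.gains.o_ref if config.gains.o_ref is not None
                      else -float(np.sum(config.gains.theta_ref)))
        self.body = biomechanics.BodyState(config.theta0.copy(), np.zeros(3))
        self.muscle_state = muscle.MuscleState(
            lam=self.su["lam0"].copy(), T_act=self.su["T_act0"].copy(),
            T_act_dot=np.zeros(3))
        self.lam_dot = np.zeros(3)
        # stored histories for the transport delays
        self.hist_theta = [config.theta0.copy()]
        self.hist_theta_dot = [np.zeros(3)]
        self.hist_p_dot: list[float] = []
        self.hist_p_ddot: list[float] = []
        self.hist_o: list[float] = []
        self.k = 0
        self._descending_command = descending_command

    def step(self, eta_th=np.zeros(3), eta_thd=np.zeros(3), eta_pd=0.0,
             eta_pdd=0.0, eta_o=0.0, eta_ld=np.zeros(3),
             eta_m_ag=np.ones(3), eta_m_an=np.ones(3)) -> dict:
        """Advance one Euler step; returns the stored step record."""
        from . import control as ctl

        cfg = self.config
        k = self.k
        theta = self.body.theta
        theta_dot = self.body.theta_dot
        tk = biomechanics.forward_task_kinematics(self.body, self.params)
        self.hist_p_dot.append(tk.p_dot)
        self.hist_o.append(tk.o)

        # sensing (delayed + noisy; signals constant for t < 0)
        idx = max(k - self.dr, 0)
        th_hat = self.hist_theta[idx] + eta_th
        thd_hat = self.hist_theta_dot[idx] + eta_thd
        idxb = k - self.db if self.db > 0 else k - 1
        if idxb < 0:
            p_dot_del, p_ddot_del, o_del = self.hist_p_dot[0], 0.0, self.hist_o[0]
        else:
            p_dot_del = self.hist_p_dot[idxb]
            p_ddot_del = self.hist_p_ddot[idxb]
            o_del = self.hist_o[idxb]

        f_p, f_o = ctl.task_feedback(p_dot_del + eta_pd, p_ddot_del + eta_pdd,
                                     o_del + eta_o, self.gains)
        dyn = biomechanics.dynamics_matrices(self.body, self.params)
        if cfg.ablation == "outer_cut":
            lam_dot = np.zeros(3)
        else:
            lam_dot = self._descending_command(
                cfg.scheme, f_p, f_o, tk, th_hat, theta_dot, thd_hat,
                self.muscle_state.lam, self.lam_dot, dyn.M, self.gains,
                self.mp, eta_ld)

        # reflex activation with the new command; threshold integration
        if cfg.ablation == "all_cut":
            E = muscle.net_activation_per_pool(self.su["E_ag0"],
                                               self.su["E_an0"],
                                               eta_m_ag, eta_m_an)
        else:
            E_ag, E_an = muscle.motoneuron_activation(
                th_hat, thd_hat, self.muscle_state.lam, lam_dot, self.mp)
            E = muscle.net_activation_per_pool(E_ag, E_an, eta_m_ag, eta_m_an)
        lam = self.muscle_state.lam + self.dt * lam_dot

        # torques and dynamics
        T_ela = muscle.passive_elastic_torque(theta, self.su["passive"])
        T_vis = muscle.viscous_torque(theta_dot, self.mp)
        T = muscle.total_torque(self.muscle_state.T_act, T_ela, T_vis)
        new_muscle = muscle.torque_filter_step(
            self.muscle_state, muscle.steady_state_torque(E, self.mp),
            self.dt, self.mp)
        theta_ddot = np.linalg.solve(dyn.M, T - dyn.Cmat @ theta_dot - dyn.N)
        p_ddot = float(tk.J_p @ theta_ddot + tk.Jdot_p @ theta_dot)
        self.hist_p_ddot.append(p_ddot)

        record = dict(theta=theta.copy(), theta_dot=theta_dot.copy(),
                      lam=self.muscle_state.lam.copy(), E=E.copy(),
                      T_act=self.muscle_state.T_act.copy(), T_ela=T_ela,
                      T_vis=T_vis, p=tk.p, o=tk.o, c=tk.c, p_dot=tk.p_dot,
                      p_ddot=p_ddot)

        # Euler integration
        new_theta = theta + self.dt * theta_dot
        new_theta_dot = theta_dot + self.dt * theta_ddot
        if not np.all(np.isfinite(new_theta)):
            raise FloatingPointError("non-finite state; trial aborted")
        self.body = biomechanics.BodyState(new_theta, new_theta_dot)
        self.muscle_state = muscle.MuscleState(lam=lam, T_act=new_muscle.T_act,
                                               T_act_dot=new_muscle.T_act_dot)
        self.lam_dot = lam_dot
        self.hist_theta.append(new_theta.copy())
        self.hist_theta_dot.append(new_theta_dot.copy())
        self.k += 1
        return record


def run_trials(config: RunConfig) -> list[Trajectory]:
    """Simulate all ``config.n_trials`` trials (independent noise substreams
    derived from the master seed)."""
    su = _setup(config)
    return [run_trial(config, i, _setup_cache=su)
            for i in range(config.n_trials)]


def ablate(config: RunConfig, mode: str) -> RunConfig:
    """Derive a feedback-ablation configuration: ``outer_cut`` zeroes the
    descending command (reflex loop intact), ``all_cut`` freezes motoneural
    activation at its initial value except for motor noise.  Ablation trials
    keep the whole trajectory (no discard)."""
    if mode not in ("outer_cut", "all_cut"):
        raise ValueError("mode must be 'outer_cut' or 'all_cut'")
    return replace(config, ablation=mode, discard=0.0)


def classify_posture(theta_frame, theta0, deadband: float = 0.01) -> str:
    """Label one posture frame relative to the initial posture.

    ``folding``: at least two joints have left the deadband in *different*
    directions (collapse); ``toppling``: joints outside the deadband all moved
    the same way (whole-body rotation); ``upright``: no joint outside.
    """
    if deadband < 0:
        raise ValueError("deadband must be nonnegative")
    dev = np.asarray(theta_frame, dtype=float) - np.asarray(theta0, dtype=float)
    signs = np.sign(dev) * (np.abs(dev) > deadband)
    pos = np.any(signs > 0)
    neg = np.any(signs < 0)
    if not (pos or neg):
        return "upright"
    if pos and neg:
        return "folding"
    return "toppling"


def _label_at(traj: Trajectory, t: float, theta0, deadband) -> str:
    """Classification at time t, using the last stored frame if the trial
    ended (fell) earlier."""
    if len(traj.t) == 0:
        return "upright"
    k = np.searchsorted(traj.t, t)
    k = min(k, len(traj.t) - 1)
    return classify_posture(traj.theta[k], theta0, deadband)


def toppling_fraction(config: RunConfig, mode: str, checkpoints,
                      n_trials: int | None = None) -> dict:
    """Percentage of ablated trials classified as toppling at each checkpoint
    time (s).  Trials that fell before a checkpoint keep their final label."""
    cfg = ablate(config, mode)
    if n_trials is not None:
        cfg = replace(cfg, n_trials=n_trials)
    cfg = replace(cfg, duration=float(max(checkpoints)) + cfg.dt)
    trajs = run_trials(cfg)
    out = {}
    for t in checkpoints:
        labels = [_label_at(tr, t, cfg.theta0, cfg.deadband) for tr in trajs]
        out[t] = 100.0 * np.mean([lab == "toppling" for lab in labels])
    return out
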