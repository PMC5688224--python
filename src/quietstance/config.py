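"""Experiment configuration: serializable specs binding the simulator and the
UCM analysis into reproducible runs.

A spec is a YAML mapping with an experiment name (``main_comparison``,
``ablation`` or ``ucm_report``), an output directory, report options, and any
subset of the run-configuration keys (absent keys take the published
defaults).  Unknown keys are rejected rather than ignored, so typos cannot
silently run a different experiment.  Every output file carries the
configuration hash and master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .control import ControlGains
from .muscle import MuscleParams
from .simulator import RunConfig

EXPERIMENTS = ("main_comparison", "ablation", "ucm_report")

# RunConfig keys settable from a config file (arrays given as lists)
_RUN_KEYS = {f.name for f in dataclasses.fields(RunConfig)} - {"muscle", "gains"}
_GAIN_KEYS = {f.name for f in dataclasses.fields(ControlGains)}
_MUSCLE_KEYS = {"alpha_E", "mu", "rho", "tau_m", "E_max", "crossover", "sigma_m"}


@dataclass
class ExperimentSpec:
    """A named experiment plus its full run configuration."""

    experiment: str = "main_comparison"
    output_dir: str = "results"
    run: RunConfig = field(default_factory=RunConfig)
    # experiment-specific options
    checkpoints: list = field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0])
    ablation_trials: int = 200
    tasks: list = field(default_factory=lambda: ["com", "head", "orientation"])
    input_series: str | None = None     # external joint-angle file for ucm_report
    write_trajectories: bool = False

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}, "
                             f"got {self.experiment!r}")

    def to_dict(self) -> dict:
        out = {k: v for k, v in vars(self).items() if k != "run"}
        run = {}
        for k in _RUN_KEYS:
            v = getattr(self.run, k)
            run[k] = v.tolist() if isinstance(v, np.ndarray) else v
        run["gains"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in vars(self.run.gains).items()}
        run["muscle"] = {k: (np.asarray(getattr(self.run.muscle, k)).tolist()
                             if k == "rho" else getattr(self.run.muscle, k))
                         for k in _MUSCLE_KEYS}
        out["run"] = run
        return out

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _build_run_config(run_block: dict) -> RunConfig:
    unknown = set(run_block) - _RUN_KEYS - {"gains", "muscle"}
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    gains_kw = dict(run_block.pop("gains", {}) or {})
    muscle_kw = dict(run_block.pop("muscle", {}) or {})
    bad = set(gains_kw) - _GAIN_KEYS
    if bad:
        raise ValueError(f"unknown gain keys: {sorted(bad)}")
    bad = set(muscle_kw) - _MUSCLE_KEYS
    if bad:
        raise ValueError(f"unknown muscle keys: {sorted(bad)}")
    if "theta_ref" in gains_kw:
        gains_kw["theta_ref"] = np.asarray(gains_kw["theta_ref"], float)
    if "rho" in muscle_kw:
        muscle_kw["rho"] = np.asarray(muscle_kw["rho"], float)
    if "theta0" in run_block:
        run_block["theta0"] = np.asarray(run_block["theta0"], float)
    return RunConfig(gains=ControlGains(**gains_kw),
                     muscle=MuscleParams(**muscle_kw), **run_block)


def load_config(path) -> ExperimentSpec:
    """Read an experiment spec from YAML; absent keys take the published
    defaults, unknown keys raise with the offending names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    run_block = dict(raw.pop("run", {}) or {})
    spec_keys = {f.name for f in dataclasses.fields(ExperimentSpec)} - {"run"}
    unknown = set(raw) - spec_keys
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return ExperimentSpec(run=_build_run_config(run_block), **raw)


def run_experiment(spec: ExperimentSpec) -> dict:
    """Execute the named experiment; writes per-result text/JSON files into
    the output directory and returns the summary dictionary."""
    from . import ucm
    from .biomechanics import build_anthropometry
    from .simulator import run_trials, toppling_fraction

    outdir = Path(spec.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = spec.run
    meta = dict(config_hash=cfg.config_hash(), seed=cfg.seed,
                experiment=spec.experiment)
    params = build_anthropometry(cfg.height, cfg.mass)
    summary: dict = dict(meta=meta)

    if spec.experiment == "main_comparison":
        blocks = {}
        for scheme in "ABCD":
            for cond in ("EO", "EC"):
                c = dataclasses.replace(cfg, scheme=scheme, condition=cond)
                trs = run_trials(c)
                per_trial = []
                for tr in trs:
                    if tr.fell:
                        continue
                    row = dict(trial=tr.trial_index)
                    for task in spec.tasks:
                        r = ucm.ucm_decompose(tr.theta, task, params)
                        row[f"V_par_{task}"] = r.V_par
                        row[f"V_perp_{task}"] = r.V_perp
                    per_trial.append(row)
                n_falls = sum(t.fell for t in trs)
                block = dict(n_trials=c.n_trials, falls=int(n_falls))
                for task in spec.tasks:
                    vp = [r[f"V_par_{task}"] for r in per_trial]
                    vo = [r[f"V_perp_{task}"] for r in per_trial]
                    if vp:
                        block[f"median_V_par_{task}"] = float(np.median(vp))
                        block[f"median_V_perp_{task}"] = float(np.median(vo))
                blocks[f"{scheme}_{cond}"] = block
                if spec.write_trajectories:
                    for tr in trs[:1]:
                        _write_trajectory(tr, outdir / f"traj_{scheme}_{cond}.csv")
        summary["blocks"] = blocks
    elif spec.experiment == "ablation":
        for mode in ("outer_cut", "all_cut"):
            fr = toppling_fraction(cfg, mode, spec.checkpoints,
                                   n_trials=spec.ablation_trials)
            summary[mode] = {str(k): float(v) for k, v in fr.items()}
    elif spec.experiment == "ucm_report":
        if spec.input_series:
            t, theta = ucm.load_joint_series(spec.input_series)
            series = [(t, theta)]
        else:
            trs = run_trials(cfg)
            series = [(tr.t, tr.theta) for tr in trs if not tr.fell]
        rows = []
        for i, s in enumerate(series):
            for ep in ucm.partition_episodes(s):
                for task in spec.tasks:
                    r = ucm.ucm_decompose(ep.theta, task, params)
                    rows.append(dict(series=i, window=ep.window_index,
                                     task=task, V_par=r.V_par,
                                     V_perp=r.V_perp))
        import pandas as pd
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "ucm_episodes.csv", index=False)
        summary["n_episd"] = len(rows)
        if len(df):
            summary["median_V_par"] = {t: float(df[df.task == t].V_par.median())
                                       for t in spec.tasks}
            summary["median_V_perp"] = {t: float(df[df.task == t].V_perp.median())
                                        for t in spec.tasks}

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    spec.save(outdir / "spec.yaml")
    return summary


def _write_trajectory(tr, path):
    import pandas as pd

    df = pd.DataFrame({
        "time_s": tr.t,
        "ankle_rad": tr.theta[:, 0], "knee_rad": tr.theta[:, 1],
        "hip_rad": tr.theta[:, 2],
        "com_m": tr.c, "head_m": tr.p, "trunk_rad": tr.o,
    })
    with open(path, "w") as fh:
        fh.write(f"# config_hash={tr.config_hash} seed={tr.seed} "
                 f"trial={tr.trial_index}\n")
        df.to_csv(fh, index=False)
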