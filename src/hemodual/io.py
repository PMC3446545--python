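"""Tabular readers/writers and the JSON run configuration.

Time-series files are TSV or CSV with a header row containing at least
``time``, ``u``, ``y`` (seconds, input amplitude, BOLD signal); simulator
output adds ``y_clean`` and the ground-truth states ``f, s, q, v``.  All
floats are written with 17 significant digits so a written file reproduces
the in-memory values exactly, and two runs with the same configuration and
seed produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dual import default_noise_spec, default_param_belief, default_state_belief
from .hemodynamics import HemoParams, StimulusTrain
from .synthetic import PRIOR_MEANS, BlockDesign, SimulationConfig
from .trace import FREE_PARAM_NAMES, FilterTrace
from .ukf import GaussianBelief, NoiseSpec, UTConfig

__all__ = [
    "RunConfig",
    "read_series",
    "write_series",
    "write_trace",
    "write_summary",
    "load_run_config",
    "load_sim_config",
]

_FLOAT_FMT = "%.17g"


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def read_series(path: str | Path) -> tuple[StimulusTrain, np.ndarray]:
    """Read a (time, u, y) series; delimiter sniffed between tab and comma.

    Raises ValueError naming the problem: a missing column, a non-uniform
    time grid, or non-finite values.
    """
    header = Path(path).open().readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in ("time", "u", "y"):
        if col not in df.columns:
            raise ValueError(f"series file {path} is missing column '{col}'")
    t = df["time"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-6 * max(abs(dt[0]), 1e-30)):
            raise ValueError(f"series file {path} has a non-uniform time grid")
    for col in ("time", "u", "y"):
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise ValueError(f"series file {path} has non-finite values in '{col}'")
    stim = StimulusTrain(times=t, u=df["u"].to_numpy(dtype=float))
    return stim, df["y"].to_numpy(dtype=float)


def write_series(df: pd.DataFrame, path: str | Path) -> None:
    """Write a series DataFrame as TSV with full-precision floats."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_trace(trace: FilterTrace, path: str | Path) -> None:
    """Write the per-acquisition trace TSV (schema: time, y, y_hat, states,
    parameters, innovation)."""
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_summary(trace: FilterTrace, path: str | Path, config_echo: dict | None = None) -> None:
    """Write the JSON run summary: final parameter means/SDs, innovation
    statistics, diagnostics counters, config echo, package version."""
    nu = trace.innovations[1:]
    summary = {
        "scheme": trace.scheme,
        "n_scans": int(len(trace)),
        "final_params": {k: float(v) for k, v in trace.final_params.items()},
        "final_param_sds": {k: float(v) for k, v in trace.final_param_sds.items()},
        "innovation_rms": float(np.sqrt(np.mean(nu**2))),
        "log_likelihood_proxy": trace.log_likelihood_proxy(),
        "diagnostics": {
            "projections": int(trace.diagnostics.get("projections", 0)),
            "positivity_clips": int(trace.diagnostics.get("positivity_clips", 0)),
            "jitter_events": int(trace.diagnostics.get("jitter_events", 0)),
        },
        "config": config_echo or {},
        "version": __version__,
    }
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """Validated filter-run configuration (JSON on disk).

    Noise may be given as convenience scalars (``obs_sd``, ``q_var``,
    ``rr_scale``, fed to :func:`hemodual.dual.default_noise_spec`) or as
    explicit matrices ``Q``, ``R``, ``R_r`` which take precedence.
    """

    dt_sub: float = 0.1
    ut: UTConfig = field(default_factory=UTConfig)
    noise: NoiseSpec = None
    init_state: GaussianBelief = None
    init_params: GaussianBelief = None
    alpha: float = PRIOR_MEANS["alpha"]
    V_0: float = PRIOR_MEANS["V_0"]
    augmented: bool = False
    state_first: bool = True
    log_space: bool = False
    rr_decay: float = 1.0
    param_r_scale: float = 30.0
    raw: dict = field(default_factory=dict)


_RUN_KEYS = {"dt_sub", "ut", "noise", "init", "fixed", "mode", "rr_decay",
             "param_r_scale"}
_UT_KEYS = {"alpha", "beta", "kappa"}
_NOISE_KEYS = {"obs_sd", "q_var", "rr_scale", "Q", "R", "R_r"}
_INIT_KEYS = {"state_cov", "param_shift_sds", "param_means", "param_cov"}
_FIXED_KEYS = {"alpha", "V_0"}
_MODE_KEYS = {"augmented", "state_first", "log_space"}


def run_config_from_dict(cfg: dict) -> RunConfig:
    _check_keys(cfg, _RUN_KEYS, "run config")
    ut_d = cfg.get("ut", {})
    _check_keys(ut_d, _UT_KEYS, "run config 'ut'")
    ut = UTConfig(
        alpha_ut=float(ut_d.get("alpha", 1.0)),
        beta_ut=float(ut_d.get("beta", 2.0)),
        kappa_ut=None if ut_d.get("kappa") is None else float(ut_d["kappa"]),
    )

    noise_d = cfg.get("noise", {})
    _check_keys(noise_d, _NOISE_KEYS, "run config 'noise'")
    if "obs_sd" not in noise_d and "R" not in noise_d:
        raise ValueError("run config 'noise' must set obs_sd or R")
    base = default_noise_spec(
        obs_noise_sd=float(noise_d.get("obs_sd", 0.0)),
        q_var=float(noise_d.get("q_var", 1e-6)),
        rr_scale=float(noise_d.get("rr_scale", 1e-4)),
    )
    Q = np.atleast_2d(np.asarray(noise_d["Q"], dtype=float)) if "Q" in noise_d else base.Q
    if Q.shape == (1, 1):
        Q = float(Q[0, 0]) * np.eye(4)
    R = np.atleast_2d(np.asarray(noise_d["R"], dtype=float)) if "R" in noise_d else base.R
    R_r = np.atleast_2d(np.asarray(noise_d["R_r"], dtype=float)) if "R_r" in noise_d else base.R_r
    noise = NoiseSpec(Q=Q, R=R, R_r=R_r)

    init_d = cfg.get("init", {})
    _check_keys(init_d, _INIT_KEYS, "run config 'init'")
    init_state = default_state_belief(float(init_d.get("state_cov", 1e-2)))
    init_params = default_param_belief(float(init_d.get("param_shift_sds", 0.0)))
    if "param_means" in init_d:
        init_params.mean = np.asarray(init_d["param_means"], dtype=float)
    if "param_cov" in init_d:
        pc = np.atleast_2d(np.asarray(init_d["param_cov"], dtype=float))
        init_params.cov = pc if pc.shape == (5, 5) else float(pc[0, 0]) * np.eye(5)

    fixed_d = cfg.get("fixed", {})
    _check_keys(fixed_d, _FIXED_KEYS, "run config 'fixed'")
    mode_d = cfg.get("mode", {})
    _check_keys(mode_d, _MODE_KEYS, "run config 'mode'")

    return RunConfig(
        dt_sub=float(cfg.get("dt_sub", 0.1)),
        ut=ut,
        noise=noise,
        init_state=init_state,
        init_params=init_params,
        alpha=float(fixed_d.get("alpha", PRIOR_MEANS["alpha"])),
        V_0=float(fixed_d.get("V_0", PRIOR_MEANS["V_0"])),
        augmented=bool(mode_d.get("augmented", False)),
        state_first=bool(mode_d.get("state_first", True)),
        log_space=bool(mode_d.get("log_space", False)),
        rr_decay=float(cfg.get("rr_decay", 1.0)),
        param_r_scale=float(cfg.get("param_r_scale", 30.0)),
        raw=cfg,
    )


def load_run_config(path: str | Path) -> RunConfig:
    return run_config_from_dict(json.loads(Path(path).read_text()))


_SIM_KEYS = {"design", "params", "process_noise_sd", "obs_noise_sd",
             "obs_noise_frac_of_peak", "seed", "dt_sub"}
_DESIGN_KEYS = {"n_blocks", "scans_per_block", "tr", "lead_in_scans", "start_with_rest"}


def sim_config_from_dict(cfg: dict, seed_override: int | None = None):
    """Parse a simulation config; returns (SimulationConfig, frac_of_peak).

    ``obs_noise_frac_of_peak`` (e.g. 0.1 for 10 % of the clean peak) is
    resolved by the caller once the clean trace is known; it is mutually
    exclusive with an absolute ``obs_noise_sd``.
    """
    _check_keys(cfg, _SIM_KEYS, "simulation config")
    design_d = dict(cfg.get("design", {}))
    _check_keys(design_d, _DESIGN_KEYS, "simulation config 'design'")
    design = BlockDesign(**design_d)
    params = HemoParams.from_dict({**PRIOR_MEANS, **cfg.get("params", {})})
    frac = cfg.get("obs_noise_frac_of_peak")
    if frac is not None and "obs_noise_sd" in cfg:
        raise ValueError("set obs_noise_sd or obs_noise_frac_of_peak, not both")
    seed = seed_override if seed_override is not None else cfg.get("seed")
    if seed is None:
        raise ValueError("simulation config requires a seed")
    sim = SimulationConfig(
        design=design,
        params=params,
        process_noise_sd=cfg.get("process_noise_sd"),
        obs_noise_sd=float(cfg.get("obs_noise_sd", 0.0)),
        seed=int(seed),
        dt_sub=float(cfg.get("dt_sub", 0.1)),
    )
    return sim, (None if frac is None else float(frac))


def load_sim_config(path: str | Path, seed_override: int | None = None):
    return sim_config_from_dict(json.loads(Path(path).read_text()), seed_override)
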