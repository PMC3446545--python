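"""Synthetic BOLD data with an alternating block design.

The generator emulates a standard auditory block paradigm: 136 acquisitions
at TR = 2 s, consisting of an 8-scan rest lead-in followed by 16 alternating
16-second blocks of 8 scans each, starting with rest.  Ground-truth
trajectories are integrated from rest with the same RK4 scheme the filters
use; process noise (if any) enters the states additively at substep
resolution with sqrt(dt) scaling, and observation noise is added per
acquisition.

Truth parameters default to the prior means: eps = 0.54, tau_s = 1.54 s,
tau_f = 2.46 s, tau_0 = 0.98 s, alpha = 0.33, E_0 = 0.34, V_0 = 0.02; the
prior itself is a set of independent normals (see ``PRIOR_MEANS`` /
``PRIOR_SDS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemodynamics import (
    HemoParams,
    StimulusTrain,
    apply_positivity_floor,
    bold_observe,
    rk4_substep,
)

__all__ = [
    "BlockDesign",
    "SimulationConfig",
    "SimulationResult",
    "PRIOR_MEANS",
    "PRIOR_SDS",
    "PARAM_NAMES",
    "make_block_stimulus",
    "draw_parameters",
    "simulate_bold",
]

PARAM_NAMES = ("epsilon", "tau_s", "tau_f", "tau_0", "alpha", "E_0", "V_0")

#: Independent normal priors over the Balloon parameters.
PRIOR_MEANS = {
    "epsilon": 0.54,
    "tau_s": 1.54,
    "tau_f": 2.46,
    "tau_0": 0.98,
    "alpha": 0.33,
    "E_0": 0.34,
    "V_0": 0.02,
}
PRIOR_SDS = {
    "epsilon": 0.1,
    "tau_s": 0.25,
    "tau_f": 0.25,
    "tau_0": 0.25,
    "alpha": 0.045,
    "E_0": 0.1,
    "V_0": 0.005,
}

# validity bounds used when projecting prior draws
_DRAW_BOUNDS = {
    "epsilon": (1e-3, 5.0),
    "tau_s": (0.05, 20.0),
    "tau_f": (0.05, 20.0),
    "tau_0": (0.05, 20.0),
    "alpha": (0.05, 0.95),
    "E_0": (0.01, 0.99),
    "V_0": (0.001, 0.2),
}


@dataclass(frozen=True)
class BlockDesign:
    """Alternating rest/stimulation block paradigm on a uniform grid."""

    n_blocks: int = 16
    scans_per_block: int = 8
    tr: float = 2.0
    lead_in_scans: int = 8
    start_with_rest: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 0 or self.scans_per_block <= 0 or self.lead_in_scans < 0:
            raise ValueError("block counts must be non-negative, scans per block positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_scans(self) -> int:
        return self.lead_in_scans + self.n_blocks * self.scans_per_block


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one synthetic run (seed included)."""

    design: BlockDesign = field(default_factory=BlockDesign)
    params: HemoParams = None
    process_noise_sd: np.ndarray = None  # per-state SDs (f, s, q, v), unit/sqrt(s)
    obs_noise_sd: float = 0.0
    seed: int = 0
    dt_sub: float = 0.1

    def __post_init__(self) -> None:
        if self.params is None:
            object.__setattr__(self, "params", HemoParams(**PRIOR_MEANS))
        sd = self.process_noise_sd
        sd = np.zeros(4) if sd is None else np.broadcast_to(
            np.asarray(sd, dtype=float), (4,)
        ).copy()
        if np.any(sd < 0) or self.obs_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        object.__setattr__(self, "process_noise_sd", sd)


@dataclass
class SimulationResult:
    """Ground truth plus clean and noisy observations on one grid."""

    stimulus: StimulusTrain
    states: np.ndarray  # (n_scans, 4) true [f, s, q, v] at acquisitions
    y_clean: np.ndarray
    y_noisy: np.ndarray
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.stimulus.times,
                "u": self.stimulus.u,
                "y": self.y_noisy,
                "y_clean": self.y_clean,
                "f": self.states[:, 0],
                "s": self.states[:, 1],
                "q": self.states[:, 2],
                "v": self.states[:, 3],
            }
        )


def make_block_stimulus(design: BlockDesign) -> StimulusTrain:
    """Boxcar 0/1 input on the acquisition grid.

    With ``start_with_rest`` the lead-in and every even-indexed block are
    rest; the default paradigm therefore has 64 stimulated scans out of 136.
    """
    u = np.zeros(design.n_scans)
    for b in range(design.n_blocks):
        stimulated = (b % 2 == 1) if design.start_with_rest else (b % 2 == 0)
        if stimulated:
            lo = design.lead_in_scans + b * design.scans_per_block
            u[lo: lo + design.scans_per_block] = 1.0
    times = np.arange(design.n_scans) * design.tr
    return StimulusTrain(times=times, u=u)


def draw_parameters(seed: int) -> HemoParams:
    """One draw from the independent normal priors, clipped to validity.

    Deterministic given the seed; draws are taken in the fixed order
    ``PARAM_NAMES`` so the same seed always yields the same parameter set.
    """
    rng = np.random.default_rng(seed)
    vals = {}
    for name in PARAM_NAMES:
        lo, hi = _DRAW_BOUNDS[name]
        vals[name] = float(np.clip(rng.normal(PRIOR_MEANS[name], PRIOR_SDS[name]), lo, hi))
    return HemoParams(**vals)


def simulate_bold(config: SimulationConfig) -> SimulationResult:
    """Integrate the Balloon model from rest under the block stimulus.

    Process noise is added after each RK4 substep as sd * sqrt(h) * N(0,1)
    per state (the Euler-Maruyama reading of continuous white process
    noise); observation noise is N(0, obs_noise_sd^2) per acquisition.
    The seed fully determines the output.
    """
    stim = make_block_stimulus(config.design)
    rng = np.random.default_rng(config.seed)
    n = len(stim)
    tr, dt = config.design.tr, config.dt_sub
    n_sub = max(1, int(np.ceil(tr / dt - 1e-12)))
    h = tr / n_sub
    sqrt_h = np.sqrt(h)
    noisy_process = bool(np.any(config.process_noise_sd > 0))

    x = np.array([1.0, 0.0, 1.0, 1.0])
    states = np.empty((n, 4))
    states[0] = x
    for k in range(1, n):
        u = stim.u[k - 1]  # zero-order hold over [t_{k-1}, t_k)
        for i in range(n_sub):
            x = rk4_substep(x, config.params, u, h)
            if noisy_process:
                x = x + config.process_noise_sd * sqrt_h * rng.standard_normal(4)
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"non-finite trajectory at scan {k}, substep {i + 1} "
                    "(process noise too large?)"
                )
            apply_positivity_floor(x, warn=False)
        states[k] = x

    y_clean = bold_observe(states, config.params)
    y_noisy = y_clean + config.obs_noise_sd * rng.standard_normal(n)
    return SimulationResult(
        stimulus=stim, states=states, y_clean=np.asarray(y_clean),
        y_noisy=y_noisy, config=config,
    )
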