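"""Per-step result container shared by the dual and joint filters."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

FREE_PARAM_NAMES = ("epsilon", "tau_s", "tau_f", "tau_0", "E_0")
STATE_COLS = ("f", "s", "q", "v")


@dataclass
class FilterTrace:
    """Per-acquisition record of a filtering run.

    The dual filter never represents a state-parameter cross-covariance, so
    ``joint_cov`` is populated only by the joint filter (where it holds the
    full 9x9 covariance whose off-diagonal block is the modeled
    interaction).
    """

    scheme: str  # "dual" or "joint"
    times: np.ndarray
    y: np.ndarray
    predicted_y: np.ndarray
    innovations: np.ndarray
    state_means: np.ndarray  # (n, 4)
    state_covs: np.ndarray  # (n, 4, 4)
    param_means: np.ndarray  # (n, 5) ordered as FREE_PARAM_NAMES
    param_covs: np.ndarray  # (n, 5, 5)
    joint_cov: Optional[np.ndarray] = None  # (n, 9, 9), joint filter only
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.times.size

    @property
    def final_params(self) -> dict:
        return dict(zip(FREE_PARAM_NAMES, self.param_means[-1]))

    @property
    def final_param_sds(self) -> dict:
        sds = np.sqrt(np.diag(self.param_covs[-1]))
        return dict(zip(FREE_PARAM_NAMES, sds))

    def log_likelihood_proxy(self) -> float:
        """Gaussian innovation log-likelihood summed over updated steps."""
        nu = self.innovations[1:]
        S = np.array([np.atleast_2d(c)[0, 0] for c in self.diagnostics["innovation_var"][1:]])
        return float(-0.5 * np.sum(np.log(2.0 * np.pi * S) + nu**2 / S))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times, "y": self.y, "y_hat": self.predicted_y}
        for i, name in enumerate(STATE_COLS):
            cols[name] = self.state_means[:, i]
        for i, name in enumerate(FREE_PARAM_NAMES):
            cols[name] = self.param_means[:, i]
        cols["innovation"] = self.innovations
        return pd.DataFrame(cols)

    def total_variation(self, skip_scans: int = 0, normalize: bool = True) -> np.ndarray:
        """Per-parameter total variation sum |w_k - w_{k-1}| from ``skip_scans`` on.

        With ``normalize`` each parameter's increments are divided by its
        prior SD so the five traces are comparable.
        """
        from .synthetic import PRIOR_SDS

        w = self.param_means[skip_scans:]
        tv = np.sum(np.abs(np.diff(w, axis=0)), axis=0)
        if normalize:
            tv = tv / np.array([PRIOR_SDS[n] for n in FREE_PARAM_NAMES])
        return tv
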