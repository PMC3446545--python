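"""Joint unscented Kalman filtering over the concatenated state.

The baseline scheme stacks the four hemodynamic states and five free
parameters into one 9-dimensional vector [f, s, q, v, epsilon, tau_s,
tau_f, tau_0, E_0] and runs a single UKF.  The full 9x9 covariance carries
an explicit state-parameter cross block, so the filter models an
interaction that the Balloon model's biophysics does not contain — the
price of the one-filter convenience, and the source of the parameter
fluctuations the dual scheme avoids.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import block_diag

from .dual import (
    FIXED_ALPHA,
    FIXED_V0,
    _StepCounters,
    _count_warnings,
    default_param_belief,
    default_state_belief,
    params_from_vector,
    project_parameters,
)
from .hemodynamics import (
    POSITIVITY_FLOOR,
    StimulusTrain,
    apply_positivity_floor,
    bold_observe,
    integrate_step,
)
from .trace import FilterTrace
from .ukf import (
    ConditioningError,
    GaussianBelief,
    NoiseSpec,
    UTConfig,
    ukf_predict,
    ukf_update,
)

__all__ = ["JOINT_DIM", "make_joint_belief", "extract_blocks", "run_joint_ukf"]

JOINT_DIM = 9
_NX = 4
_NW = 5


def make_joint_belief(
    state: GaussianBelief, params: GaussianBelief
) -> GaussianBelief:
    """Stack independent state and parameter beliefs (zero cross block)."""
    if state.dim != _NX or params.dim != _NW:
        raise ValueError("expected a 4-dim state and 5-dim parameter belief")
    return GaussianBelief(
        np.concatenate([state.mean, params.mean]),
        block_diag(state.cov, params.cov),
    )


def extract_blocks(belief: GaussianBelief):
    """Split a joint covariance into (Pxx, Pxw, Pwx, Pww).

    The blocks partition the 9x9 matrix exactly; Pwx is Pxw transposed up
    to the symmetry of the input.
    """
    if belief.dim != JOINT_DIM:
        raise ValueError(f"joint belief must have dimension {JOINT_DIM}")
    P = belief.cov
    return (
        P[:_NX, :_NX],
        P[:_NX, _NX:],
        P[_NX:, :_NX],
        P[_NX:, _NX:],
    )


def run_joint_ukf(
    y: np.ndarray,
    stimulus: StimulusTrain,
    init: GaussianBelief | None = None,
    noise: NoiseSpec | None = None,
    config: UTConfig | None = None,
    dt_sub: float = 0.1,
    alpha: float = FIXED_ALPHA,
    V_0: float = FIXED_V0,
    augmented: bool = False,
    rr_decay: float = 1.0,
) -> FilterTrace:
    """Single-UKF joint state and parameter estimation.

    One predict/update cycle per acquisition: the transition propagates the
    state block through the Balloon integrator under each sigma point's own
    parameter block (identity on the parameter block), with process noise
    blockdiag(Q, R_r); the update evaluates the BOLD equation with each
    sigma point's own E_0.  Interfaces mirror :func:`hemodual.dual.run_dual_ukf`.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if len(stimulus) != n:
        raise ValueError("observations and stimulus must share the grid")
    if noise is None:
        raise ValueError("a NoiseSpec is required")
    tr = stimulus.tr
    config = config or UTConfig()
    belief = (init or make_joint_belief(default_state_belief(),
                                        default_param_belief())).copy()
    if belief.dim != JOINT_DIM:
        raise ValueError(f"joint belief must have dimension {JOINT_DIM}")

    R_r = np.atleast_2d(np.asarray(noise.R_r, dtype=float)).copy()
    counters = _StepCounters()

    state_means = np.empty((n, _NX))
    state_covs = np.empty((n, _NX, _NX))
    param_means = np.empty((n, _NW))
    param_covs = np.empty((n, _NW, _NW))
    joint_cov = np.empty((n, JOINT_DIM, JOINT_DIM))
    predicted = np.full(n, np.nan)
    innovations = np.full(n, np.nan)
    innovation_var = [np.array([[np.nan]])] * n

    def record(k):
        Pxx, _, _, Pww = extract_blocks(belief)
        state_means[k] = belief.mean[:_NX]
        state_covs[k] = Pxx
        w_nat, _ = project_parameters(belief.mean[_NX:])
        param_means[k] = w_nat
        param_covs[k] = Pww
        joint_cov[k] = belief.cov

    record(0)

    for k in range(1, n):
        u_prev = float(stimulus.u[k - 1])
        Q_joint = block_diag(np.asarray(noise.Q, dtype=float), R_r)
        R_r = rr_decay * R_r

        def transition(Z):
            X = apply_positivity_floor(np.array(Z[:, :_NX], copy=True), warn=False)
            w_nat, clipped = project_parameters(Z[:, _NX:])
            if clipped:
                counters.projections += 1
            params = params_from_vector(w_nat, alpha=alpha, V_0=V_0)
            Xn = integrate_step(X, params, u_prev, tr, dt_sub, warn=False)
            if np.any(Xn[:, [0, 2, 3]] <= POSITIVITY_FLOOR):
                counters.positivity += 1
            return np.hstack([Xn, Z[:, _NX:]])

        def observe(Z):
            X = apply_positivity_floor(np.array(Z[:, :_NX], copy=True), warn=False)
            w_nat, clipped = project_parameters(Z[:, _NX:])
            if clipped:
                counters.projections += 1
            params = params_from_vector(w_nat, alpha=alpha, V_0=V_0)
            return bold_observe(X, params)

        try:
            with warnings.catch_warnings(record=True) as rec:
                warnings.simplefilter("always")
                prior = ukf_predict(belief, transition, Q_joint, config,
                                    augmented=augmented)
                apply_positivity_floor(prior.mean[:_NX], warn=False)
                post, innov = ukf_update(prior, observe, y[k], noise.R, config,
                                         augmented=augmented)
            _count_warnings(rec, counters)
        except ConditioningError as err:
            raise ConditioningError(f"step {k}: {err}") from err
        apply_positivity_floor(post.mean[:_NX], warn=False)
        belief = post
        predicted[k] = innov.predicted[0]
        innovations[k] = innov.innovation[0]
        innovation_var[k] = innov.innovation_cov
        record(k)

    return FilterTrace(
        scheme="joint",
        times=stimulus.times.copy(),
        y=y.copy(),
        predicted_y=predicted,
        innovations=innovations,
        state_means=state_means,
        state_covs=state_covs,
        param_means=param_means,
        param_covs=param_covs,
        joint_cov=joint_cov,
        diagnostics={
            "projections": counters.projections,
            "positivity_clips": counters.positivity,
            "jitter_events": counters.jitter,
            "innovation_var": innovation_var,
        },
    )
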