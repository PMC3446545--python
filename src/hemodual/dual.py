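"""Dual unscented Kalman filtering: separate state and parameter filters.

Two UKFs run alternately at every acquisition.  The state filter tracks the
four hemodynamic states under the current parameter estimate; the parameter
filter tracks the five free Balloon parameters w = (epsilon, tau_s, tau_f,
tau_0, E_0) as a random walk w_{k+1} = w_k + r_k, measured through the
composite map

    G(x_hat, w) = bold_observe( integrate_step(x_hat, w), w )

i.e. a one-step propagation of the latest state estimate under each
parameter sigma point, followed by the BOLD observation equation.  Because
the two filters never share a covariance, the modeled state-parameter
cross-covariance is identically zero — it is not zeroed, it is simply never
represented — which is the statistical decoupling that distinguishes dual
from joint filtering.

The stiffness exponent alpha and the resting volume fraction V_0 stay fixed
(defaults 0.33 and 0.02): V_0 enters the observation only through the
product with the bracketed term, so it is not separately identifiable, and
alpha is a nominal factor to the BOLD contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hemodynamics import (
    POSITIVITY_FLOOR,
    HemoParams,
    PositivityWarning,
    StimulusTrain,
    apply_positivity_floor,
    bold_observe,
    integrate_step,
)
from .synthetic import PRIOR_MEANS, PRIOR_SDS
from .trace import FREE_PARAM_NAMES, FilterTrace
from .ukf import (
    ConditioningError,
    ConditioningWarning,
    GaussianBelief,
    NoiseSpec,
    UTConfig,
    ukf_predict,
    ukf_update,
)

__all__ = [
    "FREE_PARAM_NAMES",
    "PROJECTION_BOUNDS",
    "project_parameters",
    "params_from_vector",
    "parameter_time_update",
    "default_state_belief",
    "default_param_belief",
    "default_noise_spec",
    "run_dual_ukf",
]

#: Hard validity box for the free parameter vector; clips fire a diagnostic.
PROJECTION_BOUNDS = {
    "epsilon": (1e-3, 5.0),
    "tau_s": (0.05, 20.0),
    "tau_f": (0.05, 20.0),
    "tau_0": (0.05, 20.0),
    "E_0": (0.01, 0.99),
}

_LO = np.array([PROJECTION_BOUNDS[n][0] for n in FREE_PARAM_NAMES])
_HI = np.array([PROJECTION_BOUNDS[n][1] for n in FREE_PARAM_NAMES])

FIXED_ALPHA = PRIOR_MEANS["alpha"]
FIXED_V0 = PRIOR_MEANS["V_0"]


def project_parameters(w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip a parameter vector (or batch of rows) to its validity box.

    Returns the projected copy and a flag saying whether any clip fired.
    Idempotent by construction.
    """
    w = np.asarray(w, dtype=float)
    clipped = np.clip(w, _LO, _HI)
    return clipped, bool(np.any(clipped != w))


def params_from_vector(
    w: np.ndarray, alpha: float = FIXED_ALPHA, V_0: float = FIXED_V0
) -> HemoParams:
    """Assemble HemoParams from a free-parameter vector (or (M, 5) batch)."""
    w = np.asarray(w, dtype=float)
    return HemoParams(
        epsilon=w[..., 0],
        tau_s=w[..., 1],
        tau_f=w[..., 2],
        tau_0=w[..., 3],
        alpha=alpha,
        E_0=w[..., 4],
        V_0=V_0,
    )


def parameter_time_update(belief: GaussianBelief, R_r: np.ndarray) -> GaussianBelief:
    """Random-walk time update: mean unchanged, covariance grows by R_r."""
    R_r = np.atleast_2d(np.asarray(R_r, dtype=float))
    if R_r.shape != belief.cov.shape:
        raise ValueError("R_r dimension mismatch")
    return GaussianBelief(belief.mean.copy(), belief.cov + R_r)


def default_state_belief(cov_scale: float = 1e-2) -> GaussianBelief:
    """Resting-point initialization (1, 0, 1, 1) with diagonal covariance."""
    return GaussianBelief(np.array([1.0, 0.0, 1.0, 1.0]), cov_scale * np.eye(4))


def default_param_belief(shift_sds: float = 0.0) -> GaussianBelief:
    """Prior-mean initialization, optionally shifted by ``shift_sds`` prior SDs.

    The covariance is the diagonal of prior variances, so the filter starts
    from the stated parameter uncertainty rather than a token value.
    """
    means = np.array([PRIOR_MEANS[n] for n in FREE_PARAM_NAMES])
    sds = np.array([PRIOR_SDS[n] for n in FREE_PARAM_NAMES])
    return GaussianBelief(means + shift_sds * sds, np.diag(sds**2))


def default_noise_spec(
    obs_noise_sd: float,
    q_var: float = 1e-6,
    rr_scale: float = 1e-4,
) -> NoiseSpec:
    """Filter noise covariances.

    Q is a small diagonal state process noise (variance ``q_var`` per TR),
    R matches the observation noise variance, and the parameter random walk
    R_r is ``rr_scale`` times the prior variances — enough drift to keep the
    parameter filter responsive without letting it wander.
    """
    sds = np.array([PRIOR_SDS[n] for n in FREE_PARAM_NAMES])
    return NoiseSpec(
        Q=q_var * np.eye(4),
        R=np.array([[obs_noise_sd**2]]),
        R_r=rr_scale * np.diag(sds**2),
    )


@dataclass
class _StepCounters:
    projections: int = 0
    positivity: int = 0
    jitter: int = 0


def _count_warnings(records, counters: _StepCounters) -> None:
    for rec in records:
        if issubclass(rec.category, PositivityWarning):
            counters.positivity += 1
        elif issubclass(rec.category, ConditioningWarning):
            counters.jitter += 1
        else:  # re-emit anything we did not mean to swallow
            warnings.warn_explicit(
                rec.message, rec.category, rec.filename, rec.lineno
            )


def run_dual_ukf(
    y: np.ndarray,
    stimulus: StimulusTrain,
    init_params: GaussianBelief | None = None,
    init_state: GaussianBelief | None = None,
    noise: NoiseSpec | None = None,
    config: UTConfig | None = None,
    dt_sub: float = 0.1,
    alpha: float = FIXED_ALPHA,
    V_0: float = FIXED_V0,
    augmented: bool = False,
    state_first: bool = True,
    rr_decay: float = 1.0,
    log_space: bool = False,
    param_r_scale: float = 30.0,
) -> FilterTrace:
    """Run the alternating state/parameter UKF over a BOLD series.

    Parameters
    ----------
    y
        Observed BOLD signal, one scalar per acquisition.
    stimulus
        Neuronal input on the same grid (zero-order held between scans).
    init_params, init_state
        Initial Gaussian beliefs; defaults are the prior means/variances and
        the resting point.
    noise
        Q (state process noise), R (observation noise), R_r (parameter
        random walk).  Required in practice; a zero-noise default is not
        offered because R = 0 makes the update singular.
    config
        Unscented-transform scaling; classic defaults if omitted.
    augmented
        If True, process and observation noise ride inside the sigma points
        (the higher-dimensional formulation); otherwise they are added.
    state_first
        Within a step, run the state filter before the parameter filter
        (default) or the reverse.
    rr_decay
        Per-step multiplicative annealing of R_r (1.0 = none).
    param_r_scale
        Tempering factor on the parameter filter's measurement noise: the
        parameter update sees ``param_r_scale * R`` (plus the state-induced
        variance).  Values around 30 spread the evidence of one stimulation
        block over many scans, which keeps the weakly identified amplitude
        parameters (E_0 vs epsilon) from collapsing onto a ridge during the
        first block; 1 restores the untempered update.
    log_space
        Filter the parameters as log w instead of w (positivity for free);
        initialization beliefs are transformed internally.

    Returns
    -------
    FilterTrace with per-step state and parameter beliefs, predicted
    observations, innovations, and clamp/jitter diagnostics.  Step 0 holds
    the initial beliefs (no update: the rest-state observation carries no
    information about the parameters).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if len(stimulus) != n:
        raise ValueError("observations and stimulus must share the grid")
    tr = stimulus.tr
    config = config or UTConfig()
    state_belief = (init_state or default_state_belief()).copy()
    param_belief = (init_params or default_param_belief()).copy()
    if noise is None:
        raise ValueError("a NoiseSpec is required")

    if log_space:
        # z = log w; cov mapped through the Jacobian diag(1/w)
        jac = 1.0 / param_belief.mean
        param_belief = GaussianBelief(
            np.log(param_belief.mean),
            jac[:, None] * param_belief.cov * jac[None, :],
        )

    def to_natural(w):
        return np.exp(w) if log_space else w

    R_r = np.atleast_2d(np.asarray(noise.R_r, dtype=float)).copy()
    if log_space:
        # interpret R_r as relative drift in log space
        w0 = to_natural(param_belief.mean)
        R_r = R_r / np.outer(w0, w0)

    counters = _StepCounters()

    state_means = np.empty((n, 4))
    state_covs = np.empty((n, 4, 4))
    param_means = np.empty((n, 5))
    param_covs = np.empty((n, 5, 5))
    predicted = np.full(n, np.nan)
    innovations = np.full(n, np.nan)
    innovation_var = [np.array([[np.nan]])] * n

    def record(k):
        state_means[k] = state_belief.mean
        state_covs[k] = state_belief.cov
        w_nat, _ = project_parameters(to_natural(param_belief.mean))
        param_means[k] = w_nat
        if log_space:
            w = to_natural(param_belief.mean)
            param_covs[k] = w[:, None] * param_belief.cov * w[None, :]
        else:
            param_covs[k] = param_belief.cov

    record(0)

    def current_params():
        w_nat, clipped = project_parameters(to_natural(param_belief.mean))
        if clipped:
            counters.projections += 1
        return params_from_vector(w_nat, alpha=alpha, V_0=V_0)

    # Each filter conditions on the other's point estimate, so part of what
    # it sees as observation noise is really the other filter's current
    # uncertainty.  Both effective observation variances therefore carry a
    # cross term: the state filter adds the observation variance induced by
    # the parameter spread (from the parameter filter's last sigma set), the
    # parameter filter adds the one induced by the state spread (from the
    # state filter's last innovation covariance).  Without this the filters
    # are mutually overconfident and can lock each other into biased
    # estimates.
    R_meas = np.atleast_2d(np.asarray(noise.R, dtype=float))
    param_induced_var = np.zeros_like(R_meas)
    state_induced_var = np.zeros_like(R_meas)

    for k in range(1, n):
        u_prev = float(stimulus.u[k - 1])
        x_ref = state_belief.mean.copy()  # posterior state estimate at k-1

        def state_step():
            nonlocal state_belief, state_induced_var
            params = current_params()

            def transition(X):
                X = apply_positivity_floor(np.array(X, copy=True), warn=False)
                Xn = integrate_step(X, params, u_prev, tr, dt_sub, warn=False)
                if np.any(Xn[..., [0, 2, 3]] <= POSITIVITY_FLOOR):
                    counters.positivity += 1
                return Xn

            def observe(X):
                Xp = apply_positivity_floor(np.array(X, copy=True), warn=False)
                return bold_observe(Xp, params)

            R_eff = R_meas + param_induced_var
            with warnings.catch_warnings(record=True) as rec:
                warnings.simplefilter("always")
                prior = ukf_predict(state_belief, transition, noise.Q, config,
                                    augmented=augmented)
                apply_positivity_floor(prior.mean, warn=False)
                post, innov = ukf_update(prior, observe, y[k], R_eff, config,
                                         augmented=augmented)
            _count_warnings(rec, counters)
            apply_positivity_floor(post.mean, warn=False)
            state_belief = post
            # spread of y over the state sigma points = S - R_eff
            state_induced_var = np.maximum(innov.innovation_cov - R_eff, 0.0)
            predicted[k] = innov.predicted[0]
            innovations[k] = innov.innovation[0]
            innovation_var[k] = innov.innovation_cov

        def param_step():
            nonlocal param_belief, R_r, param_induced_var
            prior = parameter_time_update(param_belief, R_r)
            R_r = rr_decay * R_r

            def observe_w(W):
                w_nat, clipped = project_parameters(to_natural(W))
                if clipped:
                    counters.projections += 1
                params = params_from_vector(w_nat, alpha=alpha, V_0=V_0)
                X = np.broadcast_to(x_ref, (W.shape[0], 4))
                Xp = integrate_step(X, params, u_prev, tr, dt_sub, warn=False)
                return bold_observe(Xp, params)

            R_eff = param_r_scale * R_meas + state_induced_var
            with warnings.catch_warnings(record=True) as rec:
                warnings.simplefilter("always")
                post, innov = ukf_update(prior, observe_w, y[k], R_eff, config,
                                         augmented=augmented)
            _count_warnings(rec, counters)
            param_belief = post
            # spread of y over the parameter sigma points = S - R_eff
            param_induced_var = np.maximum(innov.innovation_cov - R_eff, 0.0)

        try:
            if state_first:
                state_step()
                param_step()
            else:
                param_step()
                state_step()
        except ConditioningError as err:
            raise ConditioningError(f"step {k}: {err}") from err

        record(k)

    return FilterTrace(
        scheme="dual",
        times=stimulus.times.copy(),
        y=y.copy(),
        predicted_y=predicted,
        innovations=innovations,
        state_means=state_means,
        state_covs=state_covs,
        param_means=param_means,
        param_covs=param_covs,
        joint_cov=None,
        diagnostics={
            "projections": counters.projections,
            "positivity_clips": counters.positivity,
            "jitter_events": counters.jitter,
            "innovation_var": innovation_var,
        },
    )
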