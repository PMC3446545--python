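"""Balloon-model hemodynamics and the BOLD observation equation.

The Balloon model couples a flow-inducing signal driven by neuronal input to
normalized cerebral blood flow (CBF), venous blood volume, and deoxyhemoglobin
(dHb) content.  Written first-order with s = df/dt, the state is
x = [f, s, q, v] and the dynamics are

    df/dt = s
    ds/dt = eps * u - s / tau_s - (f - 1) / tau_f
    dv/dt = (f - v**(1/alpha)) / tau_0
    dq/dt = ( f * (1 - (1 - E_0)**(1/f)) / E_0 - v**(1/alpha) * q / v ) / tau_0

All state variables are dimensionless relative to their resting values, so
(f, s, q, v) = (1, 0, 1, 1) is a fixed point under zero input.  The BOLD
signal is a volume-weighted mixture of intra- and extravascular contributions,

    y = V_0 * ( k1 * (1 - q) + k2 * (1 - q/v) + k3 * (1 - v) )

with k1 = 7 E_0, k2 = 2, k3 = 2 E_0 - 0.2, a calibration appropriate for a
1.5 T scanner.  No other field strength is supported.

State vectors are plain numpy arrays in the fixed order [f, s, q, v]; batch
evaluation over a leading axis is supported throughout (parameters may be
scalars or arrays broadcastable against the batch), which is what the
sigma-point filters rely on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "HemoState",
    "HemoParams",
    "BoldCoefficients",
    "StimulusTrain",
    "PositivityWarning",
    "STATE_NAMES",
    "POSITIVITY_FLOOR",
    "balloon_derivatives",
    "bold_coefficients",
    "bold_observe",
    "integrate_step",
]

STATE_NAMES = ("f", "s", "q", "v")

#: Lower floor applied to f, q, v after every integration substep and after
#: every sigma-point propagation, keeping the fractional powers defined.
POSITIVITY_FLOOR = 1e-6

# indices of the strictly positive states within [f, s, q, v]
_POSITIVE_IDX = np.array([0, 2, 3])


class PositivityWarning(UserWarning):
    """Raised (as a warning) whenever the positivity floor clips a state."""


@dataclass(frozen=True)
class HemoState:
    """Physiological state of one voxel: flow, flow signal, dHb, volume."""

    f: float
    s: float
    q: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f, self.s, self.q, self.v], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "HemoState":
        f, s, q, v = np.asarray(x, dtype=float)
        return cls(f=float(f), s=float(s), q=float(q), v=float(v))

    @classmethod
    def rest(cls) -> "HemoState":
        return cls(f=1.0, s=0.0, q=1.0, v=1.0)


@dataclass(frozen=True)
class HemoParams:
    """Balloon-model parameters.

    epsilon : neuronal efficacy (gain from stimulus to flow signal)
    tau_s   : signal decay time constant [s]
    tau_f   : autoregulatory feedback time constant [s]
    tau_0   : mean venous transit time [s]
    alpha   : stiffness exponent of the volume-outflow relation
    E_0     : resting oxygen extraction fraction, in (0, 1)
    V_0     : resting blood volume fraction, in (0, 1)

    Fields accept arrays for batch evaluation; validation applies elementwise.
    """

    epsilon: float | np.ndarray
    tau_s: float | np.ndarray
    tau_f: float | np.ndarray
    tau_0: float | np.ndarray
    alpha: float | np.ndarray
    E_0: float | np.ndarray
    V_0: float | np.ndarray

    def __post_init__(self) -> None:
        for name in ("tau_s", "tau_f", "tau_0"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("alpha", "E_0", "V_0"):
            val = np.asarray(getattr(self, name))
            if np.any(val <= 0) or np.any(val >= 1):
                raise ValueError(f"{name} must lie strictly in (0, 1)")

    def replace(self, **changes) -> "HemoParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "epsilon": float(np.asarray(self.epsilon)),
            "tau_s": float(np.asarray(self.tau_s)),
            "tau_f": float(np.asarray(self.tau_f)),
            "tau_0": float(np.asarray(self.tau_0)),
            "alpha": float(np.asarray(self.alpha)),
            "E_0": float(np.asarray(self.E_0)),
            "V_0": float(np.asarray(self.V_0)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HemoParams":
        return cls(**{k: float(d[k]) for k in
                      ("epsilon", "tau_s", "tau_f", "tau_0", "alpha", "E_0", "V_0")})


@dataclass(frozen=True)
class BoldCoefficients:
    """Observation-equation weights (k1, k2, k3); k2 is always 2."""

    k1: float
    k2: float
    k3: float


@dataclass(frozen=True)
class StimulusTrain:
    """Neuronal input u(t) sampled on the uniform acquisition grid."""

    times: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "u", u)
        if times.shape != u.shape or times.ndim != 1:
            raise ValueError("times and u must be 1-D arrays of equal length")
        if times.size >= 2:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-9 * max(abs(dt[0]), 1.0)):
                raise ValueError("acquisition grid must be uniformly spaced")

    @property
    def tr(self) -> float:
        """Repetition time (grid spacing) in seconds."""
        if self.times.size < 2:
            raise ValueError("need at least two samples to define TR")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


def _check_state_domain(x: np.ndarray) -> None:
    f = x[..., 0]
    v = x[..., 3]
    if np.any(f <= 0) or np.any(v <= 0):
        raise ValueError(
            "f and v must be strictly positive (fractional powers undefined); "
            "the caller's positivity policy failed"
        )


def _derivatives(x: np.ndarray, params: HemoParams, u) -> np.ndarray:
    """Raw vectorized derivative kernel; no domain checks."""
    f = x[..., 0]
    s = x[..., 1]
    q = x[..., 2]
    v = x[..., 3]
    inv_alpha = 1.0 / np.asarray(params.alpha, dtype=float)
    outflow = v ** inv_alpha
    df = s
    ds = params.epsilon * u - s / params.tau_s - (f - 1.0) / params.tau_f
    dv = (f - outflow) / params.tau_0
    # extraction fraction relative to rest, written over 1 - E_0 throughout
    # so the ratio is exactly 1 at f = 1 (no double rounding of E_0)
    m = 1.0 - params.E_0
    extraction_ratio = (1.0 - m ** (1.0 / f)) / (1.0 - m)
    dq = (f * extraction_ratio - outflow * q / v) / params.tau_0
    return np.stack(np.broadcast_arrays(df, ds, dq, dv), axis=-1)


def balloon_derivatives(x, params: HemoParams, u) -> np.ndarray:
    """Instantaneous time derivatives (df, ds, dq, dv) of the Balloon model.

    Parameters
    ----------
    x
        State array, shape (..., 4), ordered [f, s, q, v].  A ``HemoState``
        is also accepted.
    params
        Balloon parameters; fields may be arrays broadcastable against the
        batch axis of ``x``.
    u
        Neuronal input amplitude (scalar or broadcastable array).

    Returns
    -------
    ndarray of the same shape as ``x`` holding the four time derivatives.

    Raises
    ------
    ValueError
        If f <= 0 or v <= 0 anywhere in the batch.
    """
    if isinstance(x, HemoState):
        x = x.as_array()
    x = np.asarray(x, dtype=float)
    _check_state_domain(x)
    return _derivatives(x, params, u)


def bold_coefficients(E_0) -> BoldCoefficients:
    """Observation weights (k1, k2, k3) = (7 E_0, 2, 2 E_0 - 0.2).

    Valid for a 1.5 T scanner; E_0 must lie strictly in (0, 1).
    """
    E_0_arr = np.asarray(E_0, dtype=float)
    if np.any(E_0_arr <= 0) or np.any(E_0_arr >= 1):
        raise ValueError("E_0 must lie strictly in (0, 1)")
    if E_0_arr.ndim == 0:
        e = float(E_0_arr)
        return BoldCoefficients(k1=7.0 * e, k2=2.0, k3=2.0 * e - 0.2)
    return BoldCoefficients(k1=7.0 * E_0_arr, k2=2.0, k3=2.0 * E_0_arr - 0.2)


def bold_observe(x, params: HemoParams):
    """BOLD signal y = V_0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v)).

    The coefficients are recomputed from the *current* ``params.E_0`` on
    every call, so a filter that updates its oxygen-extraction estimate sees
    the matching observation weights immediately.

    Returns a scalar for a single state, an array for a batch.
    """
    if isinstance(x, HemoState):
        x = x.as_array()
    x = np.asarray(x, dtype=float)
    v = x[..., 3]
    if np.any(v <= 0):
        raise ValueError("v must be strictly positive in the observation")
    q = x[..., 2]
    k = bold_coefficients(params.E_0)
    y = params.V_0 * (k.k1 * (1.0 - q) + k.k2 * (1.0 - q / v) + k.k3 * (1.0 - v))
    if np.ndim(y) == 0:
        return float(y)
    return y


def apply_positivity_floor(x: np.ndarray, warn: bool = True) -> np.ndarray:
    """Clip f, q, v (not s) at ``POSITIVITY_FLOOR`` in place; return x."""
    sub = x[..., _POSITIVE_IDX]
    if np.any(sub < POSITIVITY_FLOOR):
        if warn:
            warnings.warn(
                "positivity floor triggered on a hemodynamic state",
                PositivityWarning,
                stacklevel=3,
            )
        np.maximum(sub, POSITIVITY_FLOOR, out=sub)
        x[..., _POSITIVE_IDX] = sub
    return x


def rk4_substep(x: np.ndarray, params: HemoParams, u, h: float) -> np.ndarray:
    """One classical Runge-Kutta 4 substep of length ``h`` (no floor)."""
    k1 = _derivatives(x, params, u)
    k2 = _derivatives(x + 0.5 * h * k1, params, u)
    k3 = _derivatives(x + 0.5 * h * k2, params, u)
    k4 = _derivatives(x + h * k3, params, u)
    return x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_step(
    x,
    params: HemoParams,
    u,
    tr: float,
    dt_sub: float = 0.1,
    warn: bool = True,
) -> np.ndarray:
    """Advance the state by one repetition time with fixed-step RK4.

    The input ``u`` is held constant over the interval (zero-order hold,
    matching boxcar block designs).  The interval is divided into
    ``ceil(tr / dt_sub)`` equal substeps; after each substep f, q, v are
    floored at ``POSITIVITY_FLOOR``.

    Parameters
    ----------
    x
        State, shape (..., 4), or a ``HemoState``.
    params
        Balloon parameters (scalars or per-batch-row arrays).
    u
        Input amplitude over the interval (scalar or per-row).
    tr
        Interval length in seconds (the repetition time).
    dt_sub
        Target substep length in seconds; default 0.1 s, i.e. 20 substeps
        for TR = 2 s.

    Raises
    ------
    FloatingPointError
        If the trajectory becomes non-finite (reports the substep index).
    """
    was_state = isinstance(x, HemoState)
    if was_state:
        x = x.as_array()
    x = np.array(x, dtype=float, copy=True)
    n_sub = max(1, math.ceil(tr / dt_sub - 1e-12))
    h = tr / n_sub
    for i in range(n_sub):
        x = rk4_substep(x, params, u, h)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite state after substep {i + 1}/{n_sub} (h={h:g} s)"
            )
        apply_positivity_floor(x, warn=warn)
    if was_state:
        return HemoState.from_array(x)
    return x
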