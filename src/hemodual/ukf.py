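"""Generic unscented Kalman filtering machinery.

The unscented transform represents a Gaussian belief by 2L+1 deterministic
sigma points that reproduce its mean and covariance exactly, propagates the
points through the nonlinear map, and re-estimates moments from the weighted
images — accurate to second order in the Taylor expansion of the map.

Two noise-handling modes are provided:

* plain (default): additive process noise Q is added after the transform and
  additive observation noise R is added to the innovation covariance — the
  cheap formulation whose sigma sets have dimension L.
* augmented: the noise dimensions ride inside the sigma points, i.e. the
  belief is extended with zero-mean noise components and block-diagonal
  covariance [P 0; 0 Q] (resp. [P 0; 0 R]) before sampling, so the noise
  passes through the nonlinearity itself.  For additive-noise models the two
  modes agree; the augmented one is what the larger dimension accounting in
  the complexity module refers to.

Nonlinear maps passed to these routines must be vectorized over the leading
axis: they consume an (M, L) array of points and return (M, d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "GaussianBelief",
    "UTConfig",
    "SigmaPointSet",
    "NoiseSpec",
    "Dimensions",
    "InnovationRecord",
    "ConditioningError",
    "ConditioningWarning",
    "generate_sigma_points",
    "unscented_transform",
    "ukf_predict",
    "ukf_update",
    "augment_dimensions",
    "symmetrize",
]


class ConditioningError(np.linalg.LinAlgError):
    """Cholesky factorization failed even after jitter escalation."""


class ConditioningWarning(UserWarning):
    """Jitter was added to a covariance to restore positive definiteness."""


def symmetrize(P: np.ndarray) -> np.ndarray:
    """Return the symmetric part (P + P.T) / 2."""
    return 0.5 * (P + P.T)


@dataclass
class GaussianBelief:
    """Mean vector and covariance matrix of a filter posterior."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        L = self.mean.size
        if self.cov.shape != (L, L):
            raise ValueError(f"covariance must be {L}x{L}, got {self.cov.shape}")

    @property
    def dim(self) -> int:
        return self.mean.size

    def copy(self) -> "GaussianBelief":
        return GaussianBelief(self.mean.copy(), self.cov.copy())


@dataclass(frozen=True)
class UTConfig:
    """Scaled unscented-transform constants.

    Defaults alpha_ut = 1, beta_ut = 2, kappa_ut = 3 - L give the classic
    construction that is exact for Gaussian fourth moments of quadratic
    maps.  kappa_ut = None means "use 3 - L at the point of use".
    """

    alpha_ut: float = 1.0
    beta_ut: float = 2.0
    kappa_ut: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_ut <= 1.0):
            raise ValueError("alpha_ut must lie in (0, 1]")

    def scaling(self, L: int) -> float:
        """Composite scaling lambda = alpha^2 (L + kappa) - L."""
        kappa = (3.0 - L) if self.kappa_ut is None else self.kappa_ut
        lam = self.alpha_ut**2 * (L + kappa) - L
        if L + lam <= 0:
            raise ValueError(f"L + lambda must be positive (got {L + lam})")
        return lam


@dataclass
class SigmaPointSet:
    """2L+1 sigma points with their mean and covariance weights."""

    points: np.ndarray  # (2L+1, L)
    mean_weights: np.ndarray
    cov_weights: np.ndarray

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise covariances of the filtering problem.

    Q   : process noise on the physiological states
    R   : observation noise on the BOLD measurement
    R_r : random-walk drift covariance of the parameter filter
    """

    Q: np.ndarray
    R: np.ndarray
    R_r: np.ndarray

    def __post_init__(self) -> None:
        for name in ("Q", "R", "R_r"):
            M = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if not np.allclose(M, M.T, atol=1e-12 * max(1.0, float(np.abs(M).max(initial=0.0)))):
                raise ValueError(f"{name} must be symmetric")
            object.__setattr__(self, name, M)


@dataclass(frozen=True)
class Dimensions:
    """Dimension bookkeeping for a filter's sigma-point problem."""

    L_x: int
    L_v: int
    L_n: int
    L_w: int = 0
    L_aug: Optional[int] = None


def augment_dimensions(dims: Dimensions) -> Dimensions:
    """Fill in the augmented dimension L_aug = L_x + L_v + L_n."""
    return Dimensions(
        L_x=dims.L_x,
        L_v=dims.L_v,
        L_n=dims.L_n,
        L_w=dims.L_w,
        L_aug=dims.L_x + dims.L_v + dims.L_n,
    )


def _cholesky_with_jitter(P: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; on failure add escalating diagonal jitter.

    Jitter starts at 1e-9 * trace(P)/L and escalates tenfold up to three
    times before raising ``ConditioningError`` — a persistent failure at
    that point signals a diverging filter, not a rounding artifact.
    """
    P = symmetrize(P)
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        pass
    L = P.shape[0]
    base = 1e-9 * max(np.trace(P) / L, np.finfo(float).tiny)
    jitter = base
    for _ in range(4):
        warnings.warn(
            f"covariance not positive definite; adding jitter {jitter:.3e}",
            ConditioningWarning,
            stacklevel=3,
        )
        try:
            return np.linalg.cholesky(P + jitter * np.eye(L))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise ConditioningError(
        "Cholesky failed after jitter escalation; the filter is diverging"
    )


def generate_sigma_points(belief: GaussianBelief, config: UTConfig) -> SigmaPointSet:
    """Scaled sigma points of a Gaussian belief.

    Point 0 is the mean; points i and L+i are mean +/- sqrt(L+lambda) times
    the i-th column of the lower-triangular Cholesky factor of the
    covariance.
    """
    L = belief.dim
    lam = config.scaling(L)
    c = L + lam
    S = _cholesky_with_jitter(belief.cov)
    offsets = np.sqrt(c) * S.T  # row i = sqrt(c) * column i of S
    points = np.vstack([belief.mean[None, :],
                        belief.mean[None, :] + offsets,
                        belief.mean[None, :] - offsets])
    wm = np.full(2 * L + 1, 1.0 / (2.0 * c))
    wc = wm.copy()
    wm[0] = lam / c
    wc[0] = lam / c + (1.0 - config.alpha_ut**2 + config.beta_ut)
    return SigmaPointSet(points=points, mean_weights=wm, cov_weights=wc)


def unscented_transform(
    points: SigmaPointSet, fn: Callable[[np.ndarray], np.ndarray]
) -> tuple[GaussianBelief, np.ndarray]:
    """Propagate sigma points through ``fn`` and re-estimate moments.

    Returns the transformed belief and the (2L+1, d) array of mapped points
    (needed by callers that form cross-covariances).
    """
    try:
        Y = np.atleast_2d(np.asarray(fn(points.points), dtype=float))
    except (ValueError, FloatingPointError) as err:
        raise type(err)(f"map failed on the sigma-point batch: {err}") from err
    if Y.shape[0] != points.points.shape[0]:
        Y = Y.T
    bad = np.where(~np.all(np.isfinite(Y), axis=1))[0]
    if bad.size:
        raise FloatingPointError(f"map returned non-finite values at sigma point(s) {bad.tolist()}")
    mean = points.mean_weights @ Y
    dY = Y - mean
    cov = (points.cov_weights[:, None] * dY).T @ dY
    return GaussianBelief(mean, symmetrize(cov)), Y


def ukf_predict(
    belief: GaussianBelief,
    transition: Callable[[np.ndarray], np.ndarray],
    Q: np.ndarray,
    config: UTConfig,
    augmented: bool = False,
) -> GaussianBelief:
    """Time update: propagate the belief through the transition map.

    In plain mode ``Q`` is added to the transformed covariance.  In
    augmented mode the belief is extended with the L_v process-noise
    dimensions (block-diagonal covariance) before sampling, the noise
    components are added to the propagated state inside the map, and
    nothing is added afterwards.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    L = belief.dim
    if not augmented:
        sp = generate_sigma_points(belief, config)
        prior, _ = unscented_transform(sp, transition)
        prior.cov = symmetrize(prior.cov + Q)
        return prior
    Lv = Q.shape[0]
    aug_mean = np.concatenate([belief.mean, np.zeros(Lv)])
    aug_cov = np.block([
        [belief.cov, np.zeros((L, Lv))],
        [np.zeros((Lv, L)), Q],
    ])
    sp = generate_sigma_points(GaussianBelief(aug_mean, aug_cov), config)

    def _aug_map(z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(transition(z[:, :L])) + z[:, L:]

    prior, _ = unscented_transform(sp, _aug_map)
    return prior


@dataclass
class InnovationRecord:
    """Per-step update diagnostics."""

    predicted: np.ndarray
    innovation: np.ndarray
    innovation_cov: np.ndarray
    gain: np.ndarray = field(repr=False, default=None)


def ukf_update(
    prior: GaussianBelief,
    observation_fn: Callable[[np.ndarray], np.ndarray],
    y,
    R: np.ndarray,
    config: UTConfig,
    augmented: bool = False,
) -> tuple[GaussianBelief, InnovationRecord]:
    """Measurement update against observation ``y``.

    The gain is the state-observation cross-covariance times the inverse
    innovation covariance, solved through a Cholesky factorization (no
    explicit inverse).  The posterior covariance is re-symmetrized.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    L = prior.dim
    if not augmented:
        sp = generate_sigma_points(prior, config)
        X = sp.points
        y_belief, Y = unscented_transform(sp, observation_fn)
        S = y_belief.cov + R
    else:
        Ln = R.shape[0]
        aug_mean = np.concatenate([prior.mean, np.zeros(Ln)])
        aug_cov = np.block([
            [prior.cov, np.zeros((L, Ln))],
            [np.zeros((Ln, L)), R],
        ])
        sp = generate_sigma_points(GaussianBelief(aug_mean, aug_cov), config)
        X = sp.points[:, :L]

        def _aug_obs(z: np.ndarray) -> np.ndarray:
            return np.atleast_2d(observation_fn(z[:, :L])) + z[:, L:]

        y_belief, Y = unscented_transform(sp, _aug_obs)
        S = y_belief.cov
    dX = X - prior.mean  # exact for point 0 in plain mode; small otherwise
    dY = Y - y_belief.mean
    Pxy = (sp.cov_weights[:, None] * dX).T @ dY
    try:
        S_chol = cho_factor(symmetrize(S), lower=True)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(
            "innovation covariance numerically singular (R too small?)"
        ) from err
    K = cho_solve(S_chol, Pxy.T).T
    innovation = y - y_belief.mean
    posterior = GaussianBelief(
        prior.mean + K @ innovation,
        symmetrize(prior.cov - K @ S @ K.T),
    )
    record = InnovationRecord(
        predicted=y_belief.mean,
        innovation=innovation,
        innovation_cov=S,
        gain=K,
    )
    return posterior, record
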