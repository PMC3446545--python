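"""Independent textbook linear Kalman filter used as an oracle.

Deliberately implemented from the closed-form recursion (explicit inverse,
no sigma points, no shared code with the package) so it can certify the
UKF on linear-Gaussian systems.
"""

from __future__ import annotations

import numpy as np


def kalman_predict(m, P, A, b, Q):
    return A @ m + b, A @ P @ A.T + Q


def kalman_update(m, P, H, c, R, y):
    S = H @ P @ H.T + R
    K = P @ H.T @ np.linalg.inv(S)
    innov = y - (H @ m + c)
    m_post = m + K @ innov
    P_post = P - K @ S @ K.T
    return m_post, P_post


def kalman_filter(ms0, P0, A, b, Q, H, c, R, ys):
    """Full filtering pass; returns lists of posterior means and covariances."""
    m, P = np.array(ms0, dtype=float), np.array(P0, dtype=float)
    means, covs = [], []
    for y in ys:
        m, P = kalman_predict(m, P, A, b, Q)
        m, P = kalman_update(m, P, H, c, R, np.atleast_1d(y))
        means.append(m.copy())
        covs.append(P.copy())
    return means, covs


def random_stable_system(rng, dim, obs_dim=1):
    """Random stable linear-Gaussian system (spectral radius < 0.95)."""
    A = rng.normal(size=(dim, dim))
    A *= 0.9 / max(np.abs(np.linalg.eigvals(A)).max(), 1e-9)
    b = 0.1 * rng.normal(size=dim)
    H = rng.normal(size=(obs_dim, dim))
    c = 0.1 * rng.normal(size=obs_dim)
    Lq = rng.normal(size=(dim, dim)) * 0.3
    Q = Lq @ Lq.T + 0.01 * np.eye(dim)
    Lr = rng.normal(size=(obs_dim, obs_dim)) * 0.3
    R = Lr @ Lr.T + 0.01 * np.eye(obs_dim)
    return A, b, H, c, Q, R


def simulate_linear(rng, A, b, H, c, Q, R, n_steps, x0):
    x = np.array(x0, dtype=float)
    ys = []
    Lq = np.linalg.cholesky(Q)
    Lr = np.linalg.cholesky(R)
    for _ in range(n_steps):
        x = A @ x + b + Lq @ rng.normal(size=x.size)
        ys.append(H @ x + c + Lr @ rng.normal(size=H.shape[0]))
    return ys
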