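"""Joint (concatenated-state) filter behavior and the dual/joint bridge."""

import numpy as np
import pytest

import hemodual as hd
from hemodual.dual import default_noise_spec, default_param_belief, default_state_belief
from hemodual.joint import JOINT_DIM, extract_blocks, make_joint_belief, run_joint_ukf
from hemodual.trace import FREE_PARAM_NAMES
from hemodual.ukf import GaussianBelief, NoiseSpec, UTConfig, ukf_predict, ukf_update

TRUTH = np.array([hd.PRIOR_MEANS[k] for k in FREE_PARAM_NAMES])


class TestBlocks:
    def test_zero_cross_block_round_trip(self):
        belief = make_joint_belief(default_state_belief(), default_param_belief())
        Pxx, Pxw, Pwx, Pww = extract_blocks(belief)
        np.testing.assert_array_equal(Pxw, np.zeros((4, 5)))
        np.testing.assert_array_equal(Pwx, np.zeros((5, 4)))

    def test_partition_identity(self, rng):
        A = rng.normal(size=(9, 9))
        P = A @ A.T
        belief = GaussianBelief(rng.normal(size=9), P)
        Pxx, Pxw, Pwx, Pww = extract_blocks(belief)
        np.testing.assert_array_equal(np.block([[Pxx, Pxw], [Pwx, Pww]]), P)
        np.testing.assert_array_equal(Pwx, Pxw.T)

    def test_blocks_match_index_slicing(self, rng):
        A = rng.normal(size=(9, 9))
        P = A @ A.T
        belief = GaussianBelief(np.zeros(9), P)
        Pxx, Pxw, Pwx, Pww = extract_blocks(belief)
        np.testing.assert_array_equal(Pxx, P[0:4, 0:4])
        np.testing.assert_array_equal(Pxw, P[0:4, 4:9])
        np.testing.assert_array_equal(Pwx, P[4:9, 0:4])
        np.testing.assert_array_equal(Pww, P[4:9, 4:9])

    def test_dimension_check(self):
        with pytest.raises(ValueError):
            extract_blocks(GaussianBelief(np.zeros(5), np.eye(5)))


def test_self_consistency_at_truth():
    res = hd.simulate_bold(hd.SimulationConfig(obs_noise_sd=0.0, seed=11))
    init = make_joint_belief(
        GaussianBelief(np.array([1.0, 0.0, 1.0, 1.0]), 1e-8 * np.eye(4)),
        GaussianBelief(TRUTH.copy(), 1e-8 * np.eye(5)),
    )
    noise = NoiseSpec(Q=1e-10 * np.eye(4), R=[[1e-8]], R_r=np.zeros((5, 5)))
    trace = run_joint_ukf(res.y_noisy, res.stimulus, init=init, noise=noise)
    assert np.nanmax(np.abs(trace.innovations)) < 1e-6
    assert np.abs(trace.param_means - TRUTH).max() < 1e-3


def test_cross_covariance_appears_after_first_stimulated_block():
    """The joint covariance grows a nonzero state-parameter block — the
    modeled interaction the dual scheme never represents."""
    clean = hd.simulate_bold(hd.SimulationConfig(obs_noise_sd=0.0, seed=4))
    sd = 0.1 * np.max(np.abs(clean.y_clean))
    res = hd.simulate_bold(hd.SimulationConfig(obs_noise_sd=sd, seed=4))
    trace = run_joint_ukf(
        res.y_noisy, res.stimulus,
        init=make_joint_belief(default_state_belief(), default_param_belief(1.0)),
        noise=default_noise_spec(sd),
    )
    # the initial belief is exactly decoupled
    assert np.abs(trace.joint_cov[0][:4, 4:]).max() == 0.0
    # after the first stimulated block (scan 24) the block is alive
    assert np.abs(trace.joint_cov[24][:4, 4:]).max() > 1e-8
    # stimulation couples far more strongly than rest relaxation
    assert (
        np.abs(trace.joint_cov[20][:4, 4:]).max()
        > 10 * np.abs(trace.joint_cov[16][:4, 4:]).max()
    )


def test_joint_parameter_traces_fluctuate_more_than_dual():
    """Post-first-block total variation: joint > dual on shared data."""
    wins = 0
    n_seeds = 5
    for seed in range(1, n_seeds + 1):
        clean = hd.simulate_bold(hd.SimulationConfig(obs_noise_sd=0.0, seed=seed))
        sd = 0.1 * np.max(np.abs(clean.y_clean))
        res = hd.simulate_bold(hd.SimulationConfig(obs_noise_sd=sd, seed=seed))
        noise = default_noise_spec(sd)
        dual = hd.run_dual_ukf(
            res.y_noisy, res.stimulus,
            init_params=default_param_belief(1.0), noise=noise,
        )
        joint = run_joint_ukf(
            res.y_noisy, res.stimulus,
            init=make_joint_belief(default_state_belief(), default_param_belief(1.0)),
            noise=noise,
        )
        if dual.total_variation(24).sum() < joint.total_variation(24).sum():
            wins += 1
    assert wins >= 4, f"dual quieter in only {wins}/{n_seeds} runs"


def test_zeroed_cross_covariance_bridges_joint_to_dual():
    """On a linear-observation toy model with no noise, a joint filter whose
    cross block is forced to zero equals a dual pair whose filters inflate
    their observation noise by the other's variance."""
    cfg = UTConfig()
    a = 0.9
    R = 0.04
    # toy: x' = a x,  w' = w,  y = x + w
    x_belief = GaussianBelief([0.5], [[1.0]])
    w_belief = GaussianBelief([0.2], [[0.5]])
    joint = GaussianBelief([0.5, 0.2], np.diag([1.0, 0.5]))
    ys = [0.7, 0.63, 0.6, 0.55, 0.52]

    for y in ys:
        # joint step with forced decoupling
        joint = ukf_predict(joint, lambda z: z * np.array([a, 1.0]), np.zeros((2, 2)), cfg)
        joint, _ = ukf_update(joint, lambda z: z.sum(axis=1, keepdims=True), [y], [[R]], cfg)
        joint.cov[0, 1] = joint.cov[1, 0] = 0.0

        # dual step: simultaneous updates with cross-inflated noise
        x_belief = ukf_predict(x_belief, lambda z: a * z, np.zeros((1, 1)), cfg)
        w_prior = w_belief.copy()
        Pxx, Pww = x_belief.cov[0, 0], w_prior.cov[0, 0]
        w_hat, x_hat = w_prior.mean[0], x_belief.mean[0]
        x_post, _ = ukf_update(
            x_belief, lambda z: z + w_hat, [y], [[R + Pww]], cfg
        )
        w_post, _ = ukf_update(
            w_prior, lambda z: z + x_hat, [y], [[R + Pxx]], cfg
        )
        x_belief, w_belief = x_post, w_post

        np.testing.assert_allclose(joint.mean, [x_belief.mean[0], w_belief.mean[0]], atol=1e-6)
        np.testing.assert_allclose(
            [joint.cov[0, 0], joint.cov[1, 1]],
            [x_belief.cov[0, 0], w_belief.cov[0, 0]],
            atol=1e-6,
        )


def test_cholesky_dimension_is_nine():
    """The joint filter factorizes a 9x9 covariance; dual factorizes 4 and 5."""
    assert JOINT_DIM == 9
    belief = make_joint_belief(default_state_belief(), default_param_belief())
    assert belief.cov.shape == (9, 9)
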