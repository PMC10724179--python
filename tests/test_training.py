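"""Losses, returns, BPTT gradients, and learning on degenerate tasks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempocells.agent import (AgentConfig, Architecture, build_agent,
                              forward_cache, initial_state)
from tempocells.training import (Adam, EpisodeTrace, LossBreakdown,
                                 TrainingConfig, backward_episode, compute_loss,
                                 discounted_returns, evaluate, train_agent,
                                 transfer_train)


class TestDiscountedReturns:
    def test_backward_recursion_example(self):
        assert np.allclose(discounted_returns([0, 0, 1], 0.5), [0.25, 0.5, 1.0])

    def test_zero_gamma_returns_rewards(self):
        r = [1.0, -2.0, 3.0]
        assert np.allclose(discounted_returns(r, 1e-12), r)

    def test_zero_rewards_zero_returns(self):
        assert np.allclose(discounted_returns(np.zeros(7), 0.9), 0.0)

    def test_empty_sequence(self):
        assert discounted_returns([], 0.9).size == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=1, max_value=20),
           st.floats(min_value=0.1, max_value=0.99),
           st.floats(min_value=-5, max_value=5))
    def test_terminal_reward_consistency(self, T, gamma, r):
        # a single terminal reward r: returns[t] = gamma^(T-1-t) * r
        rewards = np.zeros(T)
        rewards[-1] = r
        R = discounted_returns(rewards, gamma)
        expected = gamma ** (T - 1 - np.arange(T)) * r
        assert np.allclose(R, expected)


class TestComputeLoss:
    def test_single_step_example(self):
        # r=1, V=0, pi(chosen)=0.5: L_pi = -ln(0.5)*1, L_V = smoothL1 at 1
        trace = EpisodeTrace(rewards=np.array([1.0]),
                             chosen_log_probs=np.array([np.log(0.5)]),
                             values=np.array([0.0]),
                             returns=np.array([1.0]),
                             episode_length=1)
        loss = compute_loss(trace)
        assert abs(loss.policy_loss - 0.6931471805599453) < 1e-12
        assert loss.value_loss == 0.5
        assert abs(loss.total - 1.1931471805599453) < 1e-12

    def test_zero_advantage_zero_policy_loss(self):
        v = np.array([0.3, -0.2, 1.0])
        trace = EpisodeTrace(np.zeros(3), np.full(3, -0.7), v, v, 3)
        assert compute_loss(trace).policy_loss == 0.0

    def test_perfect_value_zero_value_loss(self):
        v = np.array([0.3, -0.2, 1.0])
        trace = EpisodeTrace(np.zeros(3), np.full(3, -0.7), v, v, 3)
        assert compute_loss(trace).value_loss == 0.0

    def test_total_is_exact_sum(self):
        rng = np.random.default_rng(0)
        trace = EpisodeTrace(rng.normal(size=5), -np.abs(rng.normal(size=5)),
                             rng.normal(size=5), rng.normal(size=5), 5)
        loss = compute_loss(trace)
        assert loss.total == loss.policy_loss + loss.value_loss

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EpisodeTrace(np.zeros(3), np.zeros(2), np.zeros(3), np.zeros(3), 3)


def _episode_grads(cfg, params, obs_seq, actions, rewards, gamma=0.9):
    state = initial_state(cfg)
    caches, values, logps = [], [], []
    for t, obs in enumerate(obs_seq):
        out, state, cache = forward_cache(obs, state, params, cfg)
        caches.append(cache)
        values.append(out.value)
        logps.append(np.log(out.policy[actions[t]]))
    values = np.array(values)
    R = discounted_returns(rewards, gamma)
    adv = R - values
    dval = np.clip(values - R, -1, 1)
    return caches, adv, dval, np.array(values), R


def _loss_given_fixed_advantage(cfg, params, obs_seq, actions, R, adv):
    state = initial_state(cfg)
    values, logps = [], []
    for t, obs in enumerate(obs_seq):
        out, state, _ = forward_cache(obs, state, params, cfg)
        values.append(out.value)
        logps.append(np.log(out.policy[actions[t]]))
    values = np.asarray(values)
    d = values - R
    lv = np.sum(np.where(np.abs(d) < 1, 0.5 * d * d, np.abs(d) - 0.5))
    return float(np.sum(-np.asarray(logps) * adv) + lv)


@pytest.mark.parametrize("arch,kwargs", [
    ("SHARED", {}),
    ("SEPARATE_PATHWAYS", {}),
    ("SPATIAL_SHARED", {"image_shape": (4, 7, 3), "n_actions": 6}),
])
def test_bptt_matches_finite_differences(arch, kwargs):
    """Analytic episode gradients agree with central finite differences."""
    kw = dict(architecture=arch, n_inputs=4, n_recurrent=6, n_linear=6,
              n_actions=2, init_seed=1)
    kw.update(kwargs)
    cfg = AgentConfig(**kw)
    params = build_agent(cfg)
    rng = np.random.default_rng(0)
    if arch == "SPATIAL_SHARED":
        obs_seq = [rng.integers(0, 256, size=(4, 7, 3)) for _ in range(4)]
    else:
        obs_seq = [np.eye(4)[i % 4] for i in range(5)]
    actions = [int(rng.integers(cfg.n_actions)) for _ in obs_seq]
    rewards = rng.normal(size=len(obs_seq))
    caches, adv, dval, values, R = _episode_grads(cfg, params, obs_seq, actions, rewards)
    grads = backward_episode(caches, actions, adv, dval, params, cfg)
    eps = 1e-6
    for k, v in params.items():
        flat = v.ravel()
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp = _loss_given_fixed_advantage(cfg, params, obs_seq, actions, R, adv)
            flat[i] = old - eps
            lm = _loss_given_fixed_advantage(cfg, params, obs_seq, actions, R, adv)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[k].ravel()[i]
            assert abs(num - ana) < 1e-4 * max(1.0, abs(num)), k


def test_separate_pathways_gradient_isolation():
    """Value loss produces zero gradient on policy-pathway parameters and
    vice versa."""
    cfg = AgentConfig(architecture="SEPARATE_PATHWAYS", n_inputs=4,
                      n_recurrent=6, n_linear=6, n_actions=2, init_seed=1)
    params = build_agent(cfg)
    rng = np.random.default_rng(0)
    obs_seq = [np.eye(4)[i % 4] for i in range(5)]
    actions = [int(rng.integers(2)) for _ in obs_seq]
    caches, *_ = _episode_grads(cfg, params, obs_seq, actions, rng.normal(size=5))
    # value-only gradients
    g_v = backward_episode(caches, actions, np.zeros(5), np.ones(5), params, cfg)
    assert all(np.all(g_v[k] == 0) for k in g_v if k.startswith("pi_"))
    assert any(np.any(g_v[k] != 0) for k in g_v if k.startswith("v_"))
    # policy-only gradients
    g_pi = backward_episode(caches, actions, np.ones(5), np.zeros(5), params, cfg)
    assert all(np.all(g_pi[k] == 0) for k in g_pi if k.startswith("v_"))
    assert any(np.any(g_pi[k] != 0) for k in g_pi if k.startswith("pi_"))


class _BanditEnv:
    """One-state, two-action task; action 0 pays +1, episode length 1."""

    n_actions = 2
    obs_dim = 1

    def reset(self, seed=None, trial_spec=None):
        from tempocells.envs import Observation, Phase
        return Observation(phase_tag=Phase.CHOICE, vector=np.ones(1))

    def step(self, action):
        obs = self.reset()
        r = 1.0 if action == 0 else 0.0
        return obs, r, True, {"correct": action == 0}


def test_bandit_policy_converges():
    env = _BanditEnv()
    cfg = AgentConfig(architecture="SHARED", n_inputs=1, n_recurrent=8,
                      n_linear=8, n_actions=2, init_seed=0)
    params = build_agent(cfg)
    tc = TrainingConfig(learning_rate=3e-3, n_episodes=2000, seed=0,
                        eval_window=100)
    params, curve = train_agent(env, params, tc, cfg)
    out, _ = forward_cache(np.ones(1), initial_state(cfg), params, cfg)[:2]
    assert out.policy[0] > 0.95
    # monotone improvement in expectation: late accuracy beats early
    assert curve[-500:].mean() > curve[:500].mean()


def test_training_deterministic_given_seed():
    from tempocells.envs import DNMSEnv, TaskConfig
    cfg = AgentConfig(architecture="SHARED", n_inputs=5, n_recurrent=8,
                      n_linear=8, n_actions=2, init_seed=0)
    curves = []
    for _ in range(2):
        env = DNMSEnv(TaskConfig(task_id="DNMS", delay_length=3, rng_seed=5))
        params = build_agent(cfg)
        tc = TrainingConfig(learning_rate=1e-3, n_episodes=50, seed=9)
        _, curve = train_agent(env, params, tc, cfg)
        curves.append(curve)
    assert np.array_equal(curves[0], curves[1])


def test_no_reset_control_carries_hidden_state():
    from tempocells.envs import DNMSEnv, TaskConfig
    cfg = AgentConfig(architecture="SHARED", n_inputs=5, n_recurrent=8,
                      n_linear=8, n_actions=2, init_seed=0)
    results = []
    for reset in (True, False):
        env = DNMSEnv(TaskConfig(task_id="DNMS", delay_length=3, rng_seed=5))
        params = build_agent(cfg)
        tc = TrainingConfig(learning_rate=1e-3, n_episodes=30, seed=9,
                            reset_hidden_between_trials=reset)
        params, _ = train_agent(env, params, tc, cfg)
        results.append(params["Wh"].copy())
    assert not np.array_equal(results[0], results[1])


def test_transfer_zero_episodes_is_noop():
    from tempocells.envs import DDCEnv, DNMSEnv, TaskConfig
    cfg = AgentConfig(architecture="SHARED", n_inputs=4, n_recurrent=8,
                      n_linear=8, n_actions=2, init_seed=0)
    params = build_agent(cfg)
    env2 = DNMSEnv(TaskConfig(task_id="DNMS", delay_length=3, rng_seed=0))
    tc = TrainingConfig(learning_rate=1e-3, n_episodes=0, seed=0)
    new_params, curve = transfer_train(params, env2, tc, cfg)
    assert len(curve) == 0
    # recurrent weights untouched; only the input map was re-initialized
    assert np.array_equal(new_params["Wh"], params["Wh"])
    assert new_params["Wx"].shape == (32, 5)


def test_transfer_runs_and_returns_curve():
    # duration-comparison pretraining carried onto the non-match task
    from tempocells.envs import DDCEnv, DNMSEnv, TaskConfig
    cfg = AgentConfig(architecture="SHARED", n_inputs=4, n_recurrent=8,
                      n_linear=8, n_actions=2, init_seed=0)
    env1 = DDCEnv(TaskConfig(task_id="DDC", duration_set=(2, 4), delay_length=2,
                             reward_incorrect=-1.0, rng_seed=0))
    params = build_agent(cfg)
    tc = TrainingConfig(learning_rate=1e-3, n_episodes=20, seed=0)
    params, _ = train_agent(env1, params, tc, cfg)
    env2 = DNMSEnv(TaskConfig(task_id="DNMS", delay_length=3, rng_seed=0))
    new_params, curve = transfer_train(params, env2, tc, cfg)
    assert len(curve) == 20
    assert new_params["Wx"].shape[1] == env2.obs_dim


def test_adam_descends_quadratic():
    params = {"x": np.array([5.0])}
    opt = Adam(params, lr=0.1)
    for _ in range(200):
        opt.step(params, {"x": 2 * params["x"]})
    assert abs(params["x"][0]) < 0.1
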