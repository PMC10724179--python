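"""Environment mechanics: phase machines, rewards, observations."""

import numpy as np
import pytest
from scipy import stats

from tempocells.envs import (ArenaSpec, DDCEnv, DNMSEnv, Phase, SpatialDNMSEnv,
                             Task, TaskConfig, make_env, render_spatial,
                             sample_ddc_trial, PALETTE)


def _ddc_config(**kw):
    base = dict(task_id="DDC", duration_set=(10, 15, 20, 25, 30, 35, 40),
                delay_length=20, reward_correct=1.0, reward_incorrect=-1.0)
    base.update(kw)
    return TaskConfig(**base)


class TestDDCTrialSampling:
    def test_durations_distinct_and_from_set(self, rng):
        cfg = _ddc_config()
        for _ in range(200):
            t1, t2 = sample_ddc_trial(cfg, rng)
            assert t1 != t2
            assert t1 in cfg.duration_set and t2 in cfg.duration_set

    def test_two_value_set_exhaustive(self, rng):
        cfg = _ddc_config(duration_set=(10, 15))
        pairs = {sample_ddc_trial(cfg, rng) for _ in range(200)}
        assert pairs == {(10, 15), (15, 10)}

    def test_ordered_pairs_uniform(self, rng):
        # 7 durations -> 42 ordered pairs, each ~1000 times in 42,000 draws
        cfg = _ddc_config()
        counts = {}
        for _ in range(42_000):
            pair = sample_ddc_trial(cfg, rng)
            counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 42
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3

    def test_single_duration_rejected(self, rng):
        with pytest.raises(ValueError):
            TaskConfig(task_id="DDC", duration_set=(10,))


class TestDDCEpisode:
    def test_episode_length_is_phase_sum(self):
        env = DDCEnv(_ddc_config(rng_seed=0))
        env.reset(seed=3, trial_spec={"T1": 10, "T2": 40})
        steps, done = 0, False
        while not done:
            _, r, done, info = env.step(0)
            steps += 1
        assert steps == 10 + 20 + 40 + 1  # STIM1 + DELAY + STIM2 + GO

    @pytest.mark.parametrize("choice,expected", [(1, 1.0), (0, -1.0)])
    def test_decision_reward(self, choice, expected):
        env = DDCEnv(_ddc_config(rng_seed=0))
        obs = env.reset(seed=3, trial_spec={"T1": 10, "T2": 40})
        done = False
        while obs.phase_tag is not Phase.GO:
            obs, r, done, _ = env.step(0)
            if not done:
                assert r == 0.0  # rewards only at the decision step
        _, r, done, info = env.step(choice)
        assert done and r == expected
        assert info["correct"] is (choice == 1)

    def test_step_after_done_is_protocol_error(self):
        env = DDCEnv(_ddc_config(rng_seed=0))
        env.reset(seed=3, trial_spec={"T1": 10, "T2": 15})
        done = False
        while not done:
            _, _, done, _ = env.step(0)
        with pytest.raises(RuntimeError):
            env.step(0)

    def test_observation_one_hot_throughout(self):
        env = DDCEnv(_ddc_config(rng_seed=1))
        obs = env.reset(seed=5)
        done = False
        while not done:
            assert obs.vector.sum() == 1.0 and set(np.unique(obs.vector)) <= {0.0, 1.0}
            obs, _, done, _ = env.step(0)


class TestDNMSEpisode:
    @pytest.mark.parametrize("task,sample,choice,expect_correct", [
        ("DNMS", 0, 1, True),            # mnemonic rewards the non-match
        ("DNMS", 0, 0, False),
        ("DNMS_NONMNEMONIC", 1, 0, True),  # non-mnemonic always rewards left
        ("DNMS_NONMNEMONIC", 1, 1, False),
    ])
    def test_choice_rule(self, task, sample, choice, expect_correct):
        cfg = TaskConfig(task_id=task, delay_length=5, rng_seed=0)
        env = DNMSEnv(cfg)
        obs = env.reset(seed=2, trial_spec={"sample": sample})
        done = False
        while obs.phase_tag is not Phase.CHOICE:
            obs, _, done, _ = env.step(sample)  # touch the shown side
        _, r, done, info = env.step(choice)
        assert done
        assert info["correct"] is expect_correct
        assert r == (cfg.reward_correct if expect_correct else cfg.reward_incorrect)

    def test_sample_phase_caps(self):
        cfg = TaskConfig(task_id="DNMS", delay_length=5, max_phase_steps=20, rng_seed=0)
        env = DNMSEnv(cfg)
        obs = env.reset(seed=2, trial_spec={"sample": 0})
        # always touch the wrong side: phase must still advance at the cap
        steps = 0
        while obs.phase_tag is Phase.SAMPLE:
            obs, _, _, _ = env.step(1)
            steps += 1
            assert steps < 100
        assert steps <= cfg.max_phase_steps + 1

    def test_random_policy_near_chance(self):
        # two-alternative symmetry of the mnemonic variant
        cfg = TaskConfig(task_id="DNMS", delay_length=3, rng_seed=0)
        env = DNMSEnv(cfg)
        rng = np.random.default_rng(0)
        correct = 0
        n = 2000
        for _ in range(n):
            env.reset()
            done = False
            while not done:
                _, _, done, info = env.step(int(rng.integers(2)))
            correct += info["correct"]
        assert abs(correct / n - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_episode_bounded_for_any_actions(self):
        cfg = TaskConfig(task_id="DNMS", delay_length=4, max_phase_steps=10, rng_seed=0)
        env = DNMSEnv(cfg)
        env.reset(seed=1)
        for k in range(1 + 11 + 4 + 1 + 5):
            _, _, done, _ = env.step(1 - env.state.trial_spec["sample"])
            if done:
                break
        assert done


def _spatial_env(task="SPATIAL_DNMS", **kw):
    cfg = TaskConfig(task_id=task, delay_length=4, reward_correct=100.0,
                     step_penalty=-5.0, max_phase_steps=15, **kw)
    return SpatialDNMSEnv(cfg)


class TestSpatialDNMS:
    def test_wall_blocks_and_penalizes(self):
        env = _spatial_env(rng_seed=0)
        env.reset(seed=1, trial_spec={"sample": 0})
        pos = env.state.agent_position
        _, r, _, _ = env.step(env.A_DOWN)  # below the apex is a wall
        assert env.state.agent_position == pos
        assert r == -5.0

    def test_interact_at_initiation_advances_phase(self):
        env = _spatial_env(rng_seed=0)
        env.reset(seed=1, trial_spec={"sample": 0})
        assert env.state.phase is Phase.NAVIGATE
        _, r, _, _ = env.step(env.A_INTERACT)  # agent starts on the init cell
        assert r == 0.0
        assert env.state.phase is Phase.SAMPLE

    def test_correct_final_choice_rewards_100(self):
        env = _spatial_env(rng_seed=0)
        env.reset(seed=1, trial_spec={"sample": 0})
        env.step(env.A_INTERACT)  # initiation
        # navigate to left sample: up, then left twice, interact
        for a in (env.A_UP, env.A_LEFT, env.A_LEFT, env.A_INTERACT):
            _, r, done, _ = env.step(a)
        assert env.state.phase is Phase.DELAY
        while env.state.phase is Phase.DELAY:
            env.step(env.A_STAY)
        # choice: non-match of left sample is the right corner
        for a in (env.A_RIGHT, env.A_RIGHT, env.A_RIGHT, env.A_RIGHT):
            env.step(a)
        _, r, done, info = env.step(env.A_INTERACT)
        assert done and info["correct"] and r == 100.0

    def test_render_palette_and_determinism(self):
        env = _spatial_env(rng_seed=0)
        obs = env.reset(seed=1, trial_spec={"sample": 0})
        img = obs.image
        blue = np.all(img == PALETTE["agent"], axis=-1)
        red = np.all(img == PALETTE["init"], axis=-1)
        assert blue.sum() == 1  # exactly one agent pixel
        # the agent starts on (and occludes) the initiation cell
        assert red.sum() == 0
        env.step(env.A_UP)
        img2 = env._observe().image
        red2 = np.all(img2 == PALETTE["init"], axis=-1)
        assert red2.sum() == 1  # initiation cell visible once the agent moves
        assert np.array_equal(env._observe().image, env._observe().image)

    def test_episode_bounded_under_random_actions(self):
        env = _spatial_env(rng_seed=3)
        rng = np.random.default_rng(0)
        env.reset()
        for _ in range(4 * 15 + 10 + 5):
            _, _, done, _ = env.step(int(rng.integers(6)))
            if done:
                break
        assert done


def test_taskconfig_yaml_roundtrip(tmp_path):
    cfg = TaskConfig(task_id="SPATIAL_DNMS", delay_length=7, reward_correct=100.0,
                     step_penalty=-5.0, arena_spec=ArenaSpec(egocentric=True))
    path = str(tmp_path / "task.yaml")
    cfg.to_yaml(path)
    back = TaskConfig.from_yaml(path)
    assert back.task_id is Task.SPATIAL_DNMS
    assert back.delay_length == 7
    assert back.arena_spec.egocentric is True


def test_make_env_dispatch():
    env = make_env(TaskConfig(task_id="DDC", duration_set=(3, 4), delay_length=2,
                              reward_incorrect=-1.0))
    assert isinstance(env, DDCEnv)
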