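"""Single-worker advantage actor-critic training.

One gradient update per episode (batch size 1) on the summed loss

    L = L_pi + L_V,
    L_pi = sum_t -log pi(a_t | S_t) * (R_t - V_hat(S_t)),
    L_V  = sum_t smoothL1(V_hat(S_t), R_t),

with the advantage R_t - V_hat treated as a constant (no gradient flows
through it) and R_t the future-discounted return computed by a backward
recursion.  Optimization uses Adam (beta1=0.9, beta2=0.999, eps=1e-8) with
global gradient-norm clipping.  Hidden states are zeroed at every trial
boundary by default; the no-reset control instead copies the end-of-trial
state into the next trial's initial state (detached from the gradient, as
backpropagation through time is truncated at episode boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .agent import (
    AgentConfig,
    Architecture,
    RecurrentState,
    build_agent,
    forward_cache,
    initial_state,
    sample_action,
    _uniform_init,
)

__all__ = [
    "TrainingConfig",
    "EpisodeTrace",
    "LossBreakdown",
    "discounted_returns",
    "compute_loss",
    "train_agent",
    "transfer_train",
    "evaluate",
    "Adam",
    "TrainingError",
]


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class TrainingConfig:
    gamma: float = 0.99
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 1
    n_episodes: int = 10_000
    reset_hidden_between_trials: bool = True
    eval_window: int = 500
    seed: int = 0
    entropy_coef: float = 0.0  # the printed loss has no entropy term
    grad_clip: float = 40.0
    # optional early stop: halt once the rolling accuracy over eval_window
    # episodes reaches this level (None = run all n_episodes)
    stop_accuracy: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EpisodeTrace:
    rewards: np.ndarray
    chosen_log_probs: np.ndarray
    values: np.ndarray
    returns: np.ndarray
    episode_length: int

    def __post_init__(self) -> None:
        T = self.episode_length
        for name in ("rewards", "chosen_log_probs", "values", "returns"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if arr.shape != (T,):
                raise ValueError(f"{name} must have length {T}")


@dataclass
class LossBreakdown:
    policy_loss: float
    value_loss: float

    @property
    def total(self) -> float:
        return self.policy_loss + self.value_loss


def discounted_returns(rewards, gamma: float) -> np.ndarray:
    """Future-discounted returns R_t = sum_{i>=t} gamma^(i-t) r_i."""
    rewards = np.asarray(rewards, dtype=np.float64)
    out = np.empty_like(rewards)
    acc = 0.0
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


def _smooth_l1(diff: np.ndarray) -> np.ndarray:
    a = np.abs(diff)
    return np.where(a < 1.0, 0.5 * diff**2, a - 0.5)


def compute_loss(trace: EpisodeTrace) -> LossBreakdown:
    """Evaluate L_pi and L_V for a logged episode."""
    adv = trace.returns - trace.values
    l_pi = float(np.sum(-trace.chosen_log_probs * adv))
    l_v = float(np.sum(_smooth_l1(trace.values - trace.returns)))
    return LossBreakdown(policy_loss=l_pi, value_loss=l_v)


class Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Backpropagation through time
# ---------------------------------------------------------------------------

def _lstm_backward(cache, dh, dc_carry, grads, params, prefix=""):
    """One step of LSTM backward; returns (dx, dh_prev, dc_prev)."""
    i, f, g, o = cache["i"], cache["f"], cache["g"], cache["o"]
    tc, c_prev = cache["tc"], cache["c_prev"]
    do = dh * tc
    dc = dh * o * (1.0 - tc * tc) + dc_carry
    di = dc * g
    df = dc * c_prev
    dg = dc * i
    dc_prev = dc * f
    dz = np.concatenate([
        di * i * (1 - i),
        df * f * (1 - f),
        dg * (1 - g * g),
        do * o * (1 - o),
    ])
    grads[prefix + "Wx"] += np.outer(dz, cache["x"])
    grads[prefix + "Wh"] += np.outer(dz, cache["h_prev"])
    grads[prefix + "b"] += dz
    dx = params[prefix + "Wx"].T @ dz
    dh_prev = params[prefix + "Wh"].T @ dz
    return dx, dh_prev, dc_prev


def _conv_backward_episode(dx_enc, conv_cache, grads, params, config):
    """Backprop through the encoder (projection, pools, ReLUs, convs)."""
    grads["We"] += np.outer(dx_enc, conv_cache["flat"])
    grads["be"] += dx_enc
    d = (params["We"].T @ dx_enc).reshape(conv_cache["feat_shape"])
    for bi in range(len(config.conv_spec) - 1, -1, -1):
        _fm, k, pool = config.conv_spec[bi]
        pre = conv_cache["pre_relu"][bi]
        arg = conv_cache["pool_arg"][bi]
        # maxpool (stride 1) backward: route grads to the argmax offsets
        da = np.zeros_like(pre)
        Ho, Wo, C = d.shape
        for oi in range(pool):
            for oj in range(pool):
                off = oi * pool + oj
                mask = arg == off
                da[oi:oi + Ho, oj:oj + Wo] += np.where(mask, d, 0.0)
        da *= pre > 0  # ReLU
        # same-padded conv backward
        x_in = conv_cache["inputs"][bi]
        H, W, Cin = x_in.shape
        Cout = da.shape[2]
        pad = k - 1
        lo = pad // 2
        xp = np.zeros((H + pad, W + pad, Cin))
        xp[lo:lo + H, lo:lo + W] = x_in
        cols = np.empty((H * W, Cin * k * k))
        idx = 0
        for ii in range(H):
            for jj in range(W):
                cols[idx] = xp[ii:ii + k, jj:jj + k].transpose(2, 0, 1).ravel()
                idx += 1
        dout = da.reshape(H * W, Cout)
        grads[f"convW{bi}"] += (dout.T @ cols).reshape(params[f"convW{bi}"].shape)
        grads[f"convb{bi}"] += dout.sum(axis=0)
        dcols = dout @ params[f"convW{bi}"].reshape(Cout, -1)
        dxp = np.zeros_like(xp)
        idx = 0
        for ii in range(H):
            for jj in range(W):
                dxp[ii:ii + k, jj:jj + k] += dcols[idx].reshape(Cin, k, k).transpose(1, 2, 0)
                idx += 1
        d = dxp[lo:lo + H, lo:lo + W]
    return d


def backward_episode(caches, actions, advantages, dvalues, params, config,
                     entropy_coef: float = 0.0) -> dict:
    """Gradients of the episode loss with respect to every parameter.

    ``advantages`` multiply the policy-gradient term (already detached);
    ``dvalues`` are dL_V/dV_hat per step (the clipped smooth-L1 derivative).
    """
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    T = len(caches)

    if config.architecture is Architecture.SEPARATE_PATHWAYS:
        dh_pi = np.zeros(config.n_recurrent)
        dc_pi = np.zeros(config.n_recurrent)
        dh_v = np.zeros(config.n_recurrent)
        dc_v = np.zeros(config.n_recurrent)
        for t in range(T - 1, -1, -1):
            cache = caches[t]
            pol = cache["policy"]
            du = pol.copy()
            du[actions[t]] -= 1.0
            du *= advantages[t]
            if entropy_coef:
                logp = np.log(np.maximum(pol, 1e-300))
                ent = -np.sum(pol * logp)
                du += entropy_coef * pol * (logp + ent)
            dv = np.array([dvalues[t]])
            dm_pi = params["pi_Wp"].T @ du
            grads["pi_Wp"] += np.outer(du, cache["m_pi"])
            grads["pi_bp"] += du
            dm_v = params["v_Wv"].T @ dv
            grads["v_Wv"] += np.outer(dv, cache["m_v"])
            grads["v_bv"] += dv
            dhp = params["pi_Wm"].T @ dm_pi + dh_pi
            grads["pi_Wm"] += np.outer(dm_pi, cache["h_pi"])
            grads["pi_bm"] += dm_pi
            dhv = params["v_Wm"].T @ dm_v + dh_v
            grads["v_Wm"] += np.outer(dm_v, cache["h_v"])
            grads["v_bm"] += dm_v
            _, dh_pi, dc_pi = _lstm_backward(cache["lstm_pi"], dhp, dc_pi, grads, params, "pi_")
            _, dh_v, dc_v = _lstm_backward(cache["lstm_v"], dhv, dc_v, grads, params, "v_")
        return grads

    dh_carry = np.zeros(config.n_recurrent)
    dc_carry = np.zeros(config.n_recurrent)
    for t in range(T - 1, -1, -1):
        cache = caches[t]
        pol = cache["policy"]
        du = pol.copy()
        du[actions[t]] -= 1.0
        du *= advantages[t]
        if entropy_coef:
            logp = np.log(np.maximum(pol, 1e-300))
            ent = -np.sum(pol * logp)
            du += entropy_coef * pol * (logp + ent)
        dv = np.array([dvalues[t]])
        dm = params["Wp"].T @ du + params["Wv"].T @ dv
        grads["Wp"] += np.outer(du, cache["m"])
        grads["bp"] += du
        grads["Wv"] += np.outer(dv, cache["m"])
        grads["bv"] += dv
        dh = params["Wm"].T @ dm + dh_carry
        grads["Wm"] += np.outer(dm, cache["h"])
        grads["bm"] += dm
        dx, dh_carry, dc_carry = _lstm_backward(cache["lstm"], dh, dc_carry, grads, params)
        if config.architecture is Architecture.SPATIAL_SHARED:
            _conv_backward_episode(dx, cache["conv"], grads, params, config)
    return grads


def _clip_gradients(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


# ---------------------------------------------------------------------------
# Rollout helpers
# ---------------------------------------------------------------------------

def run_episode(env, params, agent_config: AgentConfig, rng,
                temperature: Optional[float] = None,
                start_state=None, collect_caches: bool = False):
    """Roll one episode; returns a dict with per-step records."""
    temp = agent_config.softmax_temperature if temperature is None else temperature
    obs = env.reset()
    state = initial_state(agent_config) if start_state is None else start_state
    caches, actions, rewards, values, log_probs, hiddens = [], [], [], [], [], []
    info = {}
    while True:
        out, state, cache = forward_cache(obs.array, state, params, agent_config)
        a = sample_action(out.policy, temp, rng)
        obs, r, done, info = env.step(a)
        if collect_caches:
            caches.append(cache)
        actions.append(a)
        rewards.append(r)
        values.append(out.value)
        log_probs.append(float(np.log(max(out.policy[a], 1e-300))))
        hiddens.append(out.hidden_snapshot)
        if done:
            break
    return {
        "caches": caches,
        "actions": actions,
        "rewards": np.asarray(rewards, dtype=np.float64),
        "values": np.asarray(values, dtype=np.float64),
        "log_probs": np.asarray(log_probs, dtype=np.float64),
        "hiddens": hiddens,
        "final_state": state,
        "info": info,
    }


def train_agent(env, params: dict, config: TrainingConfig,
                agent_config: AgentConfig,
                callback: Optional[Callable[[int, dict], None]] = None):
    """Advantage actor-critic training loop (one update per episode).

    Returns (params, learning_curve) where the learning curve is the
    per-episode correctness sequence (1.0 correct / 0.0 incorrect).
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(params, config.learning_rate, config.adam_beta1,
               config.adam_beta2, config.adam_eps)
    curve = np.zeros(config.n_episodes)
    carry_state = None
    n_run = 0
    for ep in range(config.n_episodes):
        start = None if config.reset_hidden_between_trials else carry_state
        roll = run_episode(env, params, agent_config, rng,
                           start_state=start, collect_caches=True)
        if not config.reset_hidden_between_trials:
            carry_state = roll["final_state"]
            if isinstance(carry_state, tuple):
                carry_state = tuple(s.copy() for s in carry_state)
            else:
                carry_state = carry_state.copy()
        returns = discounted_returns(roll["rewards"], config.gamma)
        adv = returns - roll["values"]
        dvalues = np.clip(roll["values"] - returns, -1.0, 1.0)  # smooth-L1'
        trace = EpisodeTrace(roll["rewards"], roll["log_probs"],
                             roll["values"], returns, len(returns))
        loss = compute_loss(trace)
        if not np.isfinite(loss.total):
            raise TrainingError(
                f"non-finite loss at episode {ep}: "
                f"L_pi={loss.policy_loss}, L_V={loss.value_loss}"
            )
        grads = backward_episode(roll["caches"], roll["actions"], adv,
                                 dvalues, params, agent_config,
                                 entropy_coef=config.entropy_coef)
        _clip_gradients(grads, config.grad_clip)
        opt.step(params, grads)
        curve[ep] = float(bool(roll["info"].get("correct", False)))
        n_run = ep + 1
        if callback is not None:
            callback(ep, {"loss": loss, "correct": curve[ep]})
        if (config.stop_accuracy is not None and ep + 1 >= config.eval_window
                and curve[ep + 1 - config.eval_window:ep + 1].mean() >= config.stop_accuracy):
            break
    return params, curve[:n_run]


def evaluate(env, params: dict, agent_config: AgentConfig,
             n_episodes: int, seed: int = 0,
             temperature: Optional[float] = None) -> float:
    """Frozen-weight accuracy over n_episodes (fraction correct)."""
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_episodes):
        roll = run_episode(env, params, agent_config, rng, temperature=temperature)
        correct += bool(roll["info"].get("correct", False))
    return correct / n_episodes


def transfer_train(params: dict, env, config: TrainingConfig,
                   agent_config: AgentConfig):
    """Continue training a pretrained agent on a new task.

    Input and output heads are re-initialized when the new task's
    observation or action dimensionality differs; the softmax temperature
    is raised to 1.5 during action sampling to encourage exploration.
    """
    params = {k: v.copy() for k, v in params.items()}
    new_cfg = AgentConfig(
        architecture=agent_config.architecture,
        n_inputs=env.obs_dim,
        n_recurrent=agent_config.n_recurrent,
        n_linear=agent_config.n_linear,
        n_actions=env.n_actions,
        conv_spec=agent_config.conv_spec,
        image_shape=agent_config.image_shape,
        softmax_temperature=1.5,
        init_seed=agent_config.init_seed,
    )
    if agent_config.architecture is Architecture.SEPARATE_PATHWAYS:
        raise ValueError("transfer is implemented for shared-trunk agents")
    rng = np.random.default_rng(agent_config.init_seed + 1)
    n_rec = new_cfg.n_recurrent
    if env.obs_dim != agent_config.n_inputs:
        params["Wx"] = _uniform_init(rng, (4 * n_rec, env.obs_dim), n_rec)
    if env.n_actions != agent_config.n_actions:
        params["Wp"] = _uniform_init(rng, (env.n_actions, n_rec), n_rec)
        params["bp"] = _uniform_init(rng, (env.n_actions,), n_rec)
    if config.n_episodes == 0:
        return params, np.zeros(0)
    return train_agent(env, params, config, new_cfg)
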