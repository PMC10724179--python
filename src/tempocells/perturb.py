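"""In-silico lesion and silencing knock-out experiments.

Two perturbation modes on a trained shared-trunk agent:

* **Lesion** — the targeted units' hidden and cell states are forced to
  zero inside the recurrent update at every step, so the rest of the
  population evolves under the altered dynamics (as in killing a cell).
* **Silencing** — the recurrent update runs untouched; only the copy of
  the hidden vector passed to the downstream linear layers has the
  targeted entries zeroed, isolating the targets' direct contribution to
  the policy/value readout from their role in the dynamics.

Target selection follows the incremental protocol: batches of 5 units are
drawn uniformly from the requested pool (time cells, ramping cells, or any
unit), nested across sizes within a repeat; once the pool is exhausted,
further draws come from the remaining units.  Accuracy is measured over
balanced evaluation trials with fresh environment randomness per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import AgentConfig, forward_cache, initial_state, sample_action
from .envs import Task

__all__ = [
    "Mode",
    "Pool",
    "PerturbationPlan",
    "PerturbationCurve",
    "select_targets",
    "lesion_run",
    "silence_run",
    "run_plan",
    "perturbed_rollout",
]


class Mode(str, Enum):
    LESION = "LESION"
    SILENCE = "SILENCE"


class Pool(str, Enum):
    TIME_CELLS = "TIME_CELLS"
    RAMPING_CELLS = "RAMPING_CELLS"
    ANY = "ANY"


@dataclass
class PerturbationPlan:
    mode: Mode = Mode.LESION
    pool: Pool = Pool.ANY
    sizes: Sequence[int] = tuple(range(5, 126, 5))
    repeats: int = 50
    n_eval_trials: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        self.pool = Pool(self.pool)
        sizes = tuple(int(s) for s in self.sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        self.sizes = sizes


@dataclass
class PerturbationCurve:
    mode: Mode
    pool: Pool
    sizes: np.ndarray
    accuracy: np.ndarray  # per-size mean over repeats
    spread: np.ndarray  # per-size std over repeats
    per_repeat: np.ndarray = field(repr=False, default=None)  # (repeats, sizes)
    n_eval_trials: int = 100


def select_targets(pool_members: Sequence[int], size: int,
                   existing: Sequence[int], rng: np.random.Generator,
                   n_units: Optional[int] = None) -> np.ndarray:
    """Grow the target set to ``size``, keeping existing targets.

    New members are drawn uniformly from the pool's remainder; when the
    pool is exhausted, from the non-pool units (requires ``n_units``).
    """
    existing = list(existing)
    if size < len(existing):
        raise ValueError("size smaller than the existing target set")
    pool_rest = [u for u in pool_members if u not in set(existing)]
    need = size - len(existing)
    take = min(need, len(pool_rest))
    chosen = list(rng.choice(pool_rest, size=take, replace=False)) if take else []
    need -= take
    if need > 0:
        if n_units is None:
            raise ValueError("pool exhausted; n_units needed to recruit others")
        if size > n_units:
            raise ValueError("size exceeds the population")
        others = [u for u in range(n_units)
                  if u not in set(existing) | set(chosen) | set(pool_members)]
        chosen += list(rng.choice(others, size=need, replace=False))
    return np.array(sorted(existing + [int(c) for c in chosen]), dtype=np.int64)


def perturbed_rollout(env, params: dict, agent_config: AgentConfig,
                      rng: np.random.Generator,
                      lesion: Optional[np.ndarray] = None,
                      silence: Optional[np.ndarray] = None,
                      trial_spec: Optional[dict] = None,
                      forced_actions: Optional[Sequence[int]] = None) -> dict:
    """One episode under optional lesion/silence unit masks.

    ``forced_actions`` replays a fixed action sequence (used to verify the
    perturbation semantics independent of action stochasticity); if the
    episode outlives the sequence, remaining actions are sampled.
    """
    n = agent_config.n_recurrent
    lmask = None if lesion is None or len(lesion) == 0 else np.isin(np.arange(n), lesion)
    smask = None if silence is None or len(silence) == 0 else np.isin(np.arange(n), silence)
    obs = env.reset(trial_spec=trial_spec)
    state = initial_state(agent_config)
    hiddens, actions = [], []
    t = 0
    info: dict = {}
    while True:
        out, state, _ = forward_cache(obs.array, state, params, agent_config,
                                      lesion_mask=lmask, silence_mask=smask)
        hiddens.append(state.hidden.copy())
        if forced_actions is not None and t < len(forced_actions):
            a = int(forced_actions[t])
        else:
            a = sample_action(out.policy, agent_config.softmax_temperature, rng)
        actions.append(a)
        obs, _r, done, info = env.step(a)
        t += 1
        if done:
            break
    return {"hiddens": np.asarray(hiddens), "actions": actions, "info": info}


def _balanced_spec(env, k: int) -> Optional[dict]:
    """Alternating trial condition so evaluation trials are balanced."""
    task = Task(env.config.task_id)
    if task is Task.DDC:
        return None  # both orders equally likely by construction
    return {"sample": k % 2}


def _accuracy(env, params, agent_config, targets, mode: Mode,
              n_trials: int, rng: np.random.Generator) -> float:
    lesion = targets if mode is Mode.LESION else None
    silence = targets if mode is Mode.SILENCE else None
    correct = 0
    for k in range(n_trials):
        roll = perturbed_rollout(env, params, agent_config, rng,
                                 lesion=lesion, silence=silence,
                                 trial_spec=_balanced_spec(env, k))
        correct += bool(roll["info"].get("correct", False))
    return correct / n_trials


def lesion_run(params: dict, env, agent_config: AgentConfig,
               targets: Sequence[int], n_trials: int = 100,
               seed: int = 0) -> float:
    """Accuracy over n_trials with the target units lesioned."""
    rng = np.random.default_rng(seed)
    return _accuracy(env, params, agent_config, np.asarray(targets, dtype=np.int64),
                     Mode.LESION, n_trials, rng)


def silence_run(params: dict, env, agent_config: AgentConfig,
                targets: Sequence[int], n_trials: int = 100,
                seed: int = 0) -> float:
    """Accuracy over n_trials with the target units silenced."""
    rng = np.random.default_rng(seed)
    return _accuracy(env, params, agent_config, np.asarray(targets, dtype=np.int64),
                     Mode.SILENCE, n_trials, rng)


def _pool_members(labels: pd.DataFrame, pool: Pool) -> list[int]:
    if pool is Pool.TIME_CELLS:
        return labels.loc[labels.is_time_cell, "unit_id"].tolist()
    if pool is Pool.RAMPING_CELLS:
        return labels.loc[labels.is_ramping_cell, "unit_id"].tolist()
    return labels.unit_id.tolist()


def run_plan(params: dict, env, agent_config: AgentConfig,
             labels: pd.DataFrame, plan: PerturbationPlan) -> PerturbationCurve:
    """Full sweep over sizes x repeats for one mode and pool."""
    rng = np.random.default_rng(plan.rng_seed)
    n_units = agent_config.n_recurrent
    members = _pool_members(labels, plan.pool)
    per_repeat = np.empty((plan.repeats, len(plan.sizes)))
    for rep in range(plan.repeats):
        targets = np.array([], dtype=np.int64)
        for si, size in enumerate(plan.sizes):
            targets = select_targets(members, size, targets, rng, n_units=n_units)
            per_repeat[rep, si] = _accuracy(env, params, agent_config, targets,
                                            plan.mode, plan.n_eval_trials, rng)
    return PerturbationCurve(
        mode=plan.mode, pool=plan.pool,
        sizes=np.asarray(plan.sizes),
        accuracy=per_repeat.mean(axis=0),
        spread=per_repeat.std(axis=0),
        per_repeat=per_repeat,
        n_eval_trials=plan.n_eval_trials,
    )


def curves_to_frame(curves: Sequence[PerturbationCurve]) -> pd.DataFrame:
    """Long-format CSV-ready table (mode, pool, size, repeat, accuracy)."""
    rows = []
    for c in curves:
        for rep in range(c.per_repeat.shape[0]):
            for si, size in enumerate(c.sizes):
                rows.append({"mode": c.mode.value, "pool": c.pool.value,
                             "size": int(size), "repeat": rep,
                             "accuracy": float(c.per_repeat[rep, si])})
    return pd.DataFrame(rows)
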