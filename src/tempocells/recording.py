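"""Frozen-weight recording of hidden-unit activity.

Rollouts with the trained weights frozen (no learning) store the recurrent
hidden-state vector at every step of an analysis window — the stimulus
presentation periods or the delay period — together with per-trial
condition labels (sample side, stimulus durations, correctness, per-step
location for spatial tasks).  The resulting trials x time x units tensor is
the common input to every downstream analysis.

Windows whose length varies across trials (the DDC stimulus periods) are
stored padded with explicit per-trial lengths; ``lengths`` and the mask
returned by :meth:`ActivityTensor.mask` make the ragged structure explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import h5py
import numpy as np

from .agent import AgentConfig, forward_cache, initial_state, sample_action
from .envs import Phase

__all__ = [
    "ActivityTensor",
    "TuningCurve",
    "record_activity",
    "normalize_units",
    "tuning_curves",
    "population_tuning",
    "save_tensor",
    "load_tensor",
]

_WINDOW_PHASES = {
    "STIM1": Phase.STIM1,
    "STIM2": Phase.STIM2,
    "DELAY": Phase.DELAY,
}


@dataclass
class ActivityTensor:
    """Recorded activity, (trial, time-step-in-window, unit), padded.

    ``lengths[i]`` gives trial i's true window length; entries beyond it
    are padding (zero).  ``labels`` holds per-trial condition arrays (e.g.
    ``sample``, ``T1``, ``T2``, ``correct``) and, for spatial tasks, a
    per-step integer location index under ``location`` (-1 where padded).
    """

    activity: np.ndarray
    lengths: np.ndarray
    labels: dict[str, np.ndarray]
    window_tag: str
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.activity.shape[0]

    @property
    def n_time(self) -> int:
        return self.activity.shape[1]

    @property
    def n_units(self) -> int:
        return self.activity.shape[2]

    @property
    def ragged(self) -> bool:
        return bool(np.any(self.lengths != self.lengths[0]))

    def mask(self) -> np.ndarray:
        """(trial, time) boolean validity mask."""
        return np.arange(self.n_time)[None, :] < self.lengths[:, None]

    def select(self, trial_idx: np.ndarray) -> "ActivityTensor":
        labels = {k: v[trial_idx] for k, v in self.labels.items()}
        return ActivityTensor(self.activity[trial_idx], self.lengths[trial_idx],
                              labels, self.window_tag, self.normalized,
                              dict(self.meta))


@dataclass
class TuningCurve:
    """Trial-averaged temporal tuning of one unit.

    ``mean_activity`` is lambda(t); ``occupancy`` p(t) is the empirical
    probability of a recorded step falling in bin t (uniform for
    fixed-length windows, duration-weighted for ragged ones).
    """

    mean_activity: np.ndarray
    occupancy: np.ndarray
    n_trials: int


def record_activity(
    params: dict,
    env,
    agent_config: AgentConfig,
    n_episodes: int = 5000,
    window_tag: str = "DELAY",
    seed: int = 0,
    temperature: Optional[float] = None,
) -> ActivityTensor:
    """Record hidden activity over an analysis window for n_episodes.

    Actions are sampled from the frozen policy; no parameter updates occur.
    The caller is responsible for the agent having converged.  Correctness
    is stored per trial so incorrect trials can be filtered downstream
    (all trials are kept by default).
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    phase = _WINDOW_PHASES[window_tag]
    rng = np.random.default_rng(seed)
    temp = agent_config.softmax_temperature if temperature is None else temperature
    spatial = hasattr(env, "arena")
    if spatial:
        cells = sorted(env._walkable)
        cell_index = {c: i for i, c in enumerate(cells)}

    all_trials: list[np.ndarray] = []
    all_locs: list[np.ndarray] = []
    labels: dict[str, list] = {"sample": [], "T1": [], "T2": [], "correct": []}
    for ep in range(n_episodes):
        # reseed the environment stream once so recordings are reproducible
        obs = env.reset(seed=seed) if ep == 0 else env.reset()
        state = initial_state(agent_config)
        window: list[np.ndarray] = []
        locs: list[int] = []
        while True:
            in_window = obs.phase_tag is phase
            pos = env.state.agent_position if spatial else None
            out, state, _ = forward_cache(obs.array, state, params, agent_config)
            if in_window:
                window.append(out.hidden_snapshot)
                if spatial:
                    locs.append(cell_index[pos])
            a = sample_action(out.policy, temp, rng)
            obs, _r, done, info = env.step(a)
            if done:
                break
        all_trials.append(np.asarray(window))
        if spatial:
            all_locs.append(np.asarray(locs, dtype=np.int64))
        spec = env.state.trial_spec
        labels["sample"].append(spec.get("sample", -1))
        labels["T1"].append(spec.get("T1", -1))
        labels["T2"].append(spec.get("T2", -1))
        labels["correct"].append(bool(info.get("correct", False)))

    lengths = np.array([len(w) for w in all_trials], dtype=np.int64)
    n_units = all_trials[0].shape[1] if lengths[0] else params_n_units(params, agent_config)
    act = np.zeros((n_episodes, int(lengths.max()), n_units))
    for i, w in enumerate(all_trials):
        if len(w):
            act[i, : len(w)] = w
    out_labels = {k: np.asarray(v) for k, v in labels.items()}
    if spatial:
        loc = np.full((n_episodes, act.shape[1]), -1, dtype=np.int64)
        for i, l in enumerate(all_locs):
            loc[i, : len(l)] = l
        out_labels["location"] = loc
    return ActivityTensor(
        activity=act,
        lengths=lengths,
        labels=out_labels,
        window_tag=window_tag,
        normalized=False,
        meta={"seed": seed, "n_episodes": n_episodes},
    )


def params_n_units(params: dict, config: AgentConfig) -> int:
    return 2 * config.n_recurrent if "pi_Wx" in params else config.n_recurrent


def normalize_units(tensor: ActivityTensor) -> ActivityTensor:
    """Per-unit min-max scaling over all recorded (unpadded) steps.

    Constant units map to 0 everywhere; applying twice is idempotent.
    """
    if tensor.normalized:
        raise ValueError("tensor is already normalized")
    mask = tensor.mask()
    act = tensor.activity
    flat_mask = mask[:, :, None]
    big = np.where(flat_mask, act, np.nan)
    lo = np.nanmin(big, axis=(0, 1))
    hi = np.nanmax(big, axis=(0, 1))
    rng_ = hi - lo
    safe = np.where(rng_ > 0, rng_, 1.0)
    scaled = (act - lo) / safe
    scaled = np.where(rng_ > 0, scaled, 0.0)
    scaled = np.where(flat_mask, scaled, 0.0)
    return ActivityTensor(scaled, tensor.lengths.copy(), dict(tensor.labels),
                          tensor.window_tag, True, dict(tensor.meta))


def _filter_index(tensor: ActivityTensor, condition_filter) -> np.ndarray:
    if condition_filter is None:
        return np.arange(tensor.n_trials)
    if callable(condition_filter):
        keep = np.array([bool(condition_filter({k: v[i] for k, v in tensor.labels.items()}))
                         for i in range(tensor.n_trials)])
    else:
        keep = np.ones(tensor.n_trials, dtype=bool)
        for key, val in condition_filter.items():
            keep &= tensor.labels[key] == val
    return np.flatnonzero(keep)


def population_tuning(
    tensor: ActivityTensor,
    condition_filter=None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Tuning curves for every unit at once.

    Returns (lam, p, n_trials): ``lam`` has shape (units, time) — the mean
    over matching trials per bin; ``p`` the occupancy distribution over
    bins, duration-weighted for ragged windows.
    """
    idx = _filter_index(tensor, condition_filter)
    if len(idx) < 2:
        raise ValueError("condition filter matches fewer than 2 trials")
    sub = tensor.activity[idx]
    mask = tensor.mask()[idx]
    counts = mask.sum(axis=0)  # trials covering each bin
    used = counts > 0
    lam = np.zeros((tensor.n_units, tensor.n_time))
    sums = np.einsum("ijk,ij->kj", sub, mask.astype(float))
    lam[:, used] = sums[:, used] / counts[used]
    lam = lam[:, used]
    p = counts[used] / counts.sum()
    return lam, p, len(idx)


def tuning_curves(tensor: ActivityTensor, condition_filter=None) -> list[TuningCurve]:
    """Per-unit :class:`TuningCurve` list (see :func:`population_tuning`)."""
    lam, p, n = population_tuning(tensor, condition_filter)
    return [TuningCurve(mean_activity=lam[u], occupancy=p.copy(), n_trials=n)
            for u in range(lam.shape[0])]


# ---------------------------------------------------------------------------
# Persistence (hierarchical array container)
# ---------------------------------------------------------------------------

def save_tensor(path: str, tensor: ActivityTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=tensor.activity)
        f.create_dataset("lengths", data=tensor.lengths)
        grp = f.create_group("labels")
        for k, v in tensor.labels.items():
            grp.create_dataset(k, data=np.asarray(v))
        f.attrs["window_tag"] = tensor.window_tag
        f.attrs["normalized"] = tensor.normalized
        for k, v in tensor.meta.items():
            f.attrs[f"meta_{k}"] = v


def load_tensor(path: str) -> ActivityTensor:
    with h5py.File(path, "r") as f:
        labels = {k: f["labels"][k][...] for k in f["labels"]}
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return ActivityTensor(
            activity=f["activity"][...],
            lengths=f["lengths"][...],
            labels=labels,
            window_tag=str(f.attrs["window_tag"]),
            normalized=bool(f.attrs["normalized"]),
            meta=meta,
        )
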