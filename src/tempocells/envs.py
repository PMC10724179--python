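"""Simulated cognitive-task environments.

Discrete-time episodic tasks used to train and probe recurrent actor-critic
agents:

* **DDC** (delayed duration comparison) — two stimuli of different duration
  separated by a delay; the agent reports which was longer.
* **DNMS** (delayed non-match-to-stimulus) — a left/right sample, a delay,
  then a two-alternative choice rewarded for the *non-matching* side
  (mnemonic) or always for the left side (non-mnemonic).
* **Spatial DNMS** — the same trial structure embedded in a small walled
  grid arena rendered as an RGB image; the agent navigates and interacts
  with lit signals.

All environments follow the standard episodic protocol:
``reset(seed) -> Observation`` and ``step(action) -> (Observation, reward,
done, info)``, in discrete time steps.  Non-spatial observations are one-hot
channel vectors; spatial observations are small RGB integer grids.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Task",
    "Phase",
    "TaskConfig",
    "Observation",
    "EnvState",
    "sample_ddc_trial",
    "DDCEnv",
    "DNMSEnv",
    "SpatialDNMSEnv",
    "make_env",
    "render_spatial",
    "write_episode_log",
    "PALETTE",
]


class Task(str, Enum):
    DDC = "DDC"
    DNMS = "DNMS"
    DNMS_NONMNEMONIC = "DNMS_NONMNEMONIC"
    SPATIAL_DNMS = "SPATIAL_DNMS"
    SPATIAL_DNMS_NONMNEMONIC = "SPATIAL_DNMS_NONMNEMONIC"


class Phase(str, Enum):
    STIM1 = "STIM1"
    DELAY = "DELAY"
    STIM2 = "STIM2"
    GO = "GO"
    SAMPLE = "SAMPLE"
    CHOICE = "CHOICE"
    NAVIGATE = "NAVIGATE"


# RGB palette for the spatial arena: walls white, floor black, agent blue,
# sample signals green, initiation signal red.
PALETTE = {
    "wall": (255, 255, 255),
    "floor": (0, 0, 0),
    "agent": (0, 0, 255),
    "sample": (0, 255, 0),
    "init": (255, 0, 0),
}


@dataclass
class ArenaSpec:
    """Walled grid arena whose walkable cells form an inverted triangle.

    Default: a 4-row x 7-column image; walkable cells are the wide top row
    (row 1, cols 1..5) and a single bottom apex (row 2, col 3).  Sample
    signals sit at the top-left/top-right walkable corners, the initiation
    signal at the apex.
    """

    n_rows: int = 4
    n_cols: int = 7
    egocentric: bool = False  # full-arena image by default

    def walkable(self) -> list[tuple[int, int]]:
        cells = [(1, c) for c in range(1, self.n_cols - 1)]
        cells.append((2, self.n_cols // 2))
        return cells

    @property
    def left_sample(self) -> tuple[int, int]:
        return (1, 1)

    @property
    def right_sample(self) -> tuple[int, int]:
        return (1, self.n_cols - 2)

    @property
    def init_cell(self) -> tuple[int, int]:
        return (2, self.n_cols // 2)


@dataclass
class TaskConfig:
    """Task rules, phase machine parameters, and reward schedule."""

    task_id: Task = Task.DNMS
    duration_set: Sequence[int] = (10, 15, 20, 25, 30, 35, 40)
    delay_length: int = 20
    reward_correct: float = 1.0
    reward_incorrect: float = 0.0
    step_penalty: float = 0.0
    max_phase_steps: int = 20
    arena_spec: Optional[ArenaSpec] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.task_id = Task(self.task_id)
        self.duration_set = tuple(int(d) for d in self.duration_set)
        if len(set(self.duration_set)) != len(self.duration_set):
            raise ValueError("duration_set entries must be distinct")
        if any(d < 1 for d in self.duration_set):
            raise ValueError("durations must be >= 1")
        if self.delay_length < 1:
            raise ValueError("delay_length must be >= 1")
        if self.task_id is Task.DDC and len(self.duration_set) < 2:
            raise ValueError("DDC needs at least two durations")
        if self.task_id in (Task.SPATIAL_DNMS, Task.SPATIAL_DNMS_NONMNEMONIC):
            if self.arena_spec is None:
                self.arena_spec = ArenaSpec()

    def to_yaml(self, path: str) -> None:
        d = {
            "task_id": self.task_id.value,
            "duration_set": list(self.duration_set),
            "delay_length": self.delay_length,
            "reward_correct": self.reward_correct,
            "reward_incorrect": self.reward_incorrect,
            "step_penalty": self.step_penalty,
            "max_phase_steps": self.max_phase_steps,
            "rng_seed": self.rng_seed,
        }
        if self.arena_spec is not None:
            d["arena_spec"] = {
                "n_rows": self.arena_spec.n_rows,
                "n_cols": self.arena_spec.n_cols,
                "egocentric": self.arena_spec.egocentric,
            }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "TaskConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "arena_spec" in d and d["arena_spec"] is not None:
            d["arena_spec"] = ArenaSpec(**d["arena_spec"])
        return cls(**d)


@dataclass
class Observation:
    """One time step of sensory input.

    ``vector`` is a one-hot channel vector for non-spatial tasks; ``image``
    a small RGB integer grid for spatial tasks.  Exactly one of the two is
    set.
    """

    phase_tag: Phase
    vector: Optional[np.ndarray] = None
    image: Optional[np.ndarray] = None

    @property
    def array(self) -> np.ndarray:
        return self.vector if self.vector is not None else self.image


@dataclass
class EnvState:
    phase: Phase
    t_in_phase: int = 0
    episode_t: int = 0
    trial_spec: dict = field(default_factory=dict)
    agent_position: Optional[tuple[int, int]] = None
    done: bool = False
    cumulative_reward: float = 0.0


def sample_ddc_trial(config: TaskConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Draw an ordered pair of distinct stimulus durations, uniformly.

    Every ordered pair (T1, T2) with T1 != T2 from ``config.duration_set``
    is equally likely.
    """
    ds = config.duration_set
    if len(ds) < 2:
        raise ValueError("DDC requires at least two distinct durations")
    i = rng.integers(len(ds))
    j = rng.integers(len(ds) - 1)
    if j >= i:
        j += 1
    return int(ds[i]), int(ds[j])


def _onehot(n: int, k: int) -> np.ndarray:
    v = np.zeros(n, dtype=np.float64)
    v[k] = 1.0
    return v


class _BaseEnv:
    """Shared reset/step plumbing for the episodic environments."""

    n_actions: int
    obs_dim: int

    def __init__(self, config: TaskConfig):
        self.config = config
        self.rng = np.random.default_rng(config.rng_seed)
        self.state: Optional[EnvState] = None

    def reset(self, seed: Optional[int] = None,
              trial_spec: Optional[dict] = None) -> Observation:
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        self.state = self._new_trial()
        if trial_spec is not None:
            self.state.trial_spec.update(trial_spec)
        return self._observe()

    def step(self, action: int):
        if self.state is None:
            raise RuntimeError("reset() must be called before step()")
        if self.state.done:
            raise RuntimeError("step() called on a finished episode")
        reward, info = self._transition(int(action))
        self.state.episode_t += 1
        self.state.cumulative_reward += reward
        obs = self._observe()
        return obs, reward, self.state.done, info

    # subclass hooks -----------------------------------------------------
    def _new_trial(self) -> EnvState:  # pragma: no cover - abstract
        raise NotImplementedError

    def _observe(self) -> Observation:  # pragma: no cover - abstract
        raise NotImplementedError

    def _transition(self, action: int):  # pragma: no cover - abstract
        raise NotImplementedError


class DDCEnv(_BaseEnv):
    """Delayed duration comparison.

    Phase sequence STIM1 (T1 steps) -> DELAY -> STIM2 (T2 steps) -> GO
    (one decision step).  Observation channels: {stim1-on, delay, stim2-on,
    go}.  Actions: 0 = "first was longer", 1 = "second was longer"; the
    choice matters only at the GO step, where the agent receives
    ``reward_correct`` (+1) or ``reward_incorrect`` (-1).
    """

    n_actions = 2
    obs_dim = 4
    _CH = {"STIM1": 0, "DELAY": 1, "STIM2": 2, "GO": 3}

    def __init__(self, config: TaskConfig):
        if Task(config.task_id) is not Task.DDC:
            raise ValueError("DDCEnv requires task_id=DDC")
        super().__init__(config)

    def _new_trial(self) -> EnvState:
        t1, t2 = sample_ddc_trial(self.config, self.rng)
        return EnvState(phase=Phase.STIM1, trial_spec={"T1": t1, "T2": t2})

    def _observe(self) -> Observation:
        return Observation(
            phase_tag=self.state.phase,
            vector=_onehot(self.obs_dim, self._CH[self.state.phase.value]),
        )

    def _transition(self, action: int):
        s = self.state
        t1, t2 = s.trial_spec["T1"], s.trial_spec["T2"]
        reward, info = 0.0, {}
        if s.phase is Phase.GO:
            longer = 0 if t1 > t2 else 1
            correct = action == longer
            reward = self.config.reward_correct if correct else self.config.reward_incorrect
            s.done = True
            info = {"correct": correct, "T1": t1, "T2": t2, "choice": action}
            return reward, info
        s.t_in_phase += 1
        bound = {Phase.STIM1: t1, Phase.DELAY: self.config.delay_length, Phase.STIM2: t2}[s.phase]
        if s.t_in_phase >= bound:
            nxt = {Phase.STIM1: Phase.DELAY, Phase.DELAY: Phase.STIM2, Phase.STIM2: Phase.GO}
            s.phase = nxt[s.phase]
            s.t_in_phase = 0
        return reward, info


class DNMSEnv(_BaseEnv):
    """Delayed non-match-to-stimulus (mnemonic or non-mnemonic).

    Observation channels: {init, sample-left, sample-right, delay, choice}.
    Actions: 0 = touch-left, 1 = touch-right.  The reset observation is the
    initiation cue; from the next step the sample side is displayed until
    the agent touches it (capped at ``max_phase_steps``, after which the
    phase auto-advances).  After the delay a single choice step follows:
    the mnemonic variant rewards the non-match side, the non-mnemonic
    variant always rewards the left side.
    """

    n_actions = 2
    obs_dim = 5
    CH_INIT, CH_LEFT, CH_RIGHT, CH_DELAY, CH_CHOICE = range(5)

    def __init__(self, config: TaskConfig):
        if Task(config.task_id) not in (Task.DNMS, Task.DNMS_NONMNEMONIC):
            raise ValueError("DNMSEnv requires a DNMS task_id")
        super().__init__(config)
        self.mnemonic = Task(config.task_id) is Task.DNMS

    def _new_trial(self) -> EnvState:
        side = int(self.rng.integers(2))  # 0 = left, 1 = right
        return EnvState(phase=Phase.SAMPLE, trial_spec={"sample": side})

    def _observe(self) -> Observation:
        s = self.state
        if s.phase is Phase.SAMPLE:
            ch = self.CH_INIT if s.t_in_phase == 0 else (
                self.CH_LEFT if s.trial_spec["sample"] == 0 else self.CH_RIGHT
            )
        elif s.phase is Phase.DELAY:
            ch = self.CH_DELAY
        else:
            ch = self.CH_CHOICE
        return Observation(phase_tag=s.phase, vector=_onehot(self.obs_dim, ch))

    def _transition(self, action: int):
        s = self.state
        side = s.trial_spec["sample"]
        if s.phase is Phase.SAMPLE:
            s.t_in_phase += 1
            # t_in_phase 0 is the init cue; sample shown from step 1 onward
            touched = s.t_in_phase >= 2 and action == side
            if touched or s.t_in_phase > self.config.max_phase_steps:
                s.phase = Phase.DELAY
                s.t_in_phase = 0
            return 0.0, {}
        if s.phase is Phase.DELAY:
            s.t_in_phase += 1
            if s.t_in_phase >= self.config.delay_length:
                s.phase = Phase.CHOICE
                s.t_in_phase = 0
            return 0.0, {}
        # CHOICE: single decision step
        target = (1 - side) if self.mnemonic else 0
        correct = action == target
        reward = self.config.reward_correct if correct else self.config.reward_incorrect
        s.done = True
        return reward, {"correct": correct, "sample": side, "choice": action}


class SpatialDNMSEnv(_BaseEnv):
    """DNMS in a small walled grid arena observed as an RGB image.

    Six actions: up, down, left, right, interact, stay.  The trial mirrors
    the non-spatial DNMS: reach and interact with the lit initiation signal
    (red), then with the lit sample signal (green), wait out the delay, then
    interact with the correct choice signal for ``reward_correct`` (+100).
    Every action except a successful interaction costs ``step_penalty``
    (-5); moving into a wall leaves the position unchanged (still
    penalized).  Navigation phases are capped at ``max_phase_steps`` and
    auto-advance (the choice phase instead times out as incorrect).
    """

    n_actions = 6
    A_UP, A_DOWN, A_LEFT, A_RIGHT, A_INTERACT, A_STAY = range(6)
    _MOVES = {0: (-1, 0), 1: (1, 0), 2: (0, -1), 3: (0, 1)}

    def __init__(self, config: TaskConfig):
        if Task(config.task_id) not in (Task.SPATIAL_DNMS, Task.SPATIAL_DNMS_NONMNEMONIC):
            raise ValueError("SpatialDNMSEnv requires a spatial task_id")
        super().__init__(config)
        self.mnemonic = Task(config.task_id) is Task.SPATIAL_DNMS
        self.arena = config.arena_spec or ArenaSpec()
        self._walkable = set(self.arena.walkable())
        if self.arena.egocentric:
            self.obs_shape = (4, 7, 3)
        else:
            self.obs_shape = (self.arena.n_rows, self.arena.n_cols, 3)
        self.obs_dim = int(np.prod(self.obs_shape))

    def _new_trial(self) -> EnvState:
        side = int(self.rng.integers(2))
        return EnvState(
            phase=Phase.NAVIGATE,  # initiation leg
            trial_spec={"sample": side},
            agent_position=self.arena.init_cell,
        )

    # -- signals lit in the current phase -------------------------------
    def _active_signals(self) -> dict[tuple[int, int], str]:
        s = self.state
        a = self.arena
        if s.phase is Phase.NAVIGATE:
            return {a.init_cell: "init"}
        if s.phase is Phase.SAMPLE:
            cell = a.left_sample if s.trial_spec["sample"] == 0 else a.right_sample
            return {cell: "sample"}
        if s.phase is Phase.CHOICE:
            return {a.left_sample: "sample", a.right_sample: "sample"}
        return {}

    def _observe(self) -> Observation:
        img = render_spatial(self.state, self.config, self._active_signals())
        if self.arena.egocentric:
            img = self._egocentric_crop(img)
        return Observation(phase_tag=self.state.phase, image=img)

    def _egocentric_crop(self, img: np.ndarray) -> np.ndarray:
        # 4x7 window centred (as nearly as possible) on the agent, padded
        # with wall color beyond the arena edge.
        r, c = self.state.agent_position
        out = np.empty((4, 7, 3), dtype=np.uint8)
        out[...] = PALETTE["wall"]
        r0, c0 = r - 2, c - 3
        for i in range(4):
            for j in range(7):
                rr, cc = r0 + i, c0 + j
                if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]:
                    out[i, j] = img[rr, cc]
        return out

    def _advance_phase(self) -> None:
        s = self.state
        order = [Phase.NAVIGATE, Phase.SAMPLE, Phase.DELAY, Phase.CHOICE]
        s.phase = order[order.index(s.phase) + 1]
        s.t_in_phase = 0

    def _transition(self, action: int):
        s = self.state
        penalty = self.config.step_penalty
        reward = penalty
        info: dict = {}
        signals = self._active_signals()
        if action in self._MOVES:
            dr, dc = self._MOVES[action]
            cand = (s.agent_position[0] + dr, s.agent_position[1] + dc)
            if cand in self._walkable:
                s.agent_position = cand
        elif action == self.A_INTERACT:
            if s.agent_position in signals:
                reward = 0.0  # appropriate interaction is not penalized
                if s.phase is Phase.CHOICE:
                    side = s.trial_spec["sample"]
                    if self.mnemonic:
                        target = self.arena.right_sample if side == 0 else self.arena.left_sample
                    else:
                        target = self.arena.left_sample
                    correct = s.agent_position == target
                    reward = self.config.reward_correct if correct else penalty
                    s.done = True
                    info = {"correct": correct, "sample": side}
                    return reward, info
                self._advance_phase()
                return reward, info
        s.t_in_phase += 1
        if s.phase is Phase.DELAY:
            if s.t_in_phase >= self.config.delay_length:
                self._advance_phase()
        elif s.t_in_phase >= self.config.max_phase_steps:
            if s.phase is Phase.CHOICE:
                s.done = True
                info = {"correct": False, "sample": s.trial_spec["sample"], "timeout": True}
            else:
                self._advance_phase()
        return reward, info


def render_spatial(
    state: EnvState,
    config: TaskConfig,
    signals: Optional[dict[tuple[int, int], str]] = None,
) -> np.ndarray:
    """Deterministic RGB rendering of the arena.

    Walls white, floor black, lit signals red (initiation) or green
    (samples), agent blue; the agent occludes whatever is under it.
    """
    arena = config.arena_spec or ArenaSpec()
    walkable = set(arena.walkable())
    img = np.empty((arena.n_rows, arena.n_cols, 3), dtype=np.uint8)
    img[...] = PALETTE["wall"]
    for cell in walkable:
        img[cell] = PALETTE["floor"]
    for cell, kind in (signals or {}).items():
        img[cell] = PALETTE[kind]
    if state.agent_position is not None:
        img[state.agent_position] = PALETTE["agent"]
    return img


_ENV_CLASSES = {
    Task.DDC: DDCEnv,
    Task.DNMS: DNMSEnv,
    Task.DNMS_NONMNEMONIC: DNMSEnv,
    Task.SPATIAL_DNMS: SpatialDNMSEnv,
    Task.SPATIAL_DNMS_NONMNEMONIC: SpatialDNMSEnv,
}


def make_env(config: TaskConfig) -> _BaseEnv:
    """Instantiate the environment class for ``config.task_id``."""
    return _ENV_CLASSES[Task(config.task_id)](config)


def write_episode_log(path: str, records: list[dict]) -> None:
    """Write per-step episode records (episode, phase, action, reward) as CSV."""
    fields = ["episode", "step", "phase", "action", "reward"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        w.writeheader()
        for rec in records:
            w.writerow(rec)
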