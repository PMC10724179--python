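"""Recurrent actor-critic network architectures.

Three variants, all built on a long short-term-memory (LSTM) recurrent core
with a linear "memory" layer feeding separate policy and value heads:

* ``SHARED`` — one LSTM + linear trunk shared by both heads (the default
  agent for the non-spatial tasks; 128/128 units at full scale).
* ``SEPARATE_PATHWAYS`` — two disjoint trunks, one computing the policy and
  one the value, with no shared representation.
* ``SPATIAL_SHARED`` — a small convolutional encoder (two blocks: 2x2
  convolutions with 16 then 32 feature maps, each followed by 2x2 max
  pooling at stride 1) whose flattened output is linearly projected into
  the LSTM input.

Everything is plain numpy.  The forward pass is deterministic given
(observation, recurrent state, parameters); the ``*_cache`` variants also
return the intermediate quantities needed for backpropagation through time
(see :mod:`tempocells.training`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Architecture",
    "AgentConfig",
    "RecurrentState",
    "StepOutput",
    "build_agent",
    "forward",
    "forward_cache",
    "sample_action",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]


class Architecture(str, Enum):
    SHARED = "SHARED"
    SEPARATE_PATHWAYS = "SEPARATE_PATHWAYS"
    SPATIAL_SHARED = "SPATIAL_SHARED"


@dataclass
class AgentConfig:
    """Architecture hyperparameters.

    ``n_recurrent`` and ``n_linear`` are kept equal (128/128 for the
    non-spatial agents, 256/256 for the spatial agent at full scale).
    ``conv_spec`` lists (feature_maps, kernel, pool) per block and only
    applies to the spatial variant; ``image_shape`` is (rows, cols, 3).
    """

    architecture: Architecture = Architecture.SHARED
    n_inputs: int = 5
    n_recurrent: int = 128
    n_linear: int = 128
    n_actions: int = 2
    conv_spec: tuple = ((16, 2, 2), (32, 2, 2))
    image_shape: Optional[tuple[int, int, int]] = None
    softmax_temperature: float = 1.0
    init_seed: int = 0

    def __post_init__(self) -> None:
        self.architecture = Architecture(self.architecture)
        if self.n_recurrent != self.n_linear:
            raise ValueError("n_recurrent must equal n_linear")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")
        if self.architecture is Architecture.SPATIAL_SHARED and self.image_shape is None:
            raise ValueError("SPATIAL_SHARED requires image_shape")


@dataclass
class RecurrentState:
    hidden: np.ndarray
    cell: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "RecurrentState":
        return cls(hidden=np.zeros(n), cell=np.zeros(n))

    def copy(self) -> "RecurrentState":
        return RecurrentState(self.hidden.copy(), self.cell.copy())


@dataclass
class StepOutput:
    policy: np.ndarray  # pi(a_t | S_t)
    value: float  # V_hat(S_t)
    hidden_snapshot: np.ndarray = field(repr=False, default=None)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _init_trunk(rng, n_in: int, n_rec: int, prefix: str = "") -> dict:
    """LSTM (gate order i, f, g, o) + linear memory layer."""
    p = {}
    p[prefix + "Wx"] = _uniform_init(rng, (4 * n_rec, n_in), n_rec)
    p[prefix + "Wh"] = _uniform_init(rng, (4 * n_rec, n_rec), n_rec)
    p[prefix + "b"] = _uniform_init(rng, (4 * n_rec,), n_rec)
    p[prefix + "Wm"] = _uniform_init(rng, (n_rec, n_rec), n_rec)
    p[prefix + "bm"] = _uniform_init(rng, (n_rec,), n_rec)
    return p


def conv_output_shape(config: AgentConfig) -> tuple[int, int, int]:
    """(rows, cols, channels) after the convolutional blocks.

    Convolutions use same padding; 2x2 max pooling at stride 1 shrinks each
    spatial dimension by 1 per block.
    """
    rows, cols, _ = config.image_shape
    ch = config.image_shape[2]
    for (fmaps, _k, pool) in config.conv_spec:
        rows = rows - (pool - 1)
        cols = cols - (pool - 1)
        ch = fmaps
        if rows < 1 or cols < 1:
            raise ValueError("conv_spec incompatible with image size")
    return rows, cols, ch


def build_agent(config: AgentConfig) -> dict:
    """Seeded parameter container for the requested architecture."""
    rng = np.random.default_rng(config.init_seed)
    n_rec, n_act = config.n_recurrent, config.n_actions
    params: dict[str, np.ndarray] = {}

    if config.architecture is Architecture.SEPARATE_PATHWAYS:
        params.update(_init_trunk(rng, config.n_inputs, n_rec, "pi_"))
        params.update(_init_trunk(rng, config.n_inputs, n_rec, "v_"))
        params["pi_Wp"] = _uniform_init(rng, (n_act, n_rec), n_rec)
        params["pi_bp"] = _uniform_init(rng, (n_act,), n_rec)
        params["v_Wv"] = _uniform_init(rng, (1, n_rec), n_rec)
        params["v_bv"] = _uniform_init(rng, (1,), n_rec)
        return params

    n_in = config.n_inputs
    if config.architecture is Architecture.SPATIAL_SHARED:
        in_ch = config.image_shape[2]
        for bi, (fmaps, k, _pool) in enumerate(config.conv_spec):
            fan = in_ch * k * k
            params[f"convW{bi}"] = _uniform_init(rng, (fmaps, in_ch, k, k), fan)
            params[f"convb{bi}"] = _uniform_init(rng, (fmaps,), fan)
            in_ch = fmaps
        rows, cols, ch = conv_output_shape(config)
        flat = rows * cols * ch
        # single learned linear map from the flattened feature maps into
        # the recurrent layer's input
        params["We"] = _uniform_init(rng, (n_in, flat), flat)
        params["be"] = _uniform_init(rng, (n_in,), flat)

    params.update(_init_trunk(rng, n_in, n_rec))
    params["Wp"] = _uniform_init(rng, (n_act, n_rec), n_rec)
    params["bp"] = _uniform_init(rng, (n_act,), n_rec)
    params["Wv"] = _uniform_init(rng, (1, n_rec), n_rec)
    params["bv"] = _uniform_init(rng, (1,), n_rec)
    return params


# ---------------------------------------------------------------------------
# Convolutional encoder (spatial variant)
# ---------------------------------------------------------------------------

def _conv_same(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 2D convolution; x (H, W, Cin), W (Cout, Cin, k, k)."""
    H, Wd, Cin = x.shape
    Cout, _, k, _ = W.shape
    pad = k - 1
    xp = np.zeros((H + pad, Wd + pad, Cin))
    lo = pad // 2
    xp[lo:lo + H, lo:lo + Wd] = x
    out = np.empty((H, Wd, Cout))
    Wf = W.reshape(Cout, -1)
    cols = np.empty((H * Wd, Cin * k * k))
    idx = 0
    for i in range(H):
        for j in range(Wd):
            cols[idx] = xp[i:i + k, j:j + k].transpose(2, 0, 1).ravel()
            idx += 1
    out = (cols @ Wf.T + b).reshape(H, Wd, Cout)
    return out


def _maxpool(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k x k max pooling at stride 1 (valid); returns output and argmax."""
    H, W, C = x.shape
    Ho, Wo = H - k + 1, W - k + 1
    stacked = np.stack(
        [x[i:i + Ho, j:j + Wo] for i in range(k) for j in range(k)], axis=-1
    )  # (Ho, Wo, C, k*k)
    arg = stacked.argmax(axis=-1)
    out = stacked.max(axis=-1)
    return out, arg


def _encode_image(img: np.ndarray, params: dict, config: AgentConfig):
    """Conv blocks + ReLU + pooling + linear projection; returns (x, cache)."""
    x = np.asarray(img, dtype=np.float64) / 255.0
    cache = {"inputs": [], "pre_relu": [], "pool_arg": []}
    for bi, (_fmaps, k, pool) in enumerate(config.conv_spec):
        cache["inputs"].append(x)
        z = _conv_same(x, params[f"convW{bi}"], params[f"convb{bi}"])
        cache["pre_relu"].append(z)
        a = np.maximum(z, 0.0)
        x, arg = _maxpool(a, pool)
        cache["pool_arg"].append(arg)
    flat = x.ravel()
    cache["flat"] = flat
    cache["feat_shape"] = x.shape
    enc = params["We"] @ flat + params["be"]
    return enc, cache


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_step(x, h_prev, c_prev, params, prefix=""):
    n = h_prev.shape[0]
    z = params[prefix + "Wx"] @ x + params[prefix + "Wh"] @ h_prev + params[prefix + "b"]
    i = _sigmoid(z[:n])
    f = _sigmoid(z[n:2 * n])
    g = np.tanh(z[2 * n:3 * n])
    o = _sigmoid(z[3 * n:])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    cache = {"x": x, "h_prev": h_prev, "c_prev": c_prev, "i": i, "f": f,
             "g": g, "o": o, "c": c, "tc": tc}
    return h, c, cache


def forward_cache(
    obs_array: np.ndarray,
    state,
    params: dict,
    config: AgentConfig,
    lesion_mask: Optional[np.ndarray] = None,
    silence_mask: Optional[np.ndarray] = None,
):
    """One deterministic forward step, returning BPTT caches.

    ``state`` is a RecurrentState (SHARED/SPATIAL_SHARED) or a pair of
    RecurrentStates (SEPARATE_PATHWAYS).  ``lesion_mask`` zeroes the hidden
    and cell values of the flagged units inside the recurrent update;
    ``silence_mask`` zeroes them only in the copy passed to the downstream
    linear layers (recurrent dynamics untouched).  Masks apply to the
    shared-trunk variants used in the knock-out experiments.
    """
    arch = config.architecture
    cache: dict = {}

    if arch is Architecture.SEPARATE_PATHWAYS:
        x = np.asarray(obs_array, dtype=np.float64).ravel()
        st_pi, st_v = state
        h_pi, c_pi, cache_pi = _lstm_step(x, st_pi.hidden, st_pi.cell, params, "pi_")
        h_v, c_v, cache_v = _lstm_step(x, st_v.hidden, st_v.cell, params, "v_")
        m_pi = params["pi_Wm"] @ h_pi + params["pi_bm"]
        m_v = params["v_Wm"] @ h_v + params["v_bm"]
        logits = params["pi_Wp"] @ m_pi + params["pi_bp"]
        value = float((params["v_Wv"] @ m_v + params["v_bv"])[0])
        pol = softmax(logits)
        cache.update({"lstm_pi": cache_pi, "lstm_v": cache_v, "h_pi": h_pi,
                      "h_v": h_v, "m_pi": m_pi, "m_v": m_v, "policy": pol})
        out = StepOutput(policy=pol, value=value,
                         hidden_snapshot=np.concatenate([h_pi, h_v]))
        new_state = (RecurrentState(h_pi, c_pi), RecurrentState(h_v, c_v))
        return out, new_state, cache

    if arch is Architecture.SPATIAL_SHARED:
        x, conv_cache = _encode_image(obs_array, params, config)
        cache["conv"] = conv_cache
    else:
        x = np.asarray(obs_array, dtype=np.float64).ravel()

    h_prev, c_prev = state.hidden, state.cell
    if lesion_mask is not None:
        h_prev = np.where(lesion_mask, 0.0, h_prev)
        c_prev = np.where(lesion_mask, 0.0, c_prev)
    h, c, lstm_cache = _lstm_step(x, h_prev, c_prev, params)
    if lesion_mask is not None:
        h = np.where(lesion_mask, 0.0, h)
        c = np.where(lesion_mask, 0.0, c)
    h_read = np.where(silence_mask, 0.0, h) if silence_mask is not None else h
    m = params["Wm"] @ h_read + params["bm"]
    logits = params["Wp"] @ m + params["bp"]
    value = float((params["Wv"] @ m + params["bv"])[0])
    pol = softmax(logits)
    cache.update({"lstm": lstm_cache, "h": h_read, "m": m, "policy": pol})
    out = StepOutput(policy=pol, value=value, hidden_snapshot=h.copy())
    return out, RecurrentState(h, c), cache


def forward(obs_array, state, params, config: AgentConfig):
    """Deterministic forward contract: (StepOutput, new recurrent state)."""
    out, new_state, _ = forward_cache(obs_array, state, params, config)
    return out, new_state


def initial_state(config: AgentConfig):
    if config.architecture is Architecture.SEPARATE_PATHWAYS:
        return (RecurrentState.zeros(config.n_recurrent),
                RecurrentState.zeros(config.n_recurrent))
    return RecurrentState.zeros(config.n_recurrent)


def sample_action(policy: np.ndarray, temperature: float, rng: np.random.Generator) -> int:
    """Draw an action from the temperature-adjusted policy.

    Temperature 1 reproduces the policy exactly; higher temperatures move
    the sampling distribution toward uniform.
    """
    p = np.asarray(policy, dtype=np.float64)
    if p.ndim != 1 or np.any(p < -1e-12) or not np.isfinite(p).all() or p.sum() <= 0:
        raise ValueError("invalid policy vector")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if temperature != 1.0:
        with np.errstate(divide="ignore"):
            logp = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
        p = softmax(logp / temperature)
        p = np.where(np.asarray(policy) > 0, p, 0.0)
    p = p / p.sum()
    return int(rng.choice(len(p), p=p))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, params: dict, config: AgentConfig) -> None:
    """Portable array archive (.npz) with a JSON sidecar for the config."""
    np.savez(path if path.endswith(".npz") else path + ".npz", **params)
    side = {
        "architecture": config.architecture.value,
        "n_inputs": config.n_inputs,
        "n_recurrent": config.n_recurrent,
        "n_linear": config.n_linear,
        "n_actions": config.n_actions,
        "conv_spec": [list(b) for b in config.conv_spec],
        "image_shape": list(config.image_shape) if config.image_shape else None,
        "softmax_temperature": config.softmax_temperature,
        "init_seed": config.init_seed,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(side, fh, indent=1)


def load_checkpoint(path: str) -> tuple[dict, AgentConfig]:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        side = json.load(fh)
    side["conv_spec"] = tuple(tuple(b) for b in side["conv_spec"])
    if side["image_shape"] is not None:
        side["image_shape"] = tuple(side["image_shape"])
    config = AgentConfig(**side)
    with np.load(base + ".npz") as data:
        params = {k: data[k].copy() for k in data.files}
    return params, config
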