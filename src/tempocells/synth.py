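"""Synthetic planted-activity populations with ground-truth labels.

Generates trials x time x units tensors whose units have known types —
single-peaked temporal fields whose width grows with latency, linear ramps
of random sign, ramp+bump combinations, oscillatory units, i.i.d. noise
units, and stimulus-/location-only units — plus per-trial additive Gaussian
noise.  Condition coding controls how a two-condition population represents
the conditions: independent latency orderings (orthogonal sequences),
shared dynamics, or a condition signal decaying linearly to zero across
the window.  Because every unit's type is known, the generator calibrates
the classification, information, and decoding analyses without training
any agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .mutualinfo import ActivityRecords
from .recording import ActivityTensor

__all__ = [
    "PlantedPopulationSpec",
    "generate",
    "generate_joint_selectivity",
]

UNIT_TYPES = ("TIME_CELL", "RAMPING_CELL", "BOTH", "OSCILLATORY", "NOISE",
              "STIMULUS_ONLY", "LOCATION_ONLY")

BUMP_BASE_WIDTH = 1.5  # time steps; receptive fields widen with latency


@dataclass
class PlantedPopulationSpec:
    n_trials: int = 500
    n_time: int = 40
    n_units: int = 128
    counts: dict[str, int] = field(default_factory=lambda: {"NOISE": 128})
    field_width_growth: float = 0.05  # bump width slope vs latency
    noise_sd: float = 0.1
    n_conditions: int = 1
    condition_coding: str = "IDENTICAL"  # ORTHOGONAL_SEQUENCES | IDENTICAL | DECAYING
    n_locations: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(UNIT_TYPES)
        if unknown:
            raise ValueError(f"unknown unit types {unknown}")
        if sum(self.counts.values()) != self.n_units:
            raise ValueError("type counts must sum to n_units")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.condition_coding not in ("ORTHOGONAL_SEQUENCES", "IDENTICAL", "DECAYING"):
            raise ValueError("unknown condition_coding")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh)


def _bump(t: np.ndarray, latency: float, growth: float) -> np.ndarray:
    width = BUMP_BASE_WIDTH + growth * latency
    return np.exp(-0.5 * ((t - latency) / width) ** 2)


def _unit_template(kind: str, t: np.ndarray, rng: np.random.Generator,
                   latency: float, growth: float) -> np.ndarray:
    T = t.size
    if kind == "TIME_CELL":
        return _bump(t, latency, growth)
    if kind == "RAMPING_CELL":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ramp = sign * t / max(T - 1, 1)
        return ramp - ramp.min()
    if kind == "BOTH":
        # bump amplitude kept small so the summed curve still satisfies the
        # |r| >= 0.9 linearity criterion while the detrended residual
        # carries significant temporal information
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ramp = sign * t / max(T - 1, 1)
        return (ramp - ramp.min()) + 0.25 * _bump(t, latency, growth)
    if kind == "OSCILLATORY":
        freq = rng.uniform(2.0, 4.0)  # cycles per window
        phase = rng.uniform(0, 2 * np.pi)
        return 0.5 * (1 + np.sin(2 * np.pi * freq * t / T + phase))
    if kind == "NOISE":
        return np.zeros(T)
    if kind == "STIMULUS_ONLY":
        return np.full(T, 0.5)
    if kind == "LOCATION_ONLY":
        return np.zeros(T)
    raise ValueError(kind)


def generate(spec: PlantedPopulationSpec) -> tuple[ActivityTensor, pd.DataFrame]:
    """Planted population tensor plus its ground-truth label table.

    Time cells tile the window at evenly spaced latencies with width
    w(latency) = w0 + growth * latency; activity is clipped at 0 then
    min-max normalized per unit, so the tensor satisfies the normalized
    ActivityTensor contract.
    """
    rng = np.random.default_rng(spec.rng_seed)
    t = np.arange(spec.n_time, dtype=np.float64)
    kinds: list[str] = []
    for kind in UNIT_TYPES:
        kinds += [kind] * spec.counts.get(kind, 0)

    cond = rng.integers(spec.n_conditions, size=spec.n_trials)
    timed = [k for k in ("TIME_CELL", "BOTH") ]
    # evenly tiled latencies across the timed units
    n_timed = sum(spec.counts.get(k, 0) for k in timed)
    latencies = iter(np.linspace(0, spec.n_time - 1, max(n_timed, 1)))

    act = np.zeros((spec.n_trials, spec.n_time, spec.n_units))
    rows = []
    for u, kind in enumerate(kinds):
        lat = float(next(latencies)) if kind in timed else np.nan
        per_cond = []
        for c in range(spec.n_conditions):
            if c == 0 or spec.condition_coding == "IDENTICAL":
                base_lat = lat
            elif kind in timed:
                # ORTHOGONAL_SEQUENCES and DECAYING both start from
                # condition-specific latencies; DECAYING then shrinks the
                # difference to zero across the window
                base_lat = float(rng.uniform(0, spec.n_time - 1))
            else:
                base_lat = lat
            tpl = _unit_template(kind, t, rng, base_lat, spec.field_width_growth)
            if kind == "STIMULUS_ONLY" and spec.n_conditions > 1:
                tpl = tpl * (1.0 if c == 0 else 0.1)
            per_cond.append(tpl)
        per_cond = np.asarray(per_cond)
        if spec.condition_coding == "DECAYING" and spec.n_conditions > 1:
            # the condition-specific part decays linearly to zero over the
            # window, leaving identical dynamics by the end
            mean_tpl = per_cond.mean(axis=0)
            decay = 1.0 - t / max(spec.n_time - 1, 1)
            per_cond = mean_tpl[None, :] + (per_cond - mean_tpl[None, :]) * decay[None, :]
        base = per_cond[cond]  # (n_trials, T)
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_trials, spec.n_time))
        act[:, :, u] = base + noise
        rows.append({"unit_id": u, "kind": kind, "latency": lat})

    act = np.clip(act, 0.0, None)
    lo = act.min(axis=(0, 1))
    hi = act.max(axis=(0, 1))
    rngs = np.where(hi - lo > 0, hi - lo, 1.0)
    act = np.where((hi - lo) > 0, (act - lo) / rngs, 0.0)

    labels = {"sample": cond,
              "T1": np.full(spec.n_trials, -1),
              "T2": np.full(spec.n_trials, -1),
              "correct": np.ones(spec.n_trials, dtype=bool)}
    tensor = ActivityTensor(
        activity=act,
        lengths=np.full(spec.n_trials, spec.n_time, dtype=np.int64),
        labels=labels,
        window_tag="DELAY",
        normalized=True,
        meta={"seed": spec.rng_seed, "planted": True},
    )
    return tensor, pd.DataFrame(rows)


def generate_joint_selectivity(
    spec: PlantedPopulationSpec,
    variables: Sequence[str] = ("stimulus", "time"),
    kind: str = "JOINT",
    effect: float = 1.0,
    n_records: int = 4000,
) -> ActivityRecords:
    """Records for one unit whose mean response depends only on ``variables``.

    ``kind`` picks the planted selectivity: "JOINT" (multiplicative
    dependence on every listed variable), a single variable name
    ("stimulus"/"time"/"location"), or "CONSTANT".  Known effect size
    ``effect`` scales the modulation above a 0.1 baseline.
    """
    variables = list(variables)
    bad = set(variables) - {"stimulus", "time", "location"}
    if bad:
        raise ValueError(f"unknown variables {bad}")
    rng = np.random.default_rng(spec.rng_seed)
    levels = {"stimulus": max(spec.n_conditions, 2), "time": spec.n_time,
              "location": spec.n_locations}
    draws = {v: rng.integers(levels[v], size=n_records) for v in variables}

    def unit_mod(v: str) -> np.ndarray:
        x = draws[v] / max(levels[v] - 1, 1)
        if v == "time":
            return np.exp(-0.5 * ((x - 0.4) / 0.2) ** 2)
        return (draws[v] % 2 == 0).astype(float)

    mean = np.full(n_records, 0.1)
    if kind == "JOINT":
        mod = np.ones(n_records)
        for v in variables:
            mod *= unit_mod(v)
        mean = 0.1 + effect * mod
    elif kind in draws:
        mean = 0.1 + effect * unit_mod(kind)
    elif kind != "CONSTANT":
        raise ValueError(f"unknown kind {kind!r}")
    activity = np.clip(mean + rng.normal(0, spec.noise_sd, size=n_records), 0, None)
    return ActivityRecords(activity=activity, variables=draws,
                           n_levels={v: levels[v] for v in variables})
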