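"""Classification of recurrent units into time cells and ramping cells.

Definitions follow the standard neuroscience criteria:

* **Temporal information** of a tuning curve lambda(t) with occupancy p(t):

      I = sum_t lambda(t) * log2(lambda(t) / lambda_bar) * p(t),

  with lambda_bar the occupancy-weighted mean activity.  A unit is a
  *candidate time cell* when the information of its (detrended, if it is a
  ramping candidate) tuning curve exceeds the 99th percentile of 100
  tuning curves rebuilt after circularly shuffling each trial's activity
  by a random offset.

* **Ramping cells** are candidates when a linear regression of lambda(t)
  on t has p <= 0.05 and |Pearson r| >= 0.9 (ramps may go up or down).

* Candidates of either kind are confirmed only if their **trial
  reliability** — the Pearson correlation between even- and odd-trial
  average curves — exceeds the 99th percentile of the same statistic on
  100 circularly shuffled surrogates.

Classification always runs on min-max normalized activity, so tuning
curves are nonnegative and the information logarithms are safe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .recording import ActivityTensor, TuningCurve, population_tuning

__all__ = [
    "CellLabel",
    "temporal_information",
    "classify_ramping",
    "classify_time",
    "circular_shuffle",
    "trial_reliability",
    "classify_population",
    "condition_correlation",
]

logger = logging.getLogger(__name__)

RAMP_P = 0.05
RAMP_R = 0.9
N_SHUFFLES = 100
PERCENTILE = 99.0


@dataclass
class CellLabel:
    unit_id: int
    is_time_cell: bool
    is_ramping_cell: bool
    temporal_info: float
    time_threshold: float
    ramp_slope: float
    ramp_r: float
    ramp_p: float
    reliability_r: float
    reliability_significant: bool


def temporal_information(curve, occupancy: Optional[np.ndarray] = None) -> float:
    """Skaggs-style temporal information (bits x activity) of one curve.

    Accepts a :class:`TuningCurve` or a raw lambda(t) array plus
    ``occupancy``.  Terms with lambda(t) = 0 contribute 0; a curve with
    zero mean has I = 0 by definition.
    """
    if isinstance(curve, TuningCurve):
        lam, p = curve.mean_activity, curve.occupancy
    else:
        lam = np.asarray(curve, dtype=np.float64)
        p = occupancy if occupancy is not None else np.full(lam.shape, 1.0 / lam.size)
    return float(_information_rows(lam[None, :], p)[0])


def _information_rows(lam: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorized information for rows of lam (n_curves, T)."""
    lam_bar = lam @ p
    out = np.zeros(lam.shape[0])
    ok = lam_bar > 0
    if np.any(ok):
        sub = lam[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = sub / lam_bar[ok, None]
            terms = np.where(sub > 0, sub * np.log2(np.where(sub > 0, ratio, 1.0)), 0.0)
        out[ok] = terms @ p
    return out


def circular_shuffle(trials: np.ndarray, rng: np.random.Generator,
                     n_shuffles: int = 1) -> np.ndarray:
    """Rotate each trial's activity by an independent uniform offset.

    ``trials`` is (n_trials, T); returns (n_shuffles, n_trials, T).  The
    multiset of values within each trial is preserved.
    """
    n_trials, T = trials.shape
    offsets = rng.integers(0, T, size=(n_shuffles, n_trials))
    idx = (np.arange(T)[None, None, :] - offsets[:, :, None]) % T
    return trials[np.arange(n_trials)[None, :, None], idx]


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between matching rows of a and b; nan if constant."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = (a * b).sum(axis=-1)
    den = np.sqrt((a * a).sum(axis=-1) * (b * b).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def trial_reliability(trials: np.ndarray, n_shuffles: int = N_SHUFFLES,
                      rng: Optional[np.random.Generator] = None,
                      shuffled: Optional[np.ndarray] = None) -> tuple[float, bool]:
    """Even/odd-trial tuning-curve correlation and its significance.

    ``shuffled`` may supply a precomputed (n_shuffles, n_trials, T)
    circular-shuffle surrogate to avoid regenerating it.
    """
    trials = np.asarray(trials, dtype=np.float64)
    if trials.shape[0] < 4:
        raise ValueError("trial_reliability needs >= 4 trials")
    rng = np.random.default_rng(0) if rng is None else rng
    even = trials[0::2].mean(axis=0)
    odd = trials[1::2].mean(axis=0)
    r = float(_pearson_rows(even[None], odd[None])[0])
    if shuffled is None:
        shuffled = circular_shuffle(trials, rng, n_shuffles)
    ev = shuffled[:, 0::2].mean(axis=1)
    od = shuffled[:, 1::2].mean(axis=1)
    null = _pearson_rows(ev, od)
    null = null[np.isfinite(null)]
    if not np.isfinite(r) or null.size == 0:
        return (r if np.isfinite(r) else np.nan), False
    thresh = np.percentile(null, PERCENTILE)
    return r, bool(r > thresh)


def _detrend(curve: np.ndarray) -> np.ndarray:
    t = np.arange(curve.size, dtype=np.float64)
    slope, intercept = np.polyfit(t, curve, 1)
    return curve - (slope * t + intercept)


def classify_ramping(curve, trials: Optional[np.ndarray] = None,
                     occupancy: Optional[np.ndarray] = None,
                     reliability: Optional[bool] = None):
    """Linear-regression ramping test on a tuning curve.

    Returns (is_candidate_and_reliable, slope, r, p).  If ``reliability``
    is None and ``trials`` are given, the trial-reliability gate is
    computed here; otherwise the supplied flag is used (True when omitted,
    i.e. the bare regression criterion).
    """
    lam = curve.mean_activity if isinstance(curve, TuningCurve) else np.asarray(curve, float)
    if lam.size < 3:
        raise ValueError("ramping test needs a window of length >= 3")
    t = np.arange(lam.size, dtype=np.float64)
    if np.allclose(lam, lam[0]):
        return False, 0.0, np.nan, np.nan
    res = stats.linregress(t, lam)
    candidate = (res.pvalue <= RAMP_P) and (abs(res.rvalue) >= RAMP_R)
    if reliability is None:
        reliability = True
        if trials is not None:
            _, reliability = trial_reliability(trials)
    return bool(candidate and reliability), float(res.slope), float(res.rvalue), float(res.pvalue)


def classify_time(curve, trials: np.ndarray,
                  n_shuffles: int = N_SHUFFLES,
                  rng: Optional[np.random.Generator] = None,
                  occupancy: Optional[np.ndarray] = None,
                  is_ramping_candidate: bool = False,
                  reliability: Optional[bool] = None,
                  shuffled: Optional[np.ndarray] = None):
    """Shuffle-based temporal-information test.

    The information of the trial-averaged curve (detrended by its own
    regression line when the unit is a ramping candidate) is compared with
    the strict 99th percentile of the same statistic on circularly
    shuffled surrogates (each detrended by its own fit, likewise).
    Returns (is_time_cell, I, threshold).
    """
    trials = np.asarray(trials, dtype=np.float64)
    if trials.shape[0] < 2:
        raise ValueError("classify_time needs >= 2 trials")
    rng = np.random.default_rng(0) if rng is None else rng
    lam = curve.mean_activity if isinstance(curve, TuningCurve) else np.asarray(curve, float)
    p = (curve.occupancy if isinstance(curve, TuningCurve)
         else (occupancy if occupancy is not None else np.full(lam.size, 1.0 / lam.size)))
    if shuffled is None:
        shuffled = circular_shuffle(trials, rng, n_shuffles)
    null_curves = shuffled.mean(axis=1)
    if is_ramping_candidate:
        lam = _detrend(lam)
        lam = lam - lam.min()  # keep the residual curve nonnegative
        null_curves = np.stack([_detrend(c) for c in null_curves])
        null_curves = null_curves - null_curves.min(axis=1, keepdims=True)
    info = temporal_information(lam, p)
    null = _information_rows(null_curves, p)
    thresh = float(np.percentile(null, PERCENTILE))
    candidate = info > thresh
    if reliability is None:
        reliability = True
    return bool(candidate and reliability), float(info), thresh


def _fixed_length_view(tensor: ActivityTensor) -> tuple[np.ndarray, np.ndarray]:
    """Trials x time x units array on a common time axis.

    Ragged windows are restricted to the trials of maximal length so each
    shuffle/rotation acts on a full-length window.
    """
    if tensor.ragged:
        keep = tensor.lengths == tensor.lengths.max()
        logger.info("ragged window: classifying on %d/%d max-length trials",
                    keep.sum(), tensor.n_trials)
        act = tensor.activity[keep]
    else:
        act = tensor.activity
    T = int(tensor.lengths.max())
    p = np.full(T, 1.0 / T)
    return act[:, :T, :], p


def classify_population(tensor: ActivityTensor,
                        n_shuffles: int = N_SHUFFLES,
                        seed: int = 0) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every unit; returns (table, category counts).

    Counts partition the population: time-only, ramp-only, both, neither.
    """
    if not tensor.normalized:
        raise ValueError("classification requires a normalized tensor")
    act, p = _fixed_length_view(tensor)
    rng = np.random.default_rng(seed)
    rows = []
    for u in range(tensor.n_units):
        trials = act[:, :, u]
        lam = trials.mean(axis=0)
        shuffled = circular_shuffle(trials, rng, n_shuffles)
        rel_r, rel_sig = trial_reliability(trials, n_shuffles, rng, shuffled=shuffled)
        _, slope, r, pv = classify_ramping(lam, reliability=True)
        ramp_candidate = np.isfinite(r) and (pv <= RAMP_P) and (abs(r) >= RAMP_R)
        _, info, thresh = classify_time(
            lam, trials, n_shuffles, rng, occupancy=p,
            is_ramping_candidate=ramp_candidate, shuffled=shuffled)
        time_candidate = info > thresh
        rows.append(CellLabel(
            unit_id=u,
            is_time_cell=bool(time_candidate and rel_sig),
            is_ramping_cell=bool(ramp_candidate and rel_sig),
            temporal_info=info,
            time_threshold=thresh,
            ramp_slope=slope,
            ramp_r=r,
            ramp_p=pv,
            reliability_r=rel_r,
            reliability_significant=rel_sig,
        ))
    table = pd.DataFrame([vars(r) for r in rows])
    tc, rc = table.is_time_cell.to_numpy(), table.is_ramping_cell.to_numpy()
    counts = {
        "time_only": int(np.sum(tc & ~rc)),
        "ramp_only": int(np.sum(rc & ~tc)),
        "both": int(np.sum(tc & rc)),
        "neither": int(np.sum(~tc & ~rc)),
    }
    return table, counts


def condition_correlation(tensor: ActivityTensor, filter_a, filter_b) -> np.ndarray:
    """Per-unit Pearson r between condition-specific tuning curves.

    Units with a constant curve in either condition are excluded (returned
    as NaN, with the exclusion logged).
    """
    lam_a, _, _ = population_tuning(tensor, filter_a)
    lam_b, _, _ = population_tuning(tensor, filter_b)
    T = min(lam_a.shape[1], lam_b.shape[1])
    r = _pearson_rows(lam_a[:, :T], lam_b[:, :T])
    n_bad = int(np.sum(~np.isfinite(r)))
    if n_bad:
        logger.info("condition_correlation: excluded %d constant-curve units", n_bad)
    return r
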