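"""Joint mutual information over stimulus x time (x location).

The temporal-information statistic extends to joint variables: with
lambda(s,t[,l]) the mean activity of a unit in each cell of the joint grid
and p(s,t[,l]) the occupancy of that cell,

    I = sum_cells lambda * log2(lambda / lambda_bar) * p,

lambda_bar being the occupancy-weighted grand mean.  Whether a particular
variable actually matters is probed by *dimension randomization*: each
record's value of that variable is replaced by an independent draw from its
marginal before the map is rebuilt — a unit indifferent to the variable
loses no information, a unit selective for it collapses toward zero.
Significance of the non-randomized score uses a shuffle null (activity
permuted across records, 100 times; significant when I exceeds the null
mean by more than 2 standard deviations), and population-level comparisons
between the raw and randomized scores use Kruskal-Wallis tests with
Bonferroni correction.

Records are (trial, time-step) observations: an activity value plus the
value of each variable at that step.  Location is discretized as one bin
per walkable grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recording import ActivityTensor

__all__ = [
    "ActivityRecords",
    "JointOccupancyMap",
    "InfoResult",
    "records_from_tensor",
    "build_map",
    "joint_information",
    "randomize_dimension",
    "information_significance",
    "compare_populations",
]

N_SHUFFLES = 100
N_RANDOMIZATION_REPEATS = 100


@dataclass
class ActivityRecords:
    """Per-(trial, step) activity of one unit with variable codes.

    ``variables`` maps a dimension name to an integer-coded array aligned
    with ``activity``; ``n_levels`` gives each dimension's cardinality.
    """

    activity: np.ndarray
    variables: dict[str, np.ndarray]
    n_levels: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.activity)
        for k, v in self.variables.items():
            if len(v) != n:
                raise ValueError(f"variable {k} misaligned with activity")

    @property
    def dims(self) -> list[str]:
        return list(self.variables)


@dataclass
class JointOccupancyMap:
    mean_activity: np.ndarray  # lambda over the joint grid
    occupancy: np.ndarray  # p over the joint grid
    dims: list[str] = field(default_factory=list)


def records_from_tensor(tensor: ActivityTensor, unit: int,
                        dims: Sequence[str] = ("stimulus", "time")) -> ActivityRecords:
    """Flatten one unit's recorded window into (trial, step) records.

    ``stimulus`` comes from the per-trial ``sample`` label, ``time`` is the
    step index within the window, ``location`` (spatial tasks) the per-step
    cell index.
    """
    mask = tensor.mask()
    act = tensor.activity[:, :, unit][mask]
    n_tr, n_t = mask.shape
    tgrid = np.broadcast_to(np.arange(n_t), (n_tr, n_t))[mask]
    variables: dict[str, np.ndarray] = {}
    n_levels: dict[str, int] = {}
    for d in dims:
        if d == "time":
            variables[d] = tgrid
            n_levels[d] = n_t
        elif d == "stimulus":
            stim = np.broadcast_to(tensor.labels["sample"][:, None], (n_tr, n_t))[mask]
            codes, _ = pd.factorize(stim)
            variables[d] = codes
            n_levels[d] = int(codes.max()) + 1
        elif d == "location":
            loc = tensor.labels["location"][:, :n_t][mask]
            variables[d] = loc
            n_levels[d] = int(loc.max()) + 1
        else:
            raise ValueError(f"unknown dimension {d!r}")
    return ActivityRecords(activity=act, variables=variables, n_levels=n_levels)


def build_map(records: ActivityRecords,
              override: Optional[dict[str, np.ndarray]] = None) -> JointOccupancyMap:
    """Empirical lambda and p over the joint grid of the record variables."""
    dims = records.dims
    shape = tuple(records.n_levels[d] for d in dims)
    coords = tuple(
        (override[d] if override and d in override else records.variables[d])
        for d in dims
    )
    counts = np.zeros(shape)
    sums = np.zeros(shape)
    np.add.at(counts, coords, 1.0)
    np.add.at(sums, coords, records.activity)
    with np.errstate(invalid="ignore"):
        lam = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
    p = counts / counts.sum()
    return JointOccupancyMap(mean_activity=lam, occupancy=p, dims=list(dims))


def joint_information(jmap: JointOccupancyMap) -> float:
    """I = sum lambda log2(lambda/lambda_bar) p over the joint grid."""
    lam, p = jmap.mean_activity, jmap.occupancy
    lam_bar = float((lam * p).sum())
    if lam_bar <= 0:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(lam > 0, lam * np.log2(np.where(lam > 0, lam / lam_bar, 1.0)), 0.0)
    return float((terms * p).sum())


def randomize_dimension(records: ActivityRecords, which: str,
                        rng: np.random.Generator) -> JointOccupancyMap:
    """Rebuild the map with one variable replaced by marginal resamples."""
    if which not in records.variables:
        raise ValueError(f"unknown variable {which!r}")
    orig = records.variables[which]
    resampled = rng.choice(orig, size=len(orig), replace=True)
    return build_map(records, override={which: resampled})


def randomized_information(records: ActivityRecords, which: str,
                           rng: np.random.Generator,
                           n_repeats: int = N_RANDOMIZATION_REPEATS) -> float:
    """Average information over repeated randomizations of one dimension."""
    return float(np.mean([
        joint_information(randomize_dimension(records, which, rng))
        for _ in range(n_repeats)
    ]))


@dataclass
class InfoResult:
    I: float
    I_randomized: dict[str, float]
    significant: bool
    null_mean: float
    null_sd: float


def information_significance(records: ActivityRecords,
                             n_shuffles: int = N_SHUFFLES,
                             rng: Optional[np.random.Generator] = None,
                             n_randomization_repeats: int = N_RANDOMIZATION_REPEATS,
                             ) -> InfoResult:
    """Shuffle-null significance of the joint information of one unit.

    The null permutes activity across records; significance is evaluated
    only on the non-randomized score (I > null mean + 2 sd).  The
    randomized-dimension scores are averages over repeated draws.
    """
    if len(records.activity) == 0:
        raise ValueError("empty records")
    rng = np.random.default_rng(0) if rng is None else rng
    real = joint_information(build_map(records))
    null = np.empty(n_shuffles)
    shuffled = ActivityRecords(records.activity.copy(), records.variables,
                               records.n_levels)
    for k in range(n_shuffles):
        shuffled.activity = rng.permutation(records.activity)
        null[k] = joint_information(build_map(shuffled))
    mu, sd = float(null.mean()), float(null.std())
    rand = {d: randomized_information(records, d, rng, n_randomization_repeats)
            for d in records.dims}
    return InfoResult(I=real, I_randomized=rand,
                      significant=bool(real > mu + 2 * sd),
                      null_mean=mu, null_sd=sd)


def compare_populations(I_values: Sequence[float],
                        I_randomized: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Kruskal-Wallis comparison of raw vs each randomized score set.

    Returns one row per randomized dimension with the H statistic, raw p,
    and Bonferroni-corrected p (times the number of comparisons made).
    """
    base = np.asarray(I_values, dtype=np.float64)
    if len(base) < 2:
        raise ValueError("need >= 2 scores per group")
    rows = []
    n_comp = len(I_randomized)
    for dim, vals in I_randomized.items():
        vals = np.asarray(vals, dtype=np.float64)
        if len(vals) < 2:
            raise ValueError("need >= 2 scores per group")
        if np.allclose(base, vals):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(base, vals)
        rows.append({
            "dimension": dim,
            "H": float(h),
            "p": float(p),
            "p_bonferroni": float(min(1.0, p * n_comp)),
        })
    return pd.DataFrame(rows)
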