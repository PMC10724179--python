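"""Population decoding of stimulus identity and elapsed time.

Stimulus identity is decoded from the single-time population vector with a
linear support vector machine, independently at every time step of the
window, under stratified 5-fold cross-validation.  A chance baseline is
obtained by shuffling cell identities across episodes — each unit's
activity at a time point is reassigned to a random episode, independently
per unit — and decoding the shuffled data identically; the surrogate
breaks any alignment between population vectors and trial labels, so its
accuracy is chance by construction.

Elapsed time is decoded with an ordinary least-squares linear map from the
population vector to the step index, trained on a random 60% of vectors
and tested on the rest.  Trial filters allow the decoder to be trained on
correct trials only and evaluated on incorrect trials (the behavioral
dissociation analysis: if temporal coding drove choices, incorrect trials
should decode worse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .recording import ActivityTensor, _filter_index

__all__ = [
    "DecodingCurve",
    "decode_stimulus",
    "TimeDecodingResult",
    "decode_time",
    "spatial_rate_map",
]

logger = logging.getLogger(__name__)


@dataclass
class DecodingCurve:
    accuracy: np.ndarray  # per-timestep, averaged over folds
    shuffled_accuracy: np.ndarray
    fold_sd: np.ndarray
    folds: int


def _fold_accuracy(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> tuple[float, float]:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[tr], y[tr])
        accs.append(clf.score(X[te], y[te]))
    return float(np.mean(accs)), float(np.std(accs))


def decode_stimulus(tensor: ActivityTensor, n_folds: int = 5,
                    seed: int = 0) -> DecodingCurve:
    """Per-timestep SVM decoding of the sample identity.

    Requires two stimulus classes with at least 10 trials each; classes
    imbalanced beyond 9:1 trigger a warning (folds are stratified either
    way).
    """
    y = np.asarray(tensor.labels["sample"])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 10:
        raise ValueError("need two stimulus classes with >= 10 trials each")
    if counts.max() / counts.min() > 9:
        logger.warning("stimulus classes imbalanced beyond 9:1 (%s)", counts)
    T = int(tensor.lengths.min())
    rng = np.random.default_rng(seed)
    acc = np.empty(T)
    sh_acc = np.empty(T)
    sd = np.empty(T)
    for t in range(T):
        X = tensor.activity[:, t, :]
        acc[t], sd[t] = _fold_accuracy(X, y, n_folds, seed + t)
        # chance surrogate: shuffle each cell's assignment to episodes, so
        # population vectors lose both their cross-cell structure and any
        # alignment with the trial labels
        Xs = rng.permuted(X, axis=0)
        sh_acc[t], _ = _fold_accuracy(Xs, y, n_folds, seed + t)
    return DecodingCurve(accuracy=acc, shuffled_accuracy=sh_acc, fold_sd=sd,
                         folds=n_folds)


@dataclass
class TimeDecodingResult:
    """Predicted-vs-actual elapsed time on train/test pools."""

    train_actual: np.ndarray
    train_predicted: np.ndarray
    test_actual: np.ndarray
    test_predicted: np.ndarray
    extra_actual: Optional[np.ndarray] = None  # from the test_filter pool
    extra_predicted: Optional[np.ndarray] = None

    @staticmethod
    def _err(a, p):
        return np.abs(p - a)

    def test_errors(self) -> np.ndarray:
        return self._err(self.test_actual, self.test_predicted)

    def train_errors(self) -> np.ndarray:
        return self._err(self.train_actual, self.train_predicted)

    def extra_errors(self) -> np.ndarray:
        return self._err(self.extra_actual, self.extra_predicted)

    def compare_errors(self) -> tuple[float, float]:
        """Rank-sum test of held-out vs filter-pool absolute errors."""
        u, p = stats.mannwhitneyu(self.test_errors(), self.extra_errors(),
                                  alternative="two-sided")
        return float(u), float(p)


def _pooled_vectors(tensor: ActivityTensor, idx: np.ndarray):
    mask = tensor.mask()[idx]
    X = tensor.activity[idx][mask]
    tgrid = np.broadcast_to(np.arange(tensor.n_time), mask.shape)[mask]
    return X, tgrid.astype(np.float64)


def decode_time(tensor: ActivityTensor, train_fraction: float = 0.6,
                seed: int = 0, train_filter=None, test_filter=None
                ) -> TimeDecodingResult:
    """Linear regression from population vectors to elapsed time.

    Fits by least squares (minimum-norm solution when the design is
    singular, with a log note).  ``train_filter`` restricts the train/test
    split to matching trials; ``test_filter`` selects an additional pool
    (e.g. incorrect trials) evaluated with the same decoder.
    """
    if tensor.lengths.min() < 3:
        raise ValueError("decode_time needs a window of length >= 3")
    rng = np.random.default_rng(seed)
    idx = _filter_index(tensor, train_filter)
    X, y = _pooled_vectors(tensor, idx)
    n = len(y)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    A = np.hstack([X, np.ones((n, 1))])
    coef, _res, rank, _sv = np.linalg.lstsq(A[tr], y[tr], rcond=None)
    if rank < A.shape[1]:
        logger.info("singular design (rank %d < %d): minimum-norm solution",
                    rank, A.shape[1])
    pred = A @ coef
    result = TimeDecodingResult(
        train_actual=y[tr], train_predicted=pred[tr],
        test_actual=y[te], test_predicted=pred[te],
    )
    if test_filter is not None:
        idx2 = _filter_index(tensor, test_filter)
        X2, y2 = _pooled_vectors(tensor, idx2)
        A2 = np.hstack([X2, np.ones((len(y2), 1))])
        result.extra_actual = y2
        result.extra_predicted = A2 @ coef
    return result


def spatial_rate_map(tensor: ActivityTensor, condition_filter=None,
                     n_cells: Optional[int] = None) -> np.ndarray:
    """Occupancy-normalized mean activity per walkable grid cell.

    Returns (units, cells); unvisited cells are NaN.  Cell indices follow
    the recording's walkable-cell ordering.
    """
    if "location" not in tensor.labels:
        raise ValueError("tensor has no per-step location labels")
    idx = _filter_index(tensor, condition_filter)
    mask = tensor.mask()[idx]
    loc = tensor.labels["location"][idx][mask]
    act = tensor.activity[idx][mask]  # (steps, units)
    if n_cells is None:
        n_cells = int(loc.max()) + 1
    occ = np.bincount(loc, minlength=n_cells).astype(float)
    sums = np.zeros((n_cells, act.shape[1]))
    np.add.at(sums, loc, act)
    with np.errstate(invalid="ignore"):
        rate = np.where(occ[:, None] > 0, sums / np.maximum(occ[:, None], 1.0), np.nan)
    return rate.T
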