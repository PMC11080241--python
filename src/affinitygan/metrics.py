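"""Evaluation statistics: concordance index, MSE, AUPR, and r_m^2.

The concordance index sums a three-valued step function over all ordered
pairs with strictly greater true affinity and normalizes by the number of
such pairs; ties in the true values contribute nothing.  AUPR is computed as
average precision (step-function integration of the precision-recall curve)
after binarizing affinities at a pKd cutoff, 7 by default.  r_m^2 combines
the squared Pearson correlation with the through-origin counterpart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score

from .errors import InputError, UndefinedStatisticError

__all__ = ["EvaluationReport", "step_h", "concordance_index", "mean_squared_error",
           "binarize_affinities", "aupr", "rm_squared", "evaluate",
           "DEFAULT_BINARIZATION_THRESHOLD"]

DEFAULT_BINARIZATION_THRESHOLD = 7.0


@dataclass(frozen=True)
class EvaluationReport:
    ci: float
    mse: float
    aupr: float | None  # None when labels are single-class at the threshold
    rm2: float
    n: int          # number of (P_i, Y_i) pairs
    z: int          # number of comparable pairs (y_i > y_j)
    threshold: float
    positives: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv(self) -> str:
        d = asdict(self)
        keys = list(d)
        fmt = lambda v: "NA" if v is None else str(v)
        return "\t".join(keys) + "\n" + "\t".join(fmt(d[k]) for k in keys) + "\n"


def step_h(x: float) -> float:
    """Three-valued step function: 1 for x>0, 0.5 for x=0, 0 for x<0."""
    if not np.isfinite(x):
        raise InputError("step function argument must be finite")
    if x > 0:
        return 1.0
    if x == 0:
        return 0.5
    return 0.0


def _check_pair(y, f, min_len: int):
    y = np.asarray(y, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if y.shape != f.shape or y.ndim != 1:
        raise InputError("inputs must be 1-D vectors of equal length")
    if y.size < min_len:
        raise InputError(f"need at least {min_len} samples")
    if not (np.isfinite(y).all() and np.isfinite(f).all()):
        raise InputError("inputs must be finite")
    return y, f


def comparable_pairs(y) -> int:
    """Number of ordered pairs (i, j) with y_i > y_j."""
    y = np.asarray(y, dtype=np.float64)
    return int(np.sum(y[:, None] > y[None, :]))


def concordance_index(y, f) -> float:
    """(1/Z) * sum over pairs with y_i > y_j of h(f_i - f_j)."""
    y, f = _check_pair(y, f, 2)
    greater = y[:, None] > y[None, :]
    z = int(greater.sum())
    if z == 0:
        raise UndefinedStatisticError("all true values equal: no comparable pairs")
    diff = f[:, None] - f[None, :]
    h = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(h[greater].sum() / z)


def mean_squared_error(Y, P) -> float:
    Y, P = _check_pair(Y, P, 1)
    return float(np.mean((P - Y) ** 2))


def binarize_affinities(y, threshold: float = DEFAULT_BINARIZATION_THRESHOLD) -> np.ndarray:
    """Label 1 iff y_i >= threshold (the boundary value counts as positive)."""
    y = np.asarray(y, dtype=np.float64)
    if not np.isfinite(y).all():
        raise InputError("affinities must be finite")
    return (y >= threshold).astype(np.int64)


def aupr(labels, scores) -> float:
    """Average precision over descending score thresholds (step integration)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise InputError("labels and scores must have equal length")
    if labels.min() == labels.max():
        raise UndefinedStatisticError("AUPR undefined for single-class labels")
    return float(average_precision_score(labels, scores))


def rm_squared(y, p) -> float:
    """r_m^2 = r^2 * (1 - sqrt(r^2 - r0^2)), r0^2 through the origin.

    r0^2 regresses y on p with slope k = sum(y*p)/sum(p^2); negative
    (r^2 - r0^2) is clamped to zero before the square root.
    """
    y, p = _check_pair(y, p, 3)
    if np.ptp(y) == 0 or np.ptp(p) == 0:
        raise UndefinedStatisticError("r_m^2 undefined for constant input")
    r = np.corrcoef(y, p)[0, 1]
    r2 = r * r
    k = float(np.sum(y * p) / np.sum(p * p))
    ss_res = float(np.sum((y - k * p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    return float(r2 * (1.0 - np.sqrt(max(0.0, r2 - r02))))


def evaluate(Y, P, threshold: float = DEFAULT_BINARIZATION_THRESHOLD) -> EvaluationReport:
    """Aggregate all four statistics into one report."""
    Y, P = _check_pair(Y, P, 2)
    labels = binarize_affinities(Y, threshold)
    try:
        aupr_val = aupr(labels, P)
    except UndefinedStatisticError:
        aupr_val = None
    return EvaluationReport(
        ci=concordance_index(Y, P),
        mse=mean_squared_error(Y, P),
        aupr=aupr_val,
        rm2=rm_squared(Y, P),
        n=int(Y.size),
        z=comparable_pairs(Y),
        threshold=float(threshold),
        positives=int(labels.sum()),
    )
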