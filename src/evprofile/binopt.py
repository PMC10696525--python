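"""Hill-climbing search over contiguous size-bin groupings.

The 30-160 nm working range is pre-separated into 13 base bins of 10 nm.
Any contiguous grouping of those bins is encoded by which of the 12
internal boundaries are kept, giving 2^12 = 4096 candidate partitions.
The search objective is cross-validated classification accuracy of the
feature matrix built under the candidate partition; hill climbing
(steepest ascent over single-boundary toggles, random restarts) is the
paper-scale search, and exhaustive enumeration serves as the oracle that
bounds its adequacy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .classify import cv_accuracy
from .features import BASE_STEP, SIZE_HI, SIZE_LO, SizePartition

MAX_EXHAUSTIVE_BASE = 20


def base_grid(
    lo: float = SIZE_LO, hi: float = SIZE_HI, step: float = BASE_STEP
) -> list[tuple[float, float]]:
    """Contiguous base bins [lo, lo+step), ...; (hi-lo) must divide by step."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    n, rem = divmod(round(hi - lo, 9), step)
    if rem != 0:
        raise ValueError(f"range {lo}-{hi} not divisible by step {step}")
    n = int(n)
    return [(lo + i * step, lo + (i + 1) * step) for i in range(n)]


def _mask_to_partition(mask: tuple[int, ...], lo: float, step: float) -> SizePartition:
    n_base = len(mask) + 1
    bounds = [lo]
    for i, keep in enumerate(mask):
        if keep:
            bounds.append(lo + (i + 1) * step)
    bounds.append(lo + n_base * step)
    return SizePartition(tuple(bounds))


def _partition_to_mask(p: SizePartition, n_base: int, lo: float, step: float):
    internal = {round(lo + (i + 1) * step, 9): i for i in range(n_base - 1)}
    mask = [0] * (n_base - 1)
    for b in p.boundaries[1:-1]:
        mask[internal[round(b, 9)]] = 1
    return tuple(mask)


def random_partition(
    n_base: int,
    rng: np.random.Generator,
    lo: float = SIZE_LO,
    step: float = BASE_STEP,
) -> SizePartition:
    """Each internal boundary kept independently with probability 1/2."""
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    mask = tuple(int(b) for b in rng.random(n_base - 1) < 0.5)
    return _mask_to_partition(mask, lo, step)


def neighbors(p: SizePartition, step: float = BASE_STEP) -> list[SizePartition]:
    """One partition per internal base boundary, with that boundary toggled."""
    lo, hi = p.boundaries[0], p.boundaries[-1]
    n_base = int(round((hi - lo) / step))
    mask = list(_partition_to_mask(p, n_base, lo, step))
    out = []
    for i in range(n_base - 1):
        flipped = mask.copy()
        flipped[i] ^= 1
        out.append(_mask_to_partition(tuple(flipped), lo, step))
    return out


@dataclass
class PartitionSearchResult:
    """Outcome of a partition search (hill climbing or exhaustive)."""

    best_partition: SizePartition
    best_value: float
    traces: list[list[float]]  # per-restart objective trace (current value per step)
    restarts: int
    seed: int | None
    n_evaluations: int
    method: str = "hill_climb"
    holdout_accuracy: float | None = None  # overfitting guard, if requested

    def to_dict(self) -> dict:
        return {
            "best_partition": self.best_partition.to_string(),
            "best_value": self.best_value,
            "traces": self.traces,
            "restarts": self.restarts,
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
            "method": self.method,
            "holdout_accuracy": self.holdout_accuracy,
        }


class _MemoObjective:
    """Memoizing wrapper; each distinct partition is evaluated exactly once."""

    def __init__(self, objective: Callable[[SizePartition], float]):
        self.objective = objective
        self.cache: dict[tuple[float, ...], float] = {}
        self.n_calls = 0

    def __call__(self, p: SizePartition) -> float:
        key = p.boundaries
        if key not in self.cache:
            self.n_calls += 1
            self.cache[key] = float(self.objective(p))
        return self.cache[key]


def _better_tie(a: SizePartition, b: SizePartition) -> bool:
    """True if a beats b on the tie-break: fewer groups, then lexicographic."""
    return (a.n_groups, a.boundaries) < (b.n_groups, b.boundaries)


def hill_climb(
    objective: Callable[[SizePartition], float],
    n_base: int = 13,
    max_iter: int = 100,
    restarts: int = 1,
    seed: int | None = None,
    target_accuracy: float | None = None,
    lo: float = SIZE_LO,
    step: float = BASE_STEP,
) -> PartitionSearchResult:
    """Greedy steepest-ascent search with random restarts.

    Each restart starts from a random partition and repeatedly moves to
    the best-scoring neighbor while it *strictly* improves the
    objective, stopping at a local optimum, ``max_iter`` steps, or when
    ``target_accuracy`` is reached.  Objective values are memoized
    across restarts; the best partition over all restarts is returned
    with the full per-restart trace.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    memo = objective if isinstance(objective, _MemoObjective) else _MemoObjective(objective)
    rng = np.random.default_rng(seed)
    best_p: SizePartition | None = None
    best_v = -np.inf
    traces: list[list[float]] = []
    done = False
    for _ in range(restarts):
        current = random_partition(n_base, rng, lo=lo, step=step)
        value = memo(current)
        trace = [value]
        for _ in range(max_iter):
            if target_accuracy is not None and value >= target_accuracy:
                done = True
                break
            move_p, move_v = None, value
            for nb in neighbors(current, step=step):
                v = memo(nb)
                if v > move_v or (
                    v == move_v and move_p is not None and _better_tie(nb, move_p)
                ):
                    move_p, move_v = nb, v
            if move_p is None:  # local optimum
                break
            current, value = move_p, move_v
            trace.append(value)
        traces.append(trace)
        if value > best_v or (value == best_v and best_p and _better_tie(current, best_p)):
            best_p, best_v = current, value
        if done or (target_accuracy is not None and best_v >= target_accuracy):
            break
    return PartitionSearchResult(
        best_partition=best_p,
        best_value=float(best_v),
        traces=traces,
        restarts=len(traces),
        seed=seed,
        n_evaluations=memo.n_calls,
        method="hill_climb",
    )


def exhaustive_search(
    objective: Callable[[SizePartition], float],
    n_base: int = 13,
    lo: float = SIZE_LO,
    step: float = BASE_STEP,
) -> PartitionSearchResult:
    """Global optimum over all 2^(n_base-1) contiguous partitions.

    Ties break toward fewer groups, then lexicographically smaller
    boundary tuples, so the result is independent of evaluation order.
    """
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    if n_base > MAX_EXHAUSTIVE_BASE:
        raise ValueError(f"n_base={n_base} too large for enumeration")
    memo = objective if isinstance(objective, _MemoObjective) else _MemoObjective(objective)
    best_p, best_v = None, -np.inf
    trace = []
    for bits in range(2 ** (n_base - 1)):
        mask = tuple((bits >> i) & 1 for i in range(n_base - 1))
        p = _mask_to_partition(mask, lo, step)
        v = memo(p)
        trace.append(v)
        if v > best_v or (v == best_v and best_p is not None and _better_tie(p, best_p)):
            best_p, best_v = p, v
    return PartitionSearchResult(
        best_partition=best_p,
        best_value=float(best_v),
        traces=[trace],
        restarts=1,
        seed=None,
        n_evaluations=memo.n_calls,
        method="exhaustive",
    )


def partition_features(
    bin_expression: pd.DataFrame,
    partition: SizePartition,
    lo: float = SIZE_LO,
    step: float = BASE_STEP,
) -> np.ndarray:
    """Raw (unnormalized) per-group expression sums for every sample."""
    markers = bin_expression.columns.get_level_values(0).unique()
    arr = np.stack([bin_expression[m].to_numpy(dtype=float) for m in markers], axis=1)
    idx = np.round((np.asarray(partition.boundaries) - lo) / step).astype(int)
    return np.concatenate(
        [arr[:, :, idx[g] : idx[g + 1]].sum(axis=2) for g in range(partition.n_groups)],
        axis=1,
    )


def make_expression_objective(
    bin_expression: pd.DataFrame,
    labels,
    n_folds: int = 5,
    seed: int = 0,
    lo: float = SIZE_LO,
    step: float = BASE_STEP,
) -> _MemoObjective:
    """CV-accuracy objective over per-base-bin expression features.

    ``bin_expression`` is the samples x (marker, bin) table from
    :func:`evprofile.features.per_bin_expression` (overall-total
    denominator, so per-group expression is the sum of member-bin
    columns).  Folds are stratified, shuffled once with ``seed`` and
    shared across every partition, making comparisons paired.  The
    returned callable memoizes per-partition values and counts true
    evaluations in ``n_calls``.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels)
    markers = bin_expression.columns.get_level_values(0).unique()
    n_bins = bin_expression[markers[0]].shape[1]
    # (n_samples, n_markers, n_bins+1) cumulative sums along the bin axis
    arr = np.stack([bin_expression[m].to_numpy(dtype=float) for m in markers], axis=1)
    csum = np.concatenate([np.zeros((arr.shape[0], len(markers), 1)), np.cumsum(arr, axis=2)], axis=2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros((len(y), 1)), y))

    def objective(p: SizePartition) -> float:
        idx = np.round((np.asarray(p.boundaries) - lo) / step).astype(int)
        X = np.concatenate(
            [csum[:, :, idx[g + 1]] - csum[:, :, idx[g]] for g in range(p.n_groups)],
            axis=1,
        )
        lo_p, hi_p = np.percentile(X, [2.5, 97.5], axis=0)
        keep = hi_p > lo_p
        X = (X[:, keep] - lo_p[keep]) / (hi_p[keep] - lo_p[keep])
        return cv_accuracy(X, y, splits)

    return _MemoObjective(objective)
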