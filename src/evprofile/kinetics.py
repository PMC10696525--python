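"""Size-resolved cumulative binding curves and saturating-exponential fits.

Digital counting of single-particle landings gives, for each size group,
a cumulative count versus time.  Under first-order association to a
finite number of surface sites the expected curve is the Langmuir
saturation form

    N(t) = N_max * (1 - exp(-k t)),

whose two parameters — the maximum binding number ``N_max`` and the
exponential (rate) coefficient ``k`` in s^-1 — are the kinetic features
fed to classification.  Fitting is unweighted nonlinear least squares on
the cumulative counts, initialized from the final count and the time to
63% saturation, with a multi-start fallback over decades of k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .features import SizePartition

DEFAULT_DT = 1.0
#: Default observation window, s (15 min acquisition).
DEFAULT_DURATION = 900.0
MIN_POINTS = 10
MIN_EVENTS = 5


class InsufficientEventsError(ValueError):
    """Raised when a curve holds too few events or points for a kinetic fit."""


@dataclass
class BindingCurve:
    """Cumulative landing count on a uniform time grid for one size group."""

    group: str
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(np.diff(self.counts) < 0) or (len(self.counts) and self.counts[0] < 0):
            raise ValueError("cumulative counts must be non-negative and non-decreasing")

    @property
    def final_count(self) -> int:
        return int(self.counts[-1]) if len(self.counts) else 0


@dataclass
class KineticFit:
    """Fitted saturation parameters for one binding curve."""

    n_max: float
    k: float
    rss: float
    n_events: int
    group: str = ""


def saturating_exponential(t: np.ndarray, n_max: float, k: float) -> np.ndarray:
    return n_max * (1.0 - np.exp(-k * t))


def cumulative_binding_curve(
    events: pd.DataFrame,
    partition: SizePartition,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
) -> list[BindingCurve]:
    """One cumulative curve per size group.

    ``counts[j]`` is the number of sized events with diameter in the
    group and landing time <= j*dt; events outside the partition's range
    are excluded.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if events["diameter_nm"].isna().any():
        raise ValueError("unsized events present; run sizing first")
    grid = np.arange(int(np.floor(duration / dt)) + 1) * dt
    groups = partition.assign_array(events["diameter_nm"].to_numpy())
    curves = []
    for gi, label in enumerate(partition.group_labels()):
        t = np.sort(events.loc[groups == gi, "time_s"].to_numpy(dtype=float))
        counts = np.searchsorted(t, grid, side="right")
        curves.append(BindingCurve(group=label, times=grid, counts=counts))
    return curves


def _jac(t, n_max, k):
    e = np.exp(-k * t)
    return np.column_stack([1.0 - e, n_max * t * e])


def fit_exponential(
    curve: BindingCurve,
    min_points: int = MIN_POINTS,
    min_events: int = MIN_EVENTS,
) -> KineticFit:
    """Nonlinear least squares of N_max*(1-exp(-k t)) to a cumulative curve."""
    t, y = curve.times, curve.counts.astype(float)
    if len(t) < min_points:
        raise InsufficientEventsError(
            f"{curve.group}: {len(t)} time points < {min_points}"
        )
    final = y[-1]
    if final < min_events:
        raise InsufficientEventsError(
            f"{curve.group}: {int(final)} events < {min_events}"
        )
    # k0 from time to 63% saturation; N_max0 from the final count
    i63 = int(np.searchsorted(y, 0.632 * final))
    k0 = 1.0 / t[i63] if 0 < i63 < len(t) and t[i63] > 0 else 1.0 / max(t[-1], 1.0)
    starts = [k0] + [10.0**e for e in (-4, -3, -2, -1)]
    last_err: Exception | None = None
    for ks in starts:
        try:
            popt, _ = optimize.curve_fit(
                saturating_exponential,
                t,
                y,
                p0=(max(final, 1.0), ks),
                jac=_jac,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10_000,
            )
            n_max, k = float(popt[0]), float(popt[1])
            rss = float(np.sum((saturating_exponential(t, n_max, k) - y) ** 2))
            if not (n_max > 0 and k > 0):
                raise RuntimeError("degenerate optimum")
            return KineticFit(n_max=n_max, k=k, rss=rss, n_events=int(final), group=curve.group)
        except RuntimeError as err:  # no convergence from this start
            last_err = err
    raise RuntimeError(f"{curve.group}: kinetic fit did not converge") from last_err


def fit_group_kinetics(
    events: pd.DataFrame,
    partition: SizePartition,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
) -> dict[str, KineticFit | None]:
    """Curves plus fits per group; ``None`` marks groups with too few events."""
    out: dict[str, KineticFit | None] = {}
    for curve in cumulative_binding_curve(events, partition, dt=dt, duration=duration):
        try:
            out[curve.group] = fit_exponential(curve)
        except InsufficientEventsError:
            out[curve.group] = None
    return out
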