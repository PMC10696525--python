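"""Intensity-to-diameter calibration with silica beads.

Interferometric intensity scales with particle polarizability, i.e.
volume times optical contrast, so for beads of one material it follows a
power law I = c * d^b with b close to 3.  Calibration fits that power
law in log-log space on Gaussian-fitted intensity peaks of monodisperse
silica beads (30/50/70/100/160 nm), then inverts it for unknown
particles.  Because EVPs (n ~ 1.40) have lower optical contrast than
silica (n ~ 1.46) in aqueous medium (n ~ 1.33), the same measured
intensity corresponds to a larger EVP; the Clausius-Mossotti contrast
ratio r compensates for this, entering the inversion as
d = (I * r / c)^(1/b).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_N_SILICA = 1.46
DEFAULT_N_EVP = 1.40
DEFAULT_N_MEDIUM = 1.33
#: Minimum bead count per size for a Gaussian peak fit.
DEFAULT_PEAK_FLOOR = 150


def _cm_contrast(n_particle: float, n_medium: float) -> float:
    """Clausius-Mossotti optical contrast (n_p^2 - n_m^2)/(n_p^2 + 2 n_m^2)."""
    return (n_particle**2 - n_medium**2) / (n_particle**2 + 2 * n_medium**2)


def ri_compensation_factor(
    n_silica: float = DEFAULT_N_SILICA,
    n_evp: float = DEFAULT_N_EVP,
    n_medium: float = DEFAULT_N_MEDIUM,
) -> float:
    """Contrast ratio silica/EVP used to correct silica-calibrated sizes."""
    if n_medium <= 0:
        raise ValueError("medium index must be positive")
    evp = _cm_contrast(n_evp, n_medium)
    if evp == 0:
        raise ValueError("EVP contrast is zero (n_evp equals n_medium)")
    return _cm_contrast(n_silica, n_medium) / evp


def fit_intensity_peak(
    intensities, min_count: int = DEFAULT_PEAK_FLOOR
) -> tuple[float, float]:
    """Peak location and width of a bead intensity population.

    Histogram (Freedman-Diaconis bins) fitted with a Gaussian by
    nonlinear least squares; falls back to the sample mean/SD when the
    histogram is degenerate or the fit does not converge.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < min_count:
        raise ValueError(f"need at least {min_count} values, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities")
    mu0, sd0 = float(x.mean()), float(x.std(ddof=1))
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2 * iqr / len(x) ** (1 / 3)
    if width <= 0 or sd0 == 0:
        return mu0, sd0
    n_bins = max(int(np.ceil((x.max() - x.min()) / width)), 5)
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(t, a, mu, sigma):
        return a * np.exp(-((t - mu) ** 2) / (2 * sigma**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=(counts.max(), mu0, sd0), maxfev=5000
        )
        return float(popt[1]), float(abs(popt[2]))
    except (RuntimeError, ValueError):
        return mu0, sd0


@dataclass
class CalibrationModel:
    """Fitted power law I = c * d^b plus the contrast compensation r."""

    b: float
    c: float
    r: float = 1.0
    peak_fits: dict[float, tuple[float, float, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.b <= 0 or self.c <= 0 or self.r <= 0:
            raise ValueError("b, c and r must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "b": self.b,
            "c": self.c,
            "r": self.r,
            "peak_fits": {str(k): list(v) for k, v in self.peak_fits.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            b=payload["b"],
            c=payload["c"],
            r=payload.get("r", 1.0),
            peak_fits={float(k): tuple(v) for k, v in payload.get("peak_fits", {}).items()},
        )


def fit_calibration(sizes, peaks, r: float | None = None) -> CalibrationModel:
    """Least-squares line in (log d, log I) space."""
    d = np.asarray(sizes, dtype=float)
    i = np.asarray(peaks, dtype=float)
    if len(d) != len(i) or len(d) < 2:
        raise ValueError("need matching size/peak lists with >= 2 entries")
    if np.any(d <= 0) or np.any(i <= 0):
        raise ValueError("sizes and peak intensities must be positive")
    if len(np.unique(d)) < 2:
        raise ValueError("degenerate calibration: identical sizes")
    res = stats.linregress(np.log(d), np.log(i))
    if r is None:
        r = ri_compensation_factor()
    return CalibrationModel(b=float(res.slope), c=float(math.exp(res.intercept)), r=r)


def calibrate_from_beads(
    bead_table: pd.DataFrame,
    min_count: int = DEFAULT_PEAK_FLOOR,
    r: float | None = None,
) -> CalibrationModel:
    """Full calibration from a (nominal_diameter_nm, intensity) bead table."""
    sizes, peaks, fits = [], [], {}
    for size, grp in bead_table.groupby("nominal_diameter_nm"):
        mu, sigma = fit_intensity_peak(grp["intensity"].to_numpy(), min_count=min_count)
        sizes.append(size)
        peaks.append(mu)
        fits[float(size)] = (mu, sigma, len(grp))
    model = fit_calibration(sizes, peaks, r=r)
    model.peak_fits = fits
    return model


def intensity_to_diameter(intensity, model: CalibrationModel) -> np.ndarray | float:
    """Invert the calibration: d = (I * r / c)^(1/b).

    For silica input use a model with r = 1; for EVPs the r > 1 contrast
    ratio maps equal intensity to a larger diameter.
    """
    i = np.asarray(intensity, dtype=float)
    if np.any(i <= 0):
        raise ValueError("intensity must be positive")
    d = (i * model.r / model.c) ** (1.0 / model.b)
    return float(d) if np.isscalar(intensity) else d


def apply_sizing(events: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    """Fill the ``diameter_nm`` column of an event table from intensities."""
    out = events.copy()
    out["diameter_nm"] = intensity_to_diameter(out["intensity"].to_numpy(), model)
    return out
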