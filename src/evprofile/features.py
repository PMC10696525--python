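"""Size partitions, marker expression levels and feature-matrix assembly.

A sample is profiled on one capture surface per membrane-protein marker
(CD63, EpCAM, HER2, PSMA, PTK7) plus one positively charged surface that
captures every EVP regardless of markers.  The *expression level* of a
marker is the fraction of marker-captured particles relative to the total
capture count.  Particle diameters in 30-160 nm are grouped by a
:class:`SizePartition`, and each sample becomes one row of a
marker x size-group x quantity feature matrix, where the quantities are
the expression level and the fitted binding-rate constant k (optionally
also the saturation count n_max).

Normalization follows the two-step scheme used throughout the analysis:
per-feature percentile scaling (subtract the 2.5th percentile, divide by
the 97.5th-2.5th percentile range, no clipping) before classification,
and per-row z-scores for heatmap-style displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Working size range of the instrument, nm.
SIZE_LO = 30.0
SIZE_HI = 160.0
#: Sizing resolution of the instrument; base bins are this wide, nm.
BASE_STEP = 10.0

OUT_OF_RANGE = -1


@dataclass(frozen=True)
class SizePartition:
    """Contiguous grouping of the size axis into half-open intervals.

    ``boundaries = (b0, b1, ..., bG)`` defines groups ``[b0,b1), [b1,b2), ...``;
    the last group is closed at its upper edge so the full range endpoint
    belongs to a group.  The standard instrument grid runs 30-160 nm in
    10 nm steps (13 base bins).
    """

    boundaries: tuple[float, ...]

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2:
            raise ValueError("a partition needs at least two boundaries")
        if any(b[i + 1] <= b[i] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be strictly increasing: {b}")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_groups(self) -> int:
        return len(self.boundaries) - 1

    @property
    def edges(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(b[i], b[i + 1]) for i in range(len(b) - 1)]

    def group_labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in self.edges]

    def assign(self, diameter: float) -> int:
        """Group index of ``diameter`` or :data:`OUT_OF_RANGE`.

        Half-open convention: a boundary value belongs to the group it
        opens, except the top edge which closes the last group.
        """
        b = self.boundaries
        if diameter < b[0] or diameter > b[-1]:
            return OUT_OF_RANGE
        if diameter == b[-1]:
            return self.n_groups - 1
        return int(np.searchsorted(b, diameter, side="right")) - 1

    def assign_array(self, diameters: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`assign`."""
        d = np.asarray(diameters, dtype=float)
        b = np.asarray(self.boundaries)
        idx = np.searchsorted(b, d, side="right") - 1
        idx[d == b[-1]] = self.n_groups - 1
        idx[(d < b[0]) | (d > b[-1])] = OUT_OF_RANGE
        return idx

    def to_string(self) -> str:
        return ",".join(self.group_labels())

    @classmethod
    def from_string(cls, text: str) -> "SizePartition":
        """Parse ``"30-70,70-120,120-160"``; segments must tile contiguously."""
        boundaries: list[float] = []
        for seg in text.split(","):
            parts = seg.strip().split("-")
            if len(parts) != 2:
                raise ValueError(f"malformed partition segment {seg!r}")
            lo, hi = float(parts[0]), float(parts[1])
            if hi <= lo:
                raise ValueError(f"empty or inverted segment {seg!r}")
            if boundaries and lo != boundaries[-1]:
                raise ValueError(
                    f"segments must be contiguous: {seg!r} does not start at "
                    f"{boundaries[-1]:g}"
                )
            if not boundaries:
                boundaries.append(lo)
            boundaries.append(hi)
        return cls(tuple(boundaries))

    @classmethod
    def single_group(cls, lo: float = SIZE_LO, hi: float = SIZE_HI) -> "SizePartition":
        """The bulk (no subtyping) partition."""
        return cls((lo, hi))


#: The empirical small/medium/large split (EVP-S, EVP-M, EVP-L).
THREE_BIN = SizePartition((30.0, 70.0, 120.0, 160.0))


def expression_level(positive_count: float, total_count: float) -> float:
    """Marker expression level: marker-captured count over total capture count."""
    if total_count <= 0:
        raise ValueError("total count must be positive")
    if positive_count < 0:
        raise ValueError("counts must be non-negative")
    return positive_count / total_count


def assign_group(diameter: float, partition: SizePartition) -> int:
    """Group index of a diameter under ``partition`` (or OUT_OF_RANGE)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return partition.assign(diameter)


def percentile_normalize(column: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Scale a feature column by its 2.5th/97.5th percentiles.

    Returns ``(x - p2.5) / (p97.5 - p2.5)`` and the percentile pair.
    Percentiles interpolate linearly between order statistics and no
    clipping is applied, so values may fall outside [0, 1].
    """
    x = np.asarray(column, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct values to normalize")
    lo, hi = np.percentile(x, [2.5, 97.5])
    if hi == lo:
        raise ValueError("degenerate column: 2.5th and 97.5th percentiles equal")
    return (x - lo) / (hi - lo), (float(lo), float(hi))


def zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Per-row standardization: subtract the row mean, divide by the row SD (ddof=1)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.where(sd[:, 0] == 0)[0]
        raise ValueError(f"zero-SD rows cannot be z-scored: rows {bad.tolist()}")
    return (m - mu) / sd


@dataclass
class SampleProfile:
    """Per-sample measurements: one value set per marker x size group.

    ``values[(marker, group_label)]`` maps quantity name ->
    value; ``k``/``n_max`` may be absent when a group held too few events
    for a kinetic fit.  ``total_count`` is the capture count on the
    positively charged surface (all sizes pooled).
    """

    sample_id: str
    class_label: str
    markers: tuple[str, ...]
    values: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    total_count: float = 0.0


@dataclass
class FeatureMatrix:
    """Rectangular samples x features block with its normalization record."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    normalization: dict[str, tuple[float, float]]
    dropped_features: list[str] = field(default_factory=list)
    class_labels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


def assemble_features(
    profiles: list[SampleProfile],
    partition: SizePartition,
    quantities: tuple[str, ...] = ("expression", "k"),
    normalize: bool = True,
) -> FeatureMatrix:
    """Build the samples x (marker x group x quantity) matrix.

    Missing cells are imputed: an empty group has expression 0 by
    definition, while a missing kinetic value (``k``/``n_max``) takes the
    column median.  Zero-variance columns are dropped with a warning, and
    the remaining columns are percentile-normalized (2.5/97.5).
    """
    if not profiles:
        raise ValueError("no profiles")
    panel = profiles[0].markers
    for p in profiles:
        if p.markers != panel:
            raise ValueError(
                f"inconsistent marker panels: {p.markers} vs {panel} ({p.sample_id})"
            )
    groups = partition.group_labels()
    names = [f"{m}:{g}:{q}" for m in panel for g in groups for q in quantities]
    raw = np.full((len(profiles), len(names)), np.nan)
    for i, p in enumerate(profiles):
        j = 0
        for m in panel:
            for g in groups:
                cell = p.values.get((m, g), {})
                for q in quantities:
                    raw[i, j] = cell.get(q, np.nan)
                    j += 1

    # imputation: expression -> 0, kinetic quantities -> column median
    for j, name in enumerate(names):
        col = raw[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        if name.endswith(":expression"):
            col[missing] = 0.0
        else:
            med = np.nanmedian(col) if not missing.all() else 0.0
            col[missing] = med

    # a column whose 2.5th/97.5th percentiles coincide (constant, or nearly
    # constant with a few outliers) cannot be percentile-scaled; drop it
    keep, dropped = [], []
    for j, name in enumerate(names):
        lo, hi = np.percentile(raw[:, j], [2.5, 97.5])
        if np.ptp(raw[:, j]) == 0 or (normalize and hi == lo):
            dropped.append(name)
        else:
            keep.append(j)
    if dropped:
        logger.warning(
            "dropping %d zero-variance/degenerate feature(s): %s", len(dropped), dropped
        )
    values = raw[:, keep]
    names = [names[j] for j in keep]

    record: dict[str, tuple[float, float]] = {}
    if normalize:
        for j, name in enumerate(names):
            values[:, j], record[name] = percentile_normalize(values[:, j])

    return FeatureMatrix(
        sample_ids=[p.sample_id for p in profiles],
        feature_names=names,
        values=values,
        normalization=record,
        dropped_features=dropped,
        class_labels=[p.class_label for p in profiles],
    )


def per_bin_expression(
    events: pd.DataFrame,
    total_surface: str = "total",
    lo: float = SIZE_LO,
    hi: float = SIZE_HI,
    step: float = BASE_STEP,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample, per-marker, per-base-bin expression levels.

    Each marker event's diameter falls into one of the ``(hi-lo)/step``
    base bins; the bin count is divided by the sample's overall total
    capture count, so per-group expression for any contiguous grouping is
    the *sum* of its member-bin columns.  Returns the samples x
    (marker, bin) table and the per-sample class labels.
    """
    n_bins = int(round((hi - lo) / step))
    base = SizePartition(tuple(lo + step * i for i in range(n_bins + 1)))
    totals = (
        events[events["surface"] == total_surface]
        .groupby("sample_id", sort=True)
        .size()
    )
    marker_ev = events[events["surface"] != total_surface].copy()
    marker_ev["bin"] = base.assign_array(marker_ev["diameter_nm"].to_numpy())
    marker_ev = marker_ev[marker_ev["bin"] != OUT_OF_RANGE]
    counts = (
        marker_ev.groupby(["sample_id", "surface", "bin"], sort=True)
        .size()
        .unstack(["surface", "bin"], fill_value=0)
    )
    markers = sorted(events.loc[events["surface"] != total_surface, "surface"].unique())
    full_cols = pd.MultiIndex.from_product([markers, range(n_bins)], names=["marker", "bin"])
    counts = counts.reindex(columns=full_cols, fill_value=0)
    counts = counts.reindex(index=totals.index, fill_value=0)
    expr = counts.div(totals, axis=0)
    labels = (
        events.drop_duplicates("sample_id").set_index("sample_id")["class_label"]
    ).reindex(expr.index)
    return expr, labels


def class_mean_zscore_table(
    profiles: list[SampleProfile],
    partition: SizePartition,
    quantity: str = "expression",
) -> pd.DataFrame:
    """Row-z-scored class means per marker x size group (heatmap export).

    Rows are markers x class, columns size groups; each row is z-scored
    across groups to highlight where along the size axis a marker sits.
    """
    groups = partition.group_labels()
    classes = sorted({p.class_label for p in profiles})
    panel = profiles[0].markers
    rows, index = [], []
    for m in panel:
        for c in classes:
            vals = []
            for g in groups:
                xs = [
                    p.values.get((m, g), {}).get(quantity, 0.0)
                    for p in profiles
                    if p.class_label == c
                ]
                vals.append(float(np.mean(xs)) if xs else 0.0)
            rows.append(vals)
            index.append(f"{m}:{c}")
    mat = np.asarray(rows)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0  # flat rows stay flat rather than erroring in a report
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd
    return pd.DataFrame(z, index=index, columns=groups)
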