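"""Synthetic data generators for the single-EVP analysis pipeline.

Everything downstream assumes a common generative picture:

* each capture surface (one aptamer per membrane-protein marker, plus a
  positively charged surface that captures every particle) has a finite
  number of binding sites ``n_max``; each site fills independently with
  an exponential waiting time at rate ``k`` (s^-1), so the expected
  cumulative landing count is the saturating curve
  ``n_max * (1 - exp(-k t))`` and the realized count never exceeds
  ``n_max``;
* particle diameters follow a class-specific truncated-lognormal mixture
  on the 30-160 nm working range, and a marker surface sees that
  distribution reweighted by the marker's size-dependent positivity
  (probability that a particle of diameter d carries the marker);
* measured interferometric intensity scales with the particle volume
  (d^3) times its optical contrast, so EVPs (refractive index ~1.40)
  appear dimmer than same-size silica beads (~1.46) by the
  Clausius-Mossotti contrast ratio.

The module also renders image stacks (a landed particle adds a fixed
point-spread-function pattern to every subsequent frame, on i.i.d.
Gaussian camera noise) so the detection stage can be exercised
end-to-end, and ships a five-class scenario generator that emulates a
four-cancer-plus-healthy-control panel with size-localized marker
signal and batch-to-batch lognormal variation in binding capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .features import BASE_STEP, SIZE_HI, SIZE_LO
from .sizing import (
    DEFAULT_N_EVP,
    DEFAULT_N_MEDIUM,
    DEFAULT_N_SILICA,
    ri_compensation_factor,
)

MARKERS = ("CD63", "EpCAM", "HER2", "PSMA", "PTK7")
TOTAL_SURFACE = "total"
#: Nominal silica calibration bead diameters, nm.
CALIBRATION_SIZES = (30.0, 50.0, 70.0, 100.0, 160.0)
#: Instrument constant relating intensity to d^3 x contrast (a.u. / nm^3).
DEFAULT_INSTRUMENT_C = 1.0

EVENT_COLUMNS = [
    "sample_id",
    "class_label",
    "surface",
    "time_s",
    "x_px",
    "y_px",
    "intensity",
    "diameter_nm",
]


# ---------------------------------------------------------------------------
# size distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeDistribution:
    """Mixture of lognormals truncated to [lo, hi] nm.

    ``medians``/``sigmas`` are per-component lognormal medians (nm) and
    log-scale SDs; ``weights`` are pre-truncation mixture weights.
    """

    medians: tuple[float, ...] = (90.0,)
    sigmas: tuple[float, ...] = (0.35,)
    weights: tuple[float, ...] = (1.0,)
    lo: float = SIZE_LO
    hi: float = SIZE_HI

    def __post_init__(self):
        if not (len(self.medians) == len(self.sigmas) == len(self.weights)):
            raise ValueError("mixture parameter lengths differ")
        if self.hi <= self.lo:
            raise ValueError("empty support")

    def _component(self, i: int) -> stats.rv_continuous:
        return stats.lognorm(s=self.sigmas[i], scale=self.medians[i])

    def bin_masses(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass of each [edges[j], edges[j+1]) bin after truncation."""
        edges = np.asarray(edges, dtype=float)
        mass = np.zeros(len(edges) - 1)
        total = 0.0
        for i, w in enumerate(self.weights):
            c = self._component(i)
            cdf = c.cdf(edges)
            mass += w * np.diff(cdf)
            total += w * (c.cdf(self.hi) - c.cdf(self.lo))
        return mass / total

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n diameters by per-component inverse-CDF sampling on [lo, hi]."""
        w = np.asarray(self.weights, dtype=float)
        trunc = np.array(
            [self._component(i).cdf([self.lo, self.hi]) for i in range(len(w))]
        )
        post = w * (trunc[:, 1] - trunc[:, 0])
        post = post / post.sum()
        comp = rng.choice(len(w), size=n, p=post)
        u = rng.uniform(size=n)
        out = np.empty(n)
        for i in range(len(w)):
            m = comp == i
            if m.any():
                lo_c, hi_c = trunc[i]
                out[m] = self._component(i).ppf(lo_c + u[m] * (hi_c - lo_c))
        return out

    def sample_in_bin(
        self, n: int, lo: float, hi: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw n diameters conditional on falling in [lo, hi)."""
        sub = replace(self, lo=max(lo, self.lo), hi=min(hi, self.hi))
        return sub.sample(n, rng)


# ---------------------------------------------------------------------------
# class / marker specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerSizeProfile:
    """Marker-specific binding kinetics and size-dependent positivity.

    ``positivity`` is either a callable mapping diameter (nm) -> [0, 1]
    or an array of per-base-bin weights on the 10 nm grid (piecewise
    constant).  ``k`` (s^-1) and ``n_max`` (sites) set the saturating
    binding curve on this marker's surface.
    """

    marker: str
    positivity: object  # callable or per-bin array
    k: float
    n_max: float

    def __post_init__(self):
        if self.k < 0 or self.n_max < 0:
            raise ValueError("k and n_max must be non-negative")
        if not callable(self.positivity):
            w = np.asarray(self.positivity, dtype=float)
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError("positivity weights must lie in [0, 1]")
            object.__setattr__(self, "positivity", w)

    def positivity_at(self, d: np.ndarray) -> np.ndarray:
        if callable(self.positivity):
            p = np.asarray(self.positivity(np.asarray(d, dtype=float)), dtype=float)
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("positivity function left [0, 1]")
            return p
        w = self.positivity
        idx = np.clip(((np.asarray(d) - SIZE_LO) // BASE_STEP).astype(int), 0, len(w) - 1)
        return w[idx]


@dataclass(frozen=True)
class ClassSpec:
    """One sample class: size distribution plus per-marker profiles."""

    label: str
    size_dist: SizeDistribution
    profiles: dict[str, MarkerSizeProfile]
    total_n_max: float
    total_k: float

    def __post_init__(self):
        for m, p in self.profiles.items():
            if p.marker != m:
                raise ValueError(f"profile key {m!r} != marker {p.marker!r}")


@dataclass
class GroundTruth:
    """Per-event truth and the generating kinetic parameters of one run."""

    diameters: np.ndarray
    times: np.ndarray
    marker_positive: np.ndarray
    n_max: float
    k: float


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------


def _landing_times(n_max: float, k: float, duration: float, rng) -> np.ndarray:
    """Per-site exponential waiting times truncated at ``duration`` (sorted).

    Expected cumulative count is n_max*(1-exp(-k t)); realized counts are
    Binomial(n_max, 1-exp(-k*duration)) and never exceed n_max.
    """
    n_sites = int(round(n_max))
    if n_sites == 0 or k == 0:
        return np.empty(0)
    t = rng.exponential(1.0 / k, size=n_sites)
    return np.sort(t[t <= duration])


def _sample_conditional_diameters(
    spec: ClassSpec, profile: MarkerSizeProfile, n: int, rng
) -> np.ndarray:
    """Diameters from the class size distribution reweighted by positivity."""
    if n == 0:
        return np.empty(0)
    if callable(profile.positivity):
        # rejection sampling against the positivity envelope
        out = np.empty(n)
        filled = 0
        for _ in range(10_000):
            draw = spec.size_dist.sample(max(n - filled, 64), rng)
            acc = draw[rng.uniform(size=len(draw)) < profile.positivity_at(draw)]
            take = min(len(acc), n - filled)
            out[filled : filled + take] = acc[:take]
            filled += take
            if filled == n:
                return out
        raise RuntimeError("positivity rejection sampling did not converge")
    w = np.asarray(profile.positivity, dtype=float)
    n_bins = len(w)
    edges = SIZE_LO + BASE_STEP * np.arange(n_bins + 1)
    mass = spec.size_dist.bin_masses(edges) * w
    if mass.sum() == 0:
        raise ValueError(f"marker {profile.marker}: positivity removes all mass")
    mass = mass / mass.sum()
    bins = rng.choice(n_bins, size=n, p=mass)
    out = np.empty(n)
    for j in np.unique(bins):
        m = bins == j
        out[m] = spec.size_dist.sample_in_bin(int(m.sum()), edges[j], edges[j + 1], rng)
    return out


def _event_table(
    spec: ClassSpec,
    surface: str,
    times: np.ndarray,
    diameters: np.ndarray,
    rng,
    sample_id: str,
    frame_px: int = 256,
    intensity_cv: float = 0.0,
) -> pd.DataFrame:
    r = ri_compensation_factor(DEFAULT_N_SILICA, DEFAULT_N_EVP, DEFAULT_N_MEDIUM)
    intensity = DEFAULT_INSTRUMENT_C * diameters**3 / r
    if intensity_cv > 0:
        intensity = intensity * (1.0 + intensity_cv * rng.standard_normal(len(times)))
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "class_label": spec.label,
            "surface": surface,
            "time_s": times,
            "x_px": rng.uniform(0, frame_px, len(times)),
            "y_px": rng.uniform(0, frame_px, len(times)),
            "intensity": intensity,
            "diameter_nm": diameters,
        },
        columns=EVENT_COLUMNS,
    )


def simulate_marker_run(
    spec: ClassSpec,
    marker: str,
    duration: float,
    rng_seed,
    sample_id: str = "s0",
    n_max_factor: float = 1.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one sample x one marker surface for ``duration`` seconds.

    ``n_max_factor`` scales the profile's site count (batch-to-batch
    variation hook).  Returns the event table and per-event ground truth.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if marker not in spec.profiles:
        raise KeyError(f"unknown marker {marker!r} for class {spec.label!r}")
    rng = np.random.default_rng(rng_seed)
    prof = spec.profiles[marker]
    n_max = prof.n_max * n_max_factor
    times = _landing_times(n_max, prof.k, duration, rng)
    diam = _sample_conditional_diameters(spec, prof, len(times), rng)
    table = _event_table(spec, marker, times, diam, rng, sample_id)
    truth = GroundTruth(diam, times, np.ones(len(times), bool), n_max, prof.k)
    return table, truth


def simulate_total_run(
    spec: ClassSpec,
    duration: float,
    rng_seed,
    sample_id: str = "s0",
    n_max_factor: float = 1.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the positively charged (total-count) surface: every EVP binds."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(rng_seed)
    n_max = spec.total_n_max * n_max_factor
    times = _landing_times(n_max, spec.total_k, duration, rng)
    diam = spec.size_dist.sample(len(times), rng)
    table = _event_table(spec, TOTAL_SURFACE, times, diam, rng, sample_id)
    truth = GroundTruth(diam, times, np.ones(len(times), bool), n_max, spec.total_k)
    return table, truth


def simulate_calibration_run(
    diameters=CALIBRATION_SIZES,
    n_per_size: int = 200,
    cv: float = 0.05,
    rng_seed=0,
    c: float = DEFAULT_INSTRUMENT_C,
) -> pd.DataFrame:
    """Silica-bead calibration run: intensity = c * d^3 * (1 + eps), eps ~ N(0, cv^2)."""
    if n_per_size < 1:
        raise ValueError("n_per_size must be >= 1")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    d = np.asarray(diameters, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for size in d:
        eps = cv * rng.standard_normal(n_per_size) if cv > 0 else np.zeros(n_per_size)
        rows.append(
            pd.DataFrame(
                {"nominal_diameter_nm": size, "intensity": c * size**3 * (1.0 + eps)}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def airy_psf(size: int = 15, first_zero_px: float = 4.0) -> np.ndarray:
    """Synthetic Airy-pattern kernel, odd side length, unit peak."""
    if size % 2 == 0:
        raise ValueError("psf side length must be odd")
    c = size // 2
    yy, xx = np.mgrid[-c : c + 1, -c : c + 1]
    r = np.hypot(xx, yy) * (3.8317 / first_zero_px)  # scale to first Bessel zero
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(r == 0, 1.0, 2.0 * special.j1(r) / np.where(r == 0, 1.0, r))
    return (amp**2) / (amp**2).max()


def render_image_stack(
    events: pd.DataFrame,
    frame_shape: tuple[int, int],
    fps: float,
    psf: np.ndarray,
    noise_sd: float,
    rng_seed,
    n_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a raw frame stack: each event adds ``psf * intensity``
    permanently from its landing frame ``floor(time * fps)`` onward, over
    i.i.d. Gaussian background noise.

    Returns ``(stack, landing_frames)``.
    """
    psf = np.asarray(psf, dtype=float)
    if not np.isclose(psf.max(), 1.0):
        raise ValueError("psf must be normalized to unit peak")
    h, w = frame_shape
    times = events["time_s"].to_numpy(dtype=float)
    if n_frames is None:
        n_frames = int(np.ceil((times.max() if len(times) else 0.0) * fps)) + 20
    landing = np.floor(times * fps).astype(int)
    if np.any(landing >= n_frames):
        raise ValueError("event times exceed the stack duration")
    rng = np.random.default_rng(rng_seed)
    stack = (
        rng.normal(0.0, noise_sd, size=(n_frames, h, w))
        if noise_sd > 0
        else np.zeros((n_frames, h, w))
    )
    kh, kw = psf.shape
    ch, cw = kh // 2, kw // 2
    rows = np.round(events["y_px"].to_numpy(dtype=float)).astype(int)
    cols = np.round(events["x_px"].to_numpy(dtype=float)).astype(int)
    if np.any((rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)):
        raise ValueError("event positions outside the field of view")
    amps = events["intensity"].to_numpy(dtype=float)
    for f, r0, c0, a in zip(landing, rows, cols, amps):
        r_lo, r_hi = max(r0 - ch, 0), min(r0 + ch + 1, h)
        c_lo, c_hi = max(c0 - cw, 0), min(c0 + cw + 1, w)
        patch = psf[r_lo - r0 + ch : r_hi - r0 + ch, c_lo - c0 + cw : c_hi - c0 + cw]
        stack[f:, r_lo:r_hi, c_lo:c_hi] += a * patch
    return stack, landing


# ---------------------------------------------------------------------------
# five-class scenario
# ---------------------------------------------------------------------------

#: Default per-marker rate constants (s^-1), shared across classes so that
#: class identity lives in *where along the size axis* markers sit, not in
#: the kinetics; values sit in the experimentally observed 1e-3..1e-2 range.
DEFAULT_MARKER_K = {
    "CD63": 0.0028,
    "EpCAM": 0.0045,
    "HER2": 0.0060,
    "PSMA": 0.0070,
    "PTK7": 0.0052,
}
DEFAULT_MARKER_N_MAX = 400.0
HEALTHY_N_MAX = 60.0
DEFAULT_TOTAL_N_MAX = 2000.0
DEFAULT_TOTAL_K = 0.0050
#: Log-scale SD of the per-run lognormal batch factor on n_max.
DEFAULT_BATCH_SIGMA = 0.15

_S = slice(0, 4)  # 30-70 nm base bins
_M = slice(4, 9)  # 70-120 nm
_L = slice(9, 13)  # 120-160 nm


def _weights_for_conditional(q: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Per-bin positivity weights giving conditional bin distribution ``q``.

    The conditional probability of bin j is w_j*m_j / sum(w*m); choosing
    w_j = q_j/m_j (rescaled to a 0.95 ceiling) realizes any target q
    supported where the size distribution has mass.
    """
    w = np.where(masses > 0, q / np.maximum(masses, 1e-12), 0.0)
    if w.max() == 0:
        raise ValueError("target conditional has no mass")
    return 0.95 * w / w.max()


def _conditional(masses: np.ndarray, s: float, m: float, l: float, l_split=None):
    """Target conditional over the 13 bins with S/M/L masses s, m, l.

    Within S and M the mass follows the size distribution; within L it
    follows ``l_split`` = (share of 120-140, share of 140-160), spread
    mass-proportionally inside each half, or the size distribution when
    ``l_split`` is None.
    """
    q = np.zeros(13)
    for sl, tot in ((_S, s), (_M, m)):
        sub = masses[sl]
        q[sl] = tot * sub / sub.sum()
    subL = masses[_L]
    if l_split is None:
        q[_L] = l * subL / subL.sum()
    else:
        lo_share, hi_share = l_split
        lo_m, hi_m = masses[9:11], masses[11:13]
        q[9:11] = l * lo_share * lo_m / lo_m.sum()
        q[11:13] = l * hi_share * hi_m / hi_m.sum()
    return q


def default_class_specs(
    markers: tuple[str, ...] = MARKERS,
    size_dist: SizeDistribution | None = None,
) -> dict[str, ClassSpec]:
    """The five default classes.

    ``lung`` mimics an A549-like line: its EpCAM and CD63 positives
    concentrate below 70 nm while the remaining markers enrich above
    120 nm.  ``liver``, ``breast`` and ``prostate`` enrich *all* markers
    above 120 nm with identical small/medium/large proportions — liver
    spreads them across 120-160 nm, breast concentrates 120-140 nm and
    prostate 140-160 nm, so the three are only separable once the
    120-160 nm range is split.  ``healthy`` has uniformly low positivity
    (site counts ~15% of the cancer classes).
    """
    sd = size_dist or SizeDistribution()
    edges = SIZE_LO + BASE_STEP * np.arange(14)
    masses = sd.bin_masses(edges)

    small_heavy = _weights_for_conditional(_conditional(masses, 0.80, 0.15, 0.05), masses)
    large_flat = _weights_for_conditional(_conditional(masses, 0.10, 0.20, 0.70), masses)
    large_lo = _weights_for_conditional(
        _conditional(masses, 0.10, 0.20, 0.70, l_split=(0.90, 0.10)), masses
    )
    large_hi = _weights_for_conditional(
        _conditional(masses, 0.10, 0.20, 0.70, l_split=(0.10, 0.90)), masses
    )
    flat = np.full(13, 0.5)  # size-uniform positivity; low capacity via n_max

    def prof(m, w, n_max=DEFAULT_MARKER_N_MAX):
        return MarkerSizeProfile(m, w, DEFAULT_MARKER_K[m], n_max)

    def spec(label, weight_of):
        return ClassSpec(
            label=label,
            size_dist=sd,
            profiles={m: weight_of(m) for m in markers},
            total_n_max=DEFAULT_TOTAL_N_MAX,
            total_k=DEFAULT_TOTAL_K,
        )

    return {
        "lung": spec(
            "lung",
            lambda m: prof(m, small_heavy if m in ("EpCAM", "CD63") else large_flat),
        ),
        "liver": spec("liver", lambda m: prof(m, large_flat)),
        "breast": spec("breast", lambda m: prof(m, large_lo)),
        "prostate": spec("prostate", lambda m: prof(m, large_hi)),
        "healthy": spec("healthy", lambda m: prof(m, flat, n_max=HEALTHY_N_MAX)),
    }


@dataclass
class ScenarioDataset:
    """A labelled multi-sample dataset plus full generative ground truth."""

    events: pd.DataFrame
    samples: pd.DataFrame  # sample_id, class_label
    truth: dict[tuple[str, str], GroundTruth] = field(default_factory=dict)
    class_specs: dict[str, ClassSpec] = field(default_factory=dict)
    seed: int | None = None

    @property
    def labels(self) -> pd.Series:
        return self.samples.set_index("sample_id")["class_label"]


def default_five_class_scenario(
    rng_seed,
    n_replicates: int = 20,
    duration: float = 900.0,
    batch_sigma: float = DEFAULT_BATCH_SIGMA,
    class_specs: dict[str, ClassSpec] | None = None,
) -> ScenarioDataset:
    """Simulate the full five-class x five-marker experiment.

    Each sample contributes six runs (five marker surfaces + the total
    surface).  A lognormal factor exp(N(0, batch_sigma^2)) multiplies
    n_max independently per run, emulating batch-to-batch heterogeneity.
    """
    specs = class_specs or default_class_specs()
    ss = np.random.SeedSequence(rng_seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    tables, truth, sample_rows = [], {}, []
    for label, spec in specs.items():
        for rep in range(n_replicates):
            sid = f"{label}_{rep:02d}"
            sample_rows.append({"sample_id": sid, "class_label": label})
            run_seeds = ss.spawn(len(MARKERS) + 1)
            for marker, seed in zip(MARKERS, run_seeds[:-1]):
                factor = float(np.exp(batch_sigma * master.standard_normal()))
                tab, gt = simulate_marker_run(
                    spec, marker, duration, seed, sample_id=sid, n_max_factor=factor
                )
                tables.append(tab)
                truth[(sid, marker)] = gt
            factor = float(np.exp(batch_sigma * master.standard_normal()))
            tab, gt = simulate_total_run(
                spec, duration, run_seeds[-1], sample_id=sid, n_max_factor=factor
            )
            tables.append(tab)
            truth[(sid, TOTAL_SURFACE)] = gt
    events = pd.concat(tables, ignore_index=True)
    return ScenarioDataset(
        events=events,
        samples=pd.DataFrame(sample_rows),
        truth=truth,
        class_specs=specs,
        seed=rng_seed if isinstance(rng_seed, int) else None,
    )
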