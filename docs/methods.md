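# Methods

## Landing-event model

Binding of particles to a capture surface is modelled with a finite
number of sites `n_max`, each filling independently after an
exponential waiting time with rate `k` (s⁻¹).  The expected cumulative
count is the Langmuir saturation curve `n_max·(1 − e^{−kt})` and the
realized count is Binomial(`n_max`, `1 − e^{−kT}`), so it never exceeds
`n_max`.  This per-site construction is equivalent in expectation to a
nonhomogeneous Poisson process with intensity `n_max·k·e^{−kt}` but, by
keeping counts bounded by the site number, it is internally consistent
with the saturating fit it is meant to exercise.  Dissociation,
mass-transport limitation and multi-state binding are deliberately out
of scope: the fit has exactly the two parameters the analysis consumes.

The kinetic fit is unweighted nonlinear least squares on the cumulative
counts (initialized from the final count and the time to 63%
saturation, with a multi-start fallback across rate decades).
Cumulative counts are serially correlated, so the residuals are not
independent; an unweighted fit is nevertheless consistent and is what
digital-counting practice uses.  On noise-free model curves the
recovery of (`n_max`, `k`) is exact (tested across `k` from 1e-4 to
1e-1 s⁻¹ whenever the observation window covers at least two rate
constants), and on simulated runs with `n_max = 500` and a 900 s window
the mean fitted rate lands within a few percent of truth; the residual
small-sample bias shrinks as `n_max` grows.  Defaults: observation
window 900 s, grid 1 s, at least 10 time points and 5 events per fit.

## Optical model and sizing

Scattering intensity is proportional to particle volume times optical
contrast: calibration beads generate `I = c·d³(1+ε)`, `ε ~ N(0, cv²)`.
The calibration fits `log I` on `log d` (so the exponent `b` is
estimated rather than pinned at 3, absorbing instrument deviations from
the ideal cubic law) on Gaussian peak positions of per-size intensity
histograms (Freedman–Diaconis binning, moment fallback for degenerate
histograms, minimum 150 beads per size).  Inversion applies the
Clausius–Mossotti contrast ratio `r` of silica over EVP material;
defaults n_silica = 1.46, n_EVP = 1.40, n_medium = 1.33 are standard
literature values and `r` can be overridden wholesale when a measured
compensation factor is available.  Sizing is reported at 1 nm
resolution; the analysis consumes only 10 nm bins.

## Detection

The moving average (n = 10 frames) and adjacent-frame differentials
turn a permanent landing at raw frame `f` into a constant-amplitude
(`I/n`) signature in exactly the differentials `f−n … f−1`.  Detection
per differential uses `skimage.feature.peak_local_max` above
`threshold_sigma` (default 5) times a MAD-based background SD, with
`min_separation_px` (default 5) non-maximum suppression.  Recurrent
detections at one position are merged and the landing frame is
recovered from the run midpoint (`round((first+last+n+1)/2)`), which is
exact when the full run is detected.  Because a genuine landing recurs
over `n` differentials while a noise exceedance is single-frame,
candidates must persist for at least 2 consecutive differentials
(`min_persistence`); this suppresses the ~2 expected 5σ pixel
exceedances per 100 differential frames of 256² px to a negligible
rate while leaving recall at moderate SNR untouched.  Only
positive-going differentials are considered by default (landed
particles persist); a flag counts dissociations from the negative ones.
Wiener deconvolution uses the plain regularized inverse filter
`F⁻¹[F(I)·conj(F(psf)) / (|F(psf)|² + ε)]` with `ε` defaulting to 1e-3
of the OTF power peak — adequate for localization; amplitude-faithful
round trips require a smaller `ε`, which the function accepts.

## Feature assembly and classification

Expression level is the marker-surface count divided by the
total-surface (positive-charge) count.  Per size group the denominator
is the group-resolved total count when that group is non-empty, falling
back to the overall total (a flag selects overall-total denominators
throughout; both variants exist because group-resolved totals are the
natural normalization but are noisier for sparse groups).  Missing
cells are imputed — expression 0 for empty groups (a true zero count),
`k`/`n_max` by the column median (no kinetic information).  Columns
that are constant, or equal at their 2.5th and 97.5th percentiles
(e.g. >97.5% zeros), cannot be percentile-scaled and are dropped with a
warning.  Percentile scaling subtracts the 2.5th percentile and divides
by the 2.5–97.5 range without clipping.  Row z-scores (ddof = 1) are
provided for heatmap-style class × size-group summaries.

LDA uses class means with a pooled within-class covariance shrunk
toward `(trace/F)·I` with a Ledoit–Wolf intensity computed from the
pooled residuals — required because feature counts (up to
5 markers × 13 groups × 2 quantities) approach the sample count.  Class
priors are equal by default since class sizes are design artifacts.
Prediction ties break toward the lowest class index.  The numpy
implementation is cross-checked against scikit-learn's lsqr/shrinkage
LDA in the test suite; it exists because the partition search evaluates
thousands of cross-validated fits and the plain linear-algebra path
keeps the exhaustive oracle cheap.  Reports aggregate out-of-fold
predictions: overall accuracy, per-true-class prediction frequencies
(the probability matrix), and one-vs-rest AUCs computed as Mann–Whitney
rank concordance of out-of-fold posterior probabilities (ties count ½).
Default evaluation is leave-one-out (deterministic, suits small n);
stratified 5-fold with a fixed seed is used inside the optimizer so all
partitions are compared on identical folds.

## Partition search

The 13 base bins give 2¹² = 4096 contiguous partitions, encoded by
which internal boundaries are kept.  Random starts keep each boundary
with probability ½; the move set toggles one boundary (merge or split),
whose graph is connected and involutive.  Hill climbing is steepest
ascent accepting only strict improvements; ties among equally improving
neighbours prefer fewer groups, then lexicographically smaller
boundaries, making runs deterministic given the seed.  Objective values
are memoized so no partition is evaluated twice.  Exhaustive
enumeration (guarded at 2¹⁹) provides the global optimum with the same
tie-breaking, independent of evaluation order.

The search objective uses expression-only features with overall-total
denominators: per-group expression is then the sum of member-bin
expressions, so the whole landscape derives from one precomputed
samples × markers × 13 matrix via cumulative sums.  Fitted `k` is
excluded from the objective because, under the generative model,
landing times are independent of diameters — every size group of a run
shares the same expected rate, so per-group `k` adds no size
information while costing a curve fit per sample × marker × group ×
partition.  Final evaluations of any chosen partition use the full
expression + `k` feature set, so bulk, fixed and optimized partitions
are compared on identical footing.

## Synthetic scenario

The default five-class scenario emulates a four-cancer plus
healthy-control panel measured on five aptamer surfaces and one
positive-charge surface, 20 replicates per class, 900 s runs:

* **Size distribution**: lognormal, median 90 nm, log-SD 0.35,
  truncated to 30–160 nm, shared by all classes (no printed source
  values exist; these produce the typical right-skewed nanoparticle
  tracking profile).
* **Kinetics**: per-marker rates between 0.0028 and 0.0070 s⁻¹ (the
  experimentally observed order of magnitude), identical across
  classes; marker site count 400 for all cancer classes, 60 for the
  healthy class; total surface 2000 sites at 0.0050 s⁻¹.
* **Positivity**: piecewise-constant per 10 nm bin, constructed from
  target conditional size distributions (weights `q_j/m_j` rescaled to
  a 0.95 ceiling, where `m_j` are the size-distribution bin masses), so
  arbitrary size localizations are realizable exactly.  The lung-like
  class carries EpCAM/CD63 at 80% below 70 nm; its other markers, and
  all markers of the liver/breast/prostate-like classes, sit at 70%
  above 120 nm with identical small/medium/large proportions
  (0.10/0.20/0.70).  Liver spreads the 120–160 nm mass naturally,
  breast concentrates 90% of it in 120–140 nm and prostate 90% in
  140–160 nm.  The healthy class has flat positivity.
* **Batch noise**: an independent lognormal factor (log-SD 0.15)
  multiplies `n_max` per run.

This geometry makes the information content size-localized by
construction: bulk features are class-identical for the four cancers
(healthy separates on level alone, putting bulk accuracy near
(20 + 80/4)/100 = 40%), the three-bin split adds the lung-like class
(~60–70%), and only partitions cutting inside 120–160 nm resolve the
remaining three (>95%).  The generator reproduces the *mechanism* the
analysis exploits — marker-size correlation — not any laboratory's
numbers, so passing tests demonstrate that the pipeline recovers
size-localized signal when present, not that it reproduces clinical
accuracies.  Real data differ in ways the generator does not emulate:
overlapping and class-specific size distributions, correlated batch
effects across surfaces, intensity-dependent sizing noise, free-protein
background, and far messier positivity landscapes.

Image rendering adds `psf × intensity` permanently from the landing
frame onward over i.i.d. Gaussian camera noise, with a synthetic
Airy-pattern kernel by default (a measured PSF image may be supplied);
drift, flicker and shot-noise statistics are not modelled.

## Numerical choices and limitations

* Size groups are half-open `[lo, hi)` with the top group closed at
  160 nm, so boundary diameters belong to the group they open.
* Percentiles interpolate linearly between order statistics
  (`numpy.percentile` default).
* The Wiener ε, detection thresholds, and fit floors are exposed
  parameters; defaults are stated above.
* Problem sizes in the test suite (20 replicates per class, 900 s
  windows, 20-dataset oracle comparisons, 4096-partition enumerations)
  were chosen as the smallest sizes at which the statistical claims
  are stable.
* Hill climbing is a local search: with 10 restarts it matched the
  exhaustive optimum on 19 of 20 default-scenario datasets; a restart
  budget, iteration cap and target-accuracy stop are all configurable.
  An optional held-out split guards against the optimizer overfitting
  the CV folds, a risk inherent to selecting the partition on the same
  samples used to score it.
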