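# evprofile

Size-resolved membrane-protein profiling of single extracellular vesicles
and particles (EVPs), for researchers working on liquid-biopsy cancer
classification with interferometric single-particle imaging.

Bulk measurements of EVP membrane-protein markers average over a highly
heterogeneous population: a marker may be carried almost exclusively by
vesicles in a narrow size range, and pooling all sizes buries that signal
under the dominant subpopulations.  `evprofile` implements the full
single-particle alternative: detect individual particle landings in an
interferometric image stack, size each particle from its scattering
intensity, build size-resolved binding kinetics per marker surface, and
classify sample origin from the resulting marker × size-group feature
matrix — including an automatic search for the size grouping that
maximizes classification accuracy.

## The model

**Detection.** Raw frames are smoothed by a 10-frame moving average;
differences of adjacent averaged frames cancel the static background, so
a particle landing at frame *f* appears in the `n` differentials
`f−n … f−1`.  Landings are local maxima above 5× the robust (MAD-based)
background SD, optionally after Wiener deconvolution with a
bead-derived point-spread function; the particle intensity is the mean
of the 3×3 pixels around the brightest pixel.

**Sizing.** Interferometric intensity scales with particle
polarizability, `I = c·d^b` with `b ≈ 3`.  The power law is fitted in
log-log space to Gaussian-fitted intensity peaks of silica beads
(30/50/70/100/160 nm) and inverted as `d = (I·r/c)^(1/b)`, where
`r = [(n_s²−n_m²)/(n_s²+2n_m²)] / [(n_e²−n_m²)/(n_e²+2n_m²)]` is the
Clausius–Mossotti contrast ratio compensating the lower refractive index
of EVPs (n_e ≈ 1.40) relative to silica (n_s ≈ 1.46) in buffer
(n_m ≈ 1.33).

**Kinetics.** Cumulative landing counts per size group follow the
Langmuir saturation form `N(t) = N_max·(1 − e^{−kt})`; nonlinear least
squares recovers the maximum binding number `N_max` and the rate
constant `k` (s⁻¹).

**Features and classification.** For each sample, each marker surface
(CD63, EpCAM, HER2, PSMA, PTK7 aptamers) and each size group, the
expression level (marker count / total count on a positively charged
surface) and `k` form the feature matrix.  Columns are percentile-scaled
(`(x − p2.5)/(p97.5 − p2.5)`, no clipping) and classified with LDA
(pooled within-class covariance, Ledoit–Wolf-type shrinkage, equal
priors), evaluated by leave-one-out or stratified k-fold CV with a
probability matrix and one-vs-rest Mann–Whitney AUCs.

**Partition search.** The 30–160 nm range splits into 13 base bins of
10 nm; the 2¹² contiguous groupings are searched by steepest-ascent hill
climbing over single-boundary toggles (random restarts, memoized
objective), with exhaustive enumeration available as an oracle.

Because no raw instrument data are publicly deposited, the package ships
a first-class synthetic generator (`evprofile.synth`) that emulates the
experiment — class-specific size distributions, size-dependent marker
positivity, saturating binding with bounded site counts, batch noise,
and rendered image stacks with ground truth — so every stage is testable
end-to-end.

## Worked example

```python
from evprofile import pipeline

result = pipeline.run_all(pipeline.RunConfig(seed=7))
print(result)
```

prints (exact numbers are seed-dependent):

```
{'config_digest': 'd25a30c0b0b6', 'seed': 7,
 'bulk_accuracy': 0.39,
 'three_bin_accuracy': 0.69,
 'optimized_accuracy': 0.99,
 'optimized_partition': '30-40,40-50,50-80,80-140,140-160',
 'search_evaluations': 174}
```

The run simulates 100 samples (5 classes × 20 replicates, five marker
surfaces plus a total-count surface each) and classifies them three
ways.  Treating all sizes as one group (`bulk_accuracy` 0.39) only the
healthy controls separate — the four cancer classes share identical
overall marker levels by construction.  The empirical small/medium/large
split at 30/70/120/160 nm (`three_bin_accuracy` 0.69) additionally
resolves the lung-like class, whose EpCAM/CD63 signal sits below 70 nm.
The hill-climbed partition (`optimized_accuracy` 0.99) also splits the
120–160 nm range, where the remaining three classes hide their
differences.  The same progression is available from a shell via
`evprofile run-all --seed 7 --out results/`.

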