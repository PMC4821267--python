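# Methods

## Measurement model and preprocessing

A sighting pairs a visual total-length estimate (consensus of several
observers against a 2 m reference, recorded on a 0.5 m grid) with a
stereo-video measurement of the same shark. Stereo-video is treated as the
reference method: its calibration is accepted when targets of known length
(1, 3, 5 m) are measured within a relative tolerance (default 2%,
consistent with the ~1% absolute error such systems achieve on well-defined
targets), and individual measurements are retained when the software's
reported precision is at most 5% of the measured length. The boundary is
inclusive (precision exactly 5% of length is kept) — the permissive reading
of "a precision of 5%" — and configurable.

Repeat sightings of the same individual within the same year share one
reference length: the arithmetic mean of that individual-year's stereo
measurements (TLN). Repeats across different years are *not* collapsed,
since the animal may have grown. Stereo measurements of one individual-year
are expected to agree within 5% relative spread; a violation warns but
still averages, because a hard drop would silently change the sample size.
Every visual estimate is kept as its own row. The analysis response is the
absolute error `diff = |visual − TLN|`; the signed error (TLN − visual,
positive = underestimation) is carried alongside for diagnostics, since the
absolute definition conflates under- and over-estimation (about 10% of field
sightings are over-estimates). Visual estimates are stored at face value;
the 0.5 m resolution is a property of the data-generating process, not a
constraint enforced on input. Whether the precision filter runs before or
after repeat-averaging is not determined by the source analysis; the
pipeline filters first (configurable).

## Bias model

Candidate models for `diff` are Gaussian random-intercept mixed models

    diff_ij = x_ij' beta + b_i + eps_ij,
    b_i ~ N(0, sigma2_id),   eps_ij ~ N(0, sigma2_eps),

with fixed effects drawn from {TLN, time of day, field-day index, previous
visual estimate} — the default set crosses TLN with the nuisance covariates
plus an intercept-only null — after a Spearman collinearity screen
(default flag at |rho| ≥ 0.7, the conventional cut; pairs with a constant
member are reported as undefined rather than guessed).

**Fitting.** For a single random intercept the covariance is
`sigma2_eps (I + theta Z Z')` with `theta = sigma2_id/sigma2_eps`. For
fixed theta, GLS gives the fixed effects and the profiled residual variance
in closed form (per-group Woodbury identity, O(n) per evaluation), leaving
a one-dimensional profiled (restricted) likelihood in theta. That profile
is maximised by a deterministic bounded search on log(theta) over
[e⁻¹⁴, e¹⁴] (absolute tolerance 1e-10), always compared against the
theta = 0 boundary so a zero variance component is representable exactly.
No random initialisation anywhere; results are seed-free. The ML variant
matches statsmodels' MixedLM to ~1e-6 in the test suite, and REML matches
the closed-form ANOVA estimators on balanced one-way designs.

**Ranking.** Models differing in fixed effects are compared under ML
(REML likelihoods are not comparable across fixed-effect structures; REML
remains available). The parameter count is k = (#fixed coefficients,
intercept included) + 2 variance parameters, and n in AICc is the number of
observations (sightings), not individuals. All candidates are fitted on the
same rows: any row missing a variable used by *any* model in the set is
dropped globally — chiefly first-of-day rows, which have no previous visual
estimate. Weights are `exp(−Δ/2)` normalised within the set. Goodness of
fit uses the variance-partition (Nakagawa) R² with the fixed-effect
variance computed as the population variance of the fitted fixed predictor
over the rows used.

The simple bias trend (the figure-style regression) is OLS of diff on TLN,
with R² the squared Pearson correlation.

## Bootstrap procedures

Both procedures are ordinary nonparametric bootstraps with resample size
equal to the original size, 10,000 iterations by default, one seeded
generator per result (seed recorded in the output):

* difference of means — each iteration independently resamples each
  method's sample with replacement and records mean(stereo*) − mean(visual*),
  so positive values mean visual underestimation;
* bootstrap SE — the standard deviation of resampled means of one sample;
  it converges to the plug-in value `sqrt((n−1)/n)·s/√n`.

Percentile intervals use the nearest-order-statistic (inverse empirical
CDF) rule, so endpoints are always order statistics of the draws;
interpolation rules are deliberately out of scope. When only published
summary statistics are available, `normal_sample_with_moments` builds a
normal-shaped sample affinely rescaled to the exact published sample mean
and sd (ddof = 1), which pins the bootstrap distribution's centre and scale
and leaves only Monte-Carlo noise in the endpoints.

## Demography

Size-class histograms use edges (3, 5, 7, 9) m with the first class closed
above at 3 m, the last closed below at 9 m and interior classes
left-closed; the convention string is embedded in every histogram object
because the class-boundary prose in survey reports is often internally
inconsistent. Maturity is assessed per individual (not per sighting):
counts strictly above the near-maturity threshold (default 8 m) and the L50
(default 9 m) are converted to whole-percent proportions (half-up rounding)
*before* multiplying by the population bounds (default 300–500) — rounding
first is the arithmetic that makes 6/95 and 20/95 map onto 18–30 and
63–105 individuals — and the sampling fraction is n over each population
bound, as whole percents.

## Literature table

The packaged CSV transcribes the published worldwide summary of
aggregation length records: 32 rows over 23 site names. Means that are
only range midpoints or were read off size-frequency graphs carry an
explicit `mean_method` flag; measurement techniques (visual,
photogrammetry, aerial-vehicle comparison, vertebral rings, unspecified)
are flag columns so photogrammetry-based rows are distinguishable. Two rows
print means outside their own printed ranges and one prints a
"mean of range" that is not the midpoint; all are transcribed as printed
and annotated in the `notes` column rather than corrected. Each record's
statistics are assigned to the last year of the study period; summaries are
keyed by (location, report year), and no cross-year trend model is fitted.

## Synthetic surveys

The generator emulates the retained survey sample: 95 individuals, 123
sightings (extras allocated in uniform without-replacement rounds, so no
unsupported resight distribution is asserted; each individual keeps one
year so within-year collapsing is well defined). True lengths are truncated
normal — the simplest shape matching the published mean 6.128 m, sd
1.609 m and range 3.5–11 m; stereo measurements add 1% multiplicative
noise; the observer's underestimation is
`d = −1.6429 + 0.4509·true + b_i + eps`, floored at 0, and the visual
estimate is the stereo length minus d, rounded to 0.5 m and floored at one
step (small sharks never acquire non-positive estimates). Sex is drawn per
individual from 65:11:19 M:F:U; sightings are laid on a 10-day-per-year
encounter calendar in a 10:00–16:00 survey window, which defines day, time
and the previous-visual covariate.

Two calibrations are the package's own choices, since no published values
exist:

* **Variance components** sigma2_id = 0.306, sigma2_eps = 0.386 m² are
  derived so the generating variance partition (with the slope acting on
  the configured spread, 0.4509²·1.609² ≈ 0.527 m²) yields Rm²/Rc² near
  0.43/0.68, the structure the bias model is meant to recover.
* **Stereo precision values** have no published distribution; they are a
  stand-in drawn right-skewed (Beta(1,3)) over 1–6% of the measurement so
  the large majority of records pass the 5% QC rule, as the retained field
  sample did by construction. The manifest flags this explicitly.

What the generator does *not* emulate: photo-identification errors, sighting
detectability, observer heterogeneity beyond the shared bias line, growth
between years, or any spatial structure. Passing tests therefore show the
pipeline recovers the assumed error structure at the survey's scale, not
that real surveys satisfy those assumptions.

Two quantitative consequences of the flooring rule are worth knowing: the
recoverable OLS slope at large n is attenuated to ≈ 0.39 (still within the
±0.1 recovery band the tests check at 500 individuals), and the realised
Rm²/Rc² at n = 1000 sit near 0.36/0.60. Both are properties of the
generating process, not estimation error.

## Problem sizes and numerical choices

The test suite runs the generator at survey scale (95/123) for pipeline
checks, 500 individuals × 50 seeds for slope recovery, 20 survey-scale
replicates for model identification, and a single 1000-individual run for
the variance partition; bootstrap checks use the full 10,000 iterations.
Mixed-model correctness is checked against a dense-matrix 200-point
grid-search oracle on bundled ≤ 30-row datasets and against statsmodels on
ML fits. Degenerate inputs are defined behaviour: a constant response fits
at the variance boundary; all-singleton grouping raises (variance
components unidentifiable); constant predictors make rank correlations
undefined rather than zero.

## Limitations

* The absolute-vs-signed error ambiguity is resolved by computing both, not
  by guessing the original intent.
* Random slopes, crossed random effects and non-Gaussian responses are out
  of scope, as are BCa/studentised intervals.
* Exact reproduction of the original study's printed means, model weights
  and bias-line coefficients requires the original paired sample, which has
  no public accession; those checks activate only when that file is
  supplied locally.
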