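# Methods

## Signal model and estimation

Multi-echo gradient-echo magnitude signal in iron-loaded tissue is modelled
as a mono-exponential decay

    y(TE) = K · exp(−TE / T2*)

with amplitude `K` (arbitrary units) and effective transverse relaxation
time `T2*` (ms). Tissue iron shortens T2*, so lower T2* means more iron.
The model assumes a single tissue compartment per ROI/pixel, no fat–water
modulation, and magnitude (non-negative) data.

`MonoExponentialDecayModel.fit()` estimates `(K, T2*)` by unweighted
nonlinear least squares on the signal scale (`scipy.optimize.curve_fit`),
initialised from an ordinary least-squares line fit of `ln y` against TE
over the strictly positive signals. The log fit alone would over-weight the
low-signal late echoes, so it only seeds the optimizer; non-positive
signals are excluded from the initialisation but retained in the nonlinear
fit. If the log-linear slope is non-negative the series does not decay and
a `DegenerateFitError` is raised; if the optimizer fails to converge the
log-linear estimate is returned with `converged=False` (logged, never
silent). Goodness of fit is the coefficient of determination on the signal
scale over the echoes actually used; `r² = 1` within 1e−9 iff the retained
points lie exactly on one exponential.

## Noise floor and automated truncation

Magnitude images have Rician noise: at long TE, where the true signal has
decayed away, the measured magnitude plateaus at the rectified-noise
(Rayleigh) level instead of zero. Fitting those plateau echoes biases T2*
upward — worst exactly in severe iron overload, where misgrading has
clinical consequences.

`TruncationPolicy` automates the remedy: starting from the full echo
train, drop the longest-TE echo and refit while

* the current `r²` is below `r2_threshold` (default 0.995),
* at least `min_echoes` (default 3) would remain,
* fewer than `max_drop` echoes have been dropped (default: down to
  `min_echoes`), and
* **the drop improves `r²`** (`improvement_gated=True`, default).

The improvement gate is this package's design choice where the truncation
criterion was genuinely open. A fixed r² threshold alone cannot separate
the two reasons a decay fits imperfectly: a noise-floor plateau (dropping
late echoes then raises r² sharply, and truncation should proceed) and
ordinary channel noise on a shallow decay (dropping echoes does not
systematically raise r², and eroding a slow decay to a 3-point fit
inflates the error severalfold — at first-echo SNR 50 the ungated rule
takes the median relative error at T2* = 20–40 ms from ~4–6% to 19–36%).
Gating on improvement keeps both regimes correct; the unconditional
threshold rule remains available with `improvement_gated=False`.

With the default policy, pooled over T2* ∈ {1, 2, 5, 10, 20, 40} ms at
first-echo SNR 50 on the 10-echo liver protocol (200 replicates each), the
median relative T2* error is ~3%. At T2* = 40 ms the 9.8 ms maximum echo
time simply carries little information about the decay rate (the signal
falls by only ~20% across the train); the ~6–7% per-value error there is a
property of the acquisition protocol, not of the estimator, and is the
same with truncation as without.

## ROI-based vs pixel-based routes

The ROI route (`roi_mean_series` then fit) averages the in-mask signal per
echo and fits once. The pixel route (`pixelwise_fit`) fits every in-mask
pixel's own time-course and averages the resulting map (`map_roi_mean`).
On noiseless uniform data the two agree to machine precision (covered by a
test); on noisy data they differ because the fit is nonlinear in the data —
this mirrors the systematic ROI-vs-pixel discrepancies reported when the
two software approaches are compared clinically. Pixels whose fit fails
(non-decaying course, optimizer failure) are marked invalid, excluded from
ROI means, and counted — never interpolated. `render_map` draws the map
through a fixed matplotlib colormap (`turbo`) clipped to a configurable
scale (defaults 0–50 ms for heart, 0–20 ms for liver/pancreas, spanning
the clinically relevant ranges), with invalid pixels in reserved black;
rendering is deterministic down to the PNG bytes.

## Severity grading

Each organ has three boundaries `b_severe < b_moderate < b_mild` splitting
(0, ∞) into severe / moderate / mild / normal, with a boundary value
assigned to the less-severe side (conservative choice). Boundaries live
exclusively in YAML config; the shipped defaults — heart 10/14/20 ms,
liver 1.4/2.7/6.3 ms, pancreas 10/20/26 ms — are conventional values from
the clinical T2* literature and are labelled as such, not verified against
any single study. Severity is a monotone step function of decreasing T2*,
and grading a cohort is idempotent.

## Cohort statistics

* **Spearman correlation** (`spearman`): Pearson correlation of average
  ranks, two-sided p via the t approximation with n − 2 degrees of
  freedom (`scipy.stats.spearmanr`); pairwise deletion of incomplete
  pairs, logged. An exact permutation p (full n! enumeration) is available
  behind a flag for n ≤ 10.
* **Magnitude labels**: |r| < 0.4 weak, 0.4 ≤ |r| ≤ 0.6 moderate,
  |r| > 0.6 strong. The band edges are assigned inclusively to
  "moderate", consistent with reading 0.595 and 0.504 as moderate.
* **Loess** (`loess_smooth`): locally weighted linear regression, tricube
  weights over the `k = floor(span·n)` nearest neighbours, default span
  0.75, degree 1, no robustness iterations. Implemented in-package and
  cross-checked in the test suite against `statsmodels`' lowess to 1e−6
  on random data; exactly collinear inputs are reproduced to 1e−8.
* **Method agreement** (`method_agreement`): mean paired difference with a
  two-sided paired-t confidence interval (default 95%); zero-variance
  differences give a degenerate interval.
* **Summaries** (`summarize_cohort`): mean, SD (n − 1 denominator; defined
  as 0 for a single observation), median, min, max for continuous
  variables; counts and percentages for categoricals, percentages rounded
  half away from zero to one decimal using decimal arithmetic (so 32/39 →
  82.1 exactly, independent of binary-float ties).
* **Stratified correlations** (`stratified_spearman`): Spearman within
  each severity stratum; strata with fewer than 3 complete pairs are
  skipped with a warning.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions every test runs under.

* `simulate_decay` produces `K·exp(−TE/T2*) + floor` under two-channel
  Gaussian (Rician) magnitude noise. The explicit `noise_floor` models the
  plateau an ROI picks up when it brushes background or very dark tissue;
  the Rician `sigma` adds the stochastic part. Default echo train mirrors
  a liver protocol: first TE 0.8 ms, 1.0 ms spacing, 10 echoes.
* `simulate_phantom` renders disjoint labelled regions of prescribed
  `(K, T2*)` over a pure-noise background (Rayleigh magnitude, mean
  `sigma·√(π/2)`), one image per echo, independent noise per pixel, a
  single phantom-level seed.
* `simulate_cohort` draws organ T2* and ferritin through a Gaussian
  copula: target Spearman correlations are converted to the latent Pearson
  correlation via `ρ_p = 2·sin(π·ρ_s/6)` (exact for continuous marginals),
  the latent normal is sampled via an eigendecomposition square root
  (tolerant of rank-deficient targets such as a perfect correlation), and
  pushed through each marginal's quantile function. Default marginals are
  log-normals matched to published cohort mean/SD pairs (liver 3.84 ± 3.49
  ms, heart 32.04 ± 14.94 ms, pancreas 18.28 ± 13.98 ms, ferritin
  4640.75 ± 4821.93 ng/dl — all heavily right-skewed, hence log-normal);
  default rank correlations are the published organ/ferritin Spearman
  values. Ages are drawn uniformly on 9–37 years and sex 1:1; the
  published "median (range)" rows are internally inconsistent and are not
  matched.

Not emulated: anatomically realistic organ shapes, motion/flow/fat
artifacts, bright- vs dark-blood sequences, coil sensitivity profiles,
spatially correlated noise. Passing tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to acquisition
artifacts in real scans.

## Numerical and design choices

* Sampling Spearman variability: at n = 5000 the sampling SD of r around
  0.5 is ≈ 0.014, so recovery of a 0.5 target is asserted on the
  Monte-Carlo mean over 20 seeds (SE ≈ 0.003) within ±0.03, not per seed.
* The severity-flip demonstration fixture (a floor-contaminated liver
  series that grades mild untruncated but severe truncated) is the
  noiseless series K = 1000, T2* = 0.8 ms, floor = 100 on the default
  train: untruncated 3.20 ms (mild), truncated 1.39 ms (severe).
* Pipeline CSVs carry `#` provenance headers (config hash over the
  scientific parameters — paths excluded — plus stage parameters) and no
  timestamps, so a rerun under the same configuration is byte-identical.
* Problem sizes in the test suite and acceptance script (200 replicates
  per grid point, 500 floor replicates, n = 5000 cohorts over 20 seeds,
  12×12–64×64 phantoms) were chosen so every quantity's Monte-Carlo error
  is well below its assertion band.

## Known limitations

* No bi-exponential, offset-model, or Rician-likelihood fitting; R2* is
  exposed only as the trivial reciprocal.
* No automatic organ segmentation: ROI masks are inputs.
* The pixel route is a generic reimplementation of the pixel-based
  colour-map approach, not a clone of any vendor's windowing or fitting
  settings.
* DICOM is read-only (per-image EchoTime tags required); NIfTI + JSON
  sidecar is the primary format.
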