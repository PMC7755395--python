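# Methods

This note documents the models, estimators and numerical choices in
`neuroscales`, the assumptions behind them, and what the synthetic-data
tests do and do not establish about real recordings.

## Timescale model

Aperiodic neural field-potential activity is modeled as a stationary
process whose autocorrelation decays exponentially with constant τ. By the
Wiener–Khinchin theorem its PSD is a generalized Lorentzian
L(f) = A/(k + f^χ); χ = 2 exactly when the ACF is a single exponential,
and empirically 2–6 for neural data, so χ is left free. The knee frequency
is f_k = k^(1/χ) (exact at χ = 2, a bend-point approximation otherwise)
and τ = 1/(2π f_k). Oscillations enter the log-spectrum additively as
Gaussian peaks and are discarded for timescale inference.

## Spectral estimation

- Continuous recordings: Welch short-time spectra (1 s Hamming windows,
  50% overlap by default), aggregated per frequency by the **median**
  across windows rather than the mean, which suppresses high-amplitude
  transients. The median of a χ²₂-distributed periodogram sits a factor
  ln 2 below its mean; this bias is deliberately not corrected — it is a
  pure scale factor, and the knee and exponent are scale-invariant (a test
  verifies the ln 2 ratio is flat across frequency).
- Task epochs: one Hamming-tapered periodogram per 900 ms epoch (frequency
  resolution 1/0.9 ≈ 1.11 Hz).
- Detrending convention: each segment is demeaned before tapering
  (scipy's constant detrend). Without this, the taper's sidelobes leak the
  signal's mean — enormous for shot-noise-like simulations — into the
  lowest bins and corrupt the aperiodic fit. The global mean's power is
  restored into the DC bin so a constant signal still reports all its
  power at 0 Hz; the DC bin is excluded from all fits by the default fit
  range.
- Density scaling includes taper power normalization, so white-noise
  levels are taper-independent and the single-epoch estimator satisfies
  Parseval within sampling error.
- Band log-power is the mean of log10 power over a closed frequency band
  (both edges inclusive); theta is 3–8 Hz, high gamma 70–100 Hz.

## Spectral parameterization

`SpectralParamModel.fit()` decomposes the log10 spectrum over the fit
range (default 1–80 Hz: above DC, below line noise; the range is a package
choice, configurable):

1. **Robust initial aperiodic fit.** Bounded trust-region least squares of
   offset − log10(k + f^χ), analytic Jacobian, deterministic start
   (knee = median-frequency², χ = 2, offset matching the first bin);
   bins whose positive residual exceeds the 97.5th percentile (oscillation
   candidates) are dropped and the fit repeated.
2. **Sequential peak extraction.** While the maximum residual exceeds
   max(2 SD of the residual, 0.05 log10 units) and fewer than `max_peaks`
   (default 6) peaks exist, a Gaussian (bandwidth limited to 0.5–12 Hz) is
   fit at the residual maximum and subtracted. Broad non-Gaussian peaks
   (e.g., drifting oscillations) are deliberately tiled by several
   overlapping Gaussians at this stage.
3. **Aperiodic refit.** The aperiodic component is refit on the spectrum
   minus all extracted Gaussians, with bins within 2.5 bandwidths of any
   extracted peak masked out. Masking matters: subtraction alone leaves
   unmodeled peak shoulders in the refit and biased the knee by ~18% under
   a strong drifting 10 Hz oscillation in development experiments; with
   masking the median shift is ~5%.
4. **Reporting.** Overlapping extracted peaks (centers closer than 0.75 ×
   the bandwidth sum) are merged keeping the taller, and goodness of fit
   (RMSE, R² on the log10 scale) is computed for the reported model.
   Failed optimisations return a flagged result (NaN goodness), never a
   silent fallback.

Parameter bounds: χ ∈ [0.1, 8], k ≥ 0. A fitted knee below 10⁻³·f_min^χ
cannot be resolved inside the fit range; such fits are flagged knee-less
and τ is reported as undefined rather than extrapolated.

Time-domain estimators of the same τ (ACF 1/e crossing with linear
interpolation; least-squares exponential fit to the ACF, whose RMS error
flags non-decaying ACFs) serve as independent cross-checks, not as the
primary method.

## Electrode-to-parcel projection

Electrode values spread to surface points with Gaussian confidence
w(r) = exp(−r²/α²), r the Euclidean distance in mm and α = 4/√(ln 2)
≈ 4.805 mm — the unique constant giving 50% confidence at 4 mm. A point's
value is the w-weighted mean over *all* of a subject's electrodes (no
hard cutoff); its confidence is the maximum single-electrode weight.
Parcels aggregate member points by confidence-weighted mean and take the
maximum confidence; subjects combine into a group map the same way.
Parcels with confidence below 0.5 (an electrode within 4 mm) are masked
invalid by default. Values are averaged on the linear scale; a log-domain
switch exists for sensitivity analysis.

## Spatial statistics

Smooth spatial autocorrelation (SA) makes naive permutation inference
anti-conservative (demonstrated in the calibration test: ~46% false
positives at nominal 5% on independent smooth maps). Surrogate maps are
generated by Moran Spectral Randomization: the weight matrix is the
elementwise inverse of the inter-parcel distance matrix; its doubly
centered eigenbasis (constant mode removed) carries the map's spectral
coefficients, and each surrogate randomizes coefficient signs and applies
independent random rotations within adjacent-eigenvalue pairs. This
preserves the mean and variance exactly and the Moran spectral profile up
to adjacent-eigenvalue mixing; ensembles reproduce the empirical Moran's I
within a few percent and the binned variogram within a few percent of its
range. Two-tailed p-values are the smoothed more-extreme proportion
(1 + #{|ρ_null| ≥ |ρ|})/(n_null + 1), bounded below by 1/(n_null+1).
Variogram bins hold equal pair counts, stabilizing long-distance
estimates.

## Transcriptomic association

Expression matrices are standardized per gene across parcels before PCA
and PLS. PCA is the plain SVD X = USVᵀ of the normalized genes × parcels
matrix (no column centering: the shared spatial gradient across genes is
the object of interest, and the rank-1 sanity case requires the first
component to explain all variance); component signs are fixed by the
highest-|loading| gene. PLS1 weights are the unit-norm covariance
direction Xᵀy computed directly (verified against
sklearn.cross_decomposition.PLSRegression in a test); gene significance
compares each gene's |empirical weight| with the 95th percentile of its
own null-weight distribution from refits against SA-preserving surrogate
maps of the response. Fisher's exact p-values are computed from the
hypergeometric pmf with scipy's tie tolerance (validated against
scipy.stats.fisher_exact and against exact binomial-coefficient
enumeration); the enrichment ratio is (b/n)/(B/N); q-values follow
Benjamini–Hochberg. Ontology terms are tested independently; no DAG
propagation. Brain-specific genes are those whose mean brain-tissue
expression strictly exceeds 4× their median across all tissues.

## Cohort analyses

Working memory: per-trial spectral fits of the baseline, delay1 and
delay2 epochs give a baseline τ and a delay change
Δln τ = ln τ_delay − ln τ_baseline. Single-trial τ estimates are strongly
non-normal (heavy right tail; ln-scale SD near 0.8 for 900 ms epochs of
~20 ms processes), which drives two choices: the two delay estimates are
combined **geometrically** (an arithmetic mean would push a Jensen bias
of order (ln-variance)/4 ≈ +0.16 into Δln τ, inflating a planted 20%
expansion to ~40%; the arithmetic mean remains available as an option),
and τ columns aggregate geometrically across channels and trials
(arithmetic trial means are dominated by right-tail outliers and can
scramble region rankings). Aggregation order is channels → trials →
subject. Region baseline differences use two-sided Mann–Whitney U; the
delay change uses the paired two-sided Wilcoxon signed-rank (the design
pairs baseline and delay within trials); behavior association is the
Spearman correlation between subject-mean Δln τ and accuracy, computed
for every region with PFC as the headline. Trials with any failed epoch
fit are dropped and counted.

Aging: each parcel column of the subjects × parcels τ matrix is divided
by its maximum across subjects before within-subject averaging, so sparse
hierarchy-biased coverage cannot masquerade as an age effect; subjects
with fewer than 10 valid parcels are excluded (threshold configurable,
results stable over 5–20), and per-parcel age correlations (parcels with
≥ 5 subjects; stable over 4–8) are summarized by a one-sample t-test.

## Synthetic data: what it emulates, and what it does not

Signals are Poisson event trains (default aggregate rate 2000 events/s)
convolved with a causal exponential kernel truncated at 10τ and not
normalized (the knee position depends only on τ; the theoretical spectrum
is Lorentzian with χ = 2 and knee 1/(2πτ)). Oscillations are sinusoids
whose instantaneous frequency random-walks (SD = drift_std per second)
reflected within ±3 drift-SDs of the center, yielding the broad spectral
peaks typical of neural rhythms. The surface is a Fibonacci-lattice
sphere of ~100 mm diameter with great-circle parcel distances — a cheap
geodesic analogue. Smooth maps are Gaussian fields with squared-
exponential covariance (length scale 20 mm unless stated); expression
matrices plant a configurable gene subset tracking a target map against
SA noise. Working-memory cohorts use region baselines
PC 12 / PFC 18 / OFC 24 / MTL 30 ms, a planted ×1.2 delay expansion, and
(for behavior tests) subject-level log-normal expansion scatter (SD 0.1)
driving accuracy through a logistic link. Aging cohorts plant a linear
compression of 0.005/year over ages 13–62 with subject-level log-normal
variability (SD 0.15) and sparse coverage (3–24 parcels/subject), chosen
so the recovered age correlation is a realistic moderate effect
(ρ ≈ −0.3 … −0.5) rather than a near-deterministic one.

Not emulated: recording artifacts, line noise, epileptiform activity,
volumetric/surface registration, inter-regional correlation structure of
real coverage, or the probe-level structure of real expression data.
Passing tests therefore establish the *estimators'* correctness and
calibration under the stated statistical structure, not robustness to
every pathology of clinical recordings.

## Problem sizes in the test suites

The recovery and calibration suites use sizes chosen to give the checks
high statistical power at desk scale: 24 signals of 60 s for the
timescale sweep; 5 paired 60 s simulations for oscillation robustness and
the frequency/time-domain cross-check (medians reported, matching the
sweep's median-error summary); 200 independent map pairs × 500 surrogates
for inference calibration; 1000 genes / 50 planted / 500 surrogates for
PLS recovery; 14 subjects × 4 regions × 40 trials for the delay-expansion
recovery (all subjects planted at exactly ×1.2, so the band tests
pipeline error rather than cohort sampling luck) and 8 independent
14-subject PFC cohorts of 100 trials for the behavior-correlation sign
power; 30 aging cohorts of 106 subjects. Every test is seeded and
deterministic.

## Known limitations

- Single-knee model only; spectral plateaus and multi-knee spectra are out
  of scope, as are burst detection and time-resolved spectral estimates.
- The knee-based τ is meaningful only when a knee is resolvable inside the
  fit range; very slow (τ ≳ 150 ms at 1 Hz resolution) or very fast
  processes report knee-less or noisy fits.
- Single-epoch (900 ms) τ estimates are individually very noisy; all
  epoch-level conclusions are about aggregates across trials and subjects.
- MSR surrogates preserve second-order spatial structure; features beyond
  it (anisotropy, non-Gaussianity) are not constrained.
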