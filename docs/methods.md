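# Methods

This note documents the models, procedures and numerical choices behind
`pasablood`, the assumptions they rest on, and what the synthetic-data
evidence does and does not establish.

## Signal model and preparation

A recording is a uniformly sampled intensity trace: 2500 samples over 5 ms
(dt = 0.002 ms) by default. Acquisition is repeated per subject (10
photoacoustic, 5 absorption-spectroscopy replicates) with a trigger whose
switching-time error is up to 0.5 ms. The pipeline order is fixed:

1. pointwise arithmetic mean across replicates (noise ∝ 1/√K),
2. baseline shift of the averaged trace by its global minimum, so
   min y = 0 exactly for the analyzed trace (a raw PA span of −1…0.5 V
   becomes 0…1.5 a.u., a raw AS span of −100…20 V becomes 0…120 a.u.),
3. steady-state selection: the leading `discard_ms` (default 0.5 ms, the
   trigger-error magnitude) is excluded from all feature computation via an
   index marker; the time axis itself is unchanged.

The global minimum (not the initial value) is used for the shift because
the reported post-shift spans are min-to-max ranges. Shifting after
averaging makes the min-zero property hold exactly for the analyzed trace;
shifting each replicate first would not commute with averaging except up to
a constant.

## Time-domain features

**Change-point partition.** The top-k (default 10) abrupt changes in
segment mean are found by exact dynamic programming over the
piecewise-constant-mean model with squared-error cost: for each m ≤ k the
globally SSE-optimal split placement is computed (O(k·N²), numba-compiled),
and splits are accepted while each additional one reduces total SSE by at
least 1e−12 of the zero-split SSE — so constant signals yield no change
points rather than fabricated ones. Indices mark the first sample of each
new segment. An exhaustive-search oracle on small instances verifies
optimality in the test suite.

**Window roles.** The windows delimited by the change points are assigned
roles: the window containing the global maximum, its immediate left
neighbor (part A) and right neighbor (part B). If the maximum falls in the
first or last window the trace is rejected with a diagnostic rather than
silently repaired — a single dominant pulse flanked by quiet windows is an
assumption of the feature definitions, not a guarantee. The baseline is
the unweighted mean of all samples pooled over part A and part B (not the
mean of the two window means; the two differ when the windows have unequal
lengths, and the pooled reading is tested explicitly).

**Amplitudes.** p2p = max − min; positive peak = max − baseline; negative
peak = baseline − min. The additivity p2p = pos + neg holds identically.

**Slopes.** Straight lines y = bx + a fitted by the closed-form
least-squares expressions for intercept and slope, over the rising flank
(first sample after part A through the maximum) and the falling flank
(maximum through the last sample before part B). Time is in ms, so slopes
are intensity/ms; slope values are invariant under time translation.
Each flank must contain at least 2 samples.

**Area.** Trapezoidal integral of the steady-state trace (intensity·ms).

## Frequency-domain features

**Spectrum.** Welch's method: Hamming windows of ⌊N/8⌋ samples, 50%
overlap, periodograms averaged, one-sided density scaling, reported as
10·log₁₀ (dB). With a single full-length segment and zero overlap the
estimator reduces exactly to a Hamming periodogram, which the tests verify
against a direct FFT oracle at 1e−10 relative tolerance.

**Sampling-rate modes.** dt = 0.002 ms puts the Nyquist frequency at
0.25 MHz, while the band edges are conventionally quoted on a 0–3 MHz
axis; the two cannot hold simultaneously. Both readings are supported and
neither is guessed: `paper_dims` keeps dt = 0.002 ms and rescales the
quoted MHz edges by nyquist/3 so the four PASA and six peak bands tile the
available spectrum; `wideband` takes the quoted edges verbatim and
requires a sampling interval with Nyquist ≥ 3 MHz.

**PASA.** Ordinary least squares of the dB spectrum on frequency within
each band (bins with f_lo ≤ f < f_hi; at least 2 required). The slope is
in dB/MHz; the intercept is the regression line evaluated at 0 MHz even
for bands not containing zero (it is defined as the zero-frequency value);
the midband fit is the line at the band center, so
midband = intercept + slope·center identically. Four bands × three
quantities give 12 features.

**Peaks.** Spectra are analyzed in dB and the prominence threshold of 10
is read as 10 dB. Local maxima are found on the full spectrum (contour
bases may extend beyond a band), assigned to bands by peak frequency, and
peaks with prominence ≤ 10 dB are discarded; the surviving max-prominence
peak per band is reported. FWHM is the width at half the prominence below
the peak, linearly interpolated between bins and converted to MHz —
prominence-relative rather than absolute half-height, the convention of
standard peak-finding routines, chosen because absolute half-height is
ill-defined for dB values that can be negative. Bands without a surviving
peak yield missing values (NaN, written as NA), never zeros. An exhaustive
contour-scan oracle validates prominences on small spectra.

**Area.** Trapezoidal integral of the dB spectrum over the full axis.

Together with the six time-domain features this yields the fixed 31-name
feature vector; extraction is deterministic and scaling-equivariant (y → cy
doubles amplitudes/slopes/area for c = 2, shifts dB levels by 10·log₁₀ c²,
and leaves PASA slopes unchanged), which the tests assert.

## Association screen

Spearman's ρ (mid-ranks for ties) with a two-sided p-value from
t = ρ√((n−2)/(1−ρ²)) on n−2 df; |ρ| = 1 gives p = 0. Pairs are evaluated
pairwise-complete over the shared subjects; a pair with fewer than 4
complete observations or a constant variable is reported as untested, not
failed. A pair is significant when |ρ| > 0.5 and p ≤ 0.05. No
multiple-testing correction is applied in the headline screen, mirroring
the analysis being reproduced; the number of tests performed is annotated
on the result, and Benjamini–Hochberg adjustment is available behind a
flag. Whether the original analysis used pairwise-complete pairs or only
dual-modality subjects is not stated; pairwise-complete is implemented.

## Modeling

Per biochemical parameter, with all thresholds configurable:

1. **Entry.** Features significant in the screen enter, ranked by |ρ|
   (ties broken alphabetically). Because the candidate features are
   strongly mutually collinear, a small cohort can produce more significant
   features than observations; the design entering the VIF stage is capped
   at n − 2 features (keeping the strongest-ranked) so the VIF regressions
   are well-posed, and the post-prune design at n − 5 so the residual
   diagnostics retain degrees of freedom. Without these caps a 13-subject
   screen with 12+ significant features cannot run the procedure at all.
2. **Multicollinearity.** VIF_j = 1/(1 − R²_j) from regressing feature j on
   the others with intercept; exact collinearity gives +∞, not an
   exception. The max-VIF feature is removed while max VIF > 10 (ties drop
   the weakest-ranked); the stage is skipped (“NA”) for a single feature.
   Termination is guaranteed since the feature count strictly decreases.
3. **Linearity diagnosis** of the degree-1 fit, following the
   global-validation framework for linear models: with residuals e,
   σ̂² = Σe²/n, fitted values ŷ and b₁, b₂ the standardized third and
   fourth moments —
   skewness n·b₁²/6; kurtosis n·(b₂−3)²/24; link: the score (LM) test
   n·R²aux for adding ŷ² to the design; heteroscedasticity: the score test
   [Σvᵢ(eᵢ²−σ̂²)]²/(2σ̂⁴Σvᵢ²) against an observation-index trend
   vᵢ = i/n − mean. Each is asymptotically χ²(1); their sum is the global
   statistic (χ²(4)). The Durbin–Watson statistic is computed with an
   asymptotic normal p-value from the lag-1 residual autocorrelation
   (z = r₁√n) — cheap, deterministic and accurate at the n used here,
   in place of the bootstrap some implementations use. The relationship is
   linear only if **all six** nulls are retained at α = 0.05 (α matching
   the screen's significance convention). These published asymptotic forms
   are validated by simulation (size ≈ 0.05 per directional test at n=500,
   near-certain rejection on curved data), not against any particular
   routine's internals.
4. **Degree.** 1 when the diagnosis is linear; otherwise the
   BIC-minimizing candidate among {2, 3} (the literal reading of the
   degree rule; degree 1 is not re-entered for non-linear calls). Ties go
   to the lower degree for determinism. Candidates whose coefficient count
   exceeds n are infeasible and dropped; if none remains the degree falls
   back to 1.
5. **Fit.** OLS on per-feature power terms 1..degree plus intercept — no
   cross-feature interactions, the minimal reading of "polynomial
   regression" that keeps the parameter count well-defined. ln L̂ is the
   Gaussian log-likelihood at its maximum (σ² at the MLE);
   BIC = ln(n)·k − 2·ln L̂ with k counting all regression coefficients plus
   the error variance (the R `BIC(lm)` convention, since degree selection
   in the source analysis was R-based); R², adjusted R² per
   1 − (1−R²)(n−1)/(n−p−1), and the overall F-test p-value are reported.
   A parameter with no significant features, or too few complete
   observations, is reported unmodelled with the reason — never silently
   dropped. Models with adjusted R² > 0.5 and F-p < 0.05 are flagged
   "well predicted".

## Synthetic data: what it emulates and what it does not

Each subject's trace is a deterministic template: a negative baseline
offset plus a pulse with smooth rise–decay envelope
(1 − e^{−s/τ_r})·e^{−s/τ_d} carrying a damped oscillation (relative
amplitude 0.10–0.18, frequency 0.15–0.22 × Nyquist), with onset at 14% of
the record. Amplitude and time constants vary across subjects
(amp ~ U(0.4, 1), τ_r ~ U(0.010, 0.024)·T, τ_d ~ U(0.10, 0.18)·T), giving
the pulse nontrivial change points, flank slopes and spectral peaks for
every extractor. Replicates add iid Gaussian noise (PA 0.01 V, AS 0.8 V —
scaled to each modality's span) and a uniform onset jitter on
[0, 0.5 ms]; traces are clipped to the configured raw range so containment
holds in the noise tails. All randomness flows from explicit seeds;
identical seeds give bit-identical traces and panels.

Cohorts default to 14 subjects — 12 measured with both modalities, one
PA-only, one AS-only — with a 19-parameter panel. Parameters named in the
effect map equal a stated degree-1..3 polynomial of a subject's *true*
(noiseless, jitter-free) feature value plus Gaussian noise; all others are
standard-normal noise. The default effect map plants ALB.BCG (linear in
time-domain area, generating R² ≈ 0.97), CRE (linear, ≈ 0.80) and UA
(quadratic, ≈ 0.90), with BUN deliberately left as pure noise as the
no-signal control. The carrier features are ones the stepwise VIF pruning
characteristically retains (the time-domain area is also essentially free
of measurement noise through the averaging pipeline), so recovery of the
planted structure is identifiable by construction: an effect planted on a
feature that the procedure itself eliminates could not be recovered by any
implementation. The quadratic is vertex-outside-range, hence monotone —
detectable by a rank screen yet genuinely curved.

The generator emulates ranges, replicate structure, jitter and pulse-like
morphology; it does **not** simulate photoacoustic wave propagation,
transducer response, laser fluence, multi-pulse records, baseline drift or
real biochemical covariance between panel parameters. Passing tests
therefore establish the correctness and statistical calibration of the
*analysis*, not the physiological fidelity of any particular correlation:
cohort-specific correlation values from real patients are replaced
throughout by parameter recovery against known ground truth.

## Problem sizes, determinism and degenerate inputs

The test suite and acceptance script size their simulations to single-CPU
desk scale: 200 null cohorts at n = 12 for the screen's false-significance
rate (compared with a direct 200k-draw simulation of the same rule —
the composite rule has no closed-form null), 200 trials for diagnosis size
and power, 100 trials for BIC degree recovery, and five (test) or one
(script) 60-subject planted cohorts run end-to-end through the signal
pipeline. At n = 60 the recovery checks are assessed by modal degree and
median adjusted-R² error across cohorts because the diagnosis battery's
compound type-I rate (~25% with six tests at α = 0.05) occasionally sends
a truly linear parameter to the {2, 3} branch — a property of the
procedure, visible here only because the generating truth is known. The
default 14-subject cohort exhibits the same small-sample effects
(occasional chance associations for noise parameters); they are expected
behavior, not defects.

Numerical guards: spectral bins at exactly zero power are floored before
the dB transform; cumulative-sum cancellation in the change-point costs is
clipped at zero; exact collinearity reports infinite VIF; perfect fits
report R² = adj R² = 1 with infinite log-likelihood (BIC −∞); empty
traces, non-uniform time grids, NaN cells, unknown modalities, bands with
fewer than two bins and slope regions with fewer than two samples are
rejected with messages naming the offending value. Tables are written with
fixed float formatting so reruns are byte-identical.

## Known limitations

* The template is a best-effort emulation; no distributional description
  of real traces beyond ranges and qualitative morphology is available.
* The sampling-rate/band-edge inconsistency is surfaced as an explicit
  mode rather than resolved.
* The Durbin–Watson p-value is asymptotic; at very small n it is
  approximate (the statistic itself is exact).
* In-sample adjusted R² only — no cross-validation or out-of-sample
  claims, and no regularized alternatives to the stepwise VIF pruning.
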