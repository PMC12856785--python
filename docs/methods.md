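# Methods

This note documents the models and procedures the package implements, the
assumptions behind the synthetic-data generator, and the numerical choices
made where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scientific setting

During a modified Sternberg verbal working-memory task (2 s fixation, 1 s
encoding of a 1/3/5-consonant memory set, 4 s retention, probe until
response; 20 blocks x 15 trials = 300 trials, 100 per load, probe present at
50%), the EEG power spectrum's aperiodic component — the 1/f-like decay with
log-log slope `-chi` — changes with task phase and differs between younger
and older adults. The package analyzes:

1. the aperiodic exponent `chi` per participant x load x 1-s task segment x
   electrode (fixation F and retention seconds R2–R4, the first retention
   second excluded to avoid memory-set ERP contamination);
2. behavioral sensitivity `dL = ln[H(1-FA)/(FA(1-H))]` (logistic analogue of
   `d' = PhiInv(H) - PhiInv(FA)`), RT, and the P3b peak (maximum amplitude
   300–800 ms post-stimulus at Pz after -200–0 ms baseline correction);
3. the neural-inefficiency composite `NI = z(P3b load slope) - z(behavioral
   load slope)` (RT slope sign-inverted before standardization), where load
   slopes are per-participant OLS slopes over loads {1, 3, 5};
4. Bayesian Gaussian mixed models over these outcomes, summarized by
   posterior median, 95% HDI, probability of direction (pd), and the
   percentage of HDI draws inside a region of practical equivalence (ROPE,
   ±0.1 SD of the outcome).

Raw EEG of this kind is rarely deposited, so all validation here is
parameter recovery on synthetic cohorts with known ground truth.

## Spectral estimation

Each epoch (-6.5 to 1 s around probe onset, 256 Hz, 62-channel 10-10
montage) is cut into half-open 1-s windows: F = [-6, -5) s (the last full
fixation second inside every epoch; which fixation second the original
analysis used is unstated, so the window is configurable), R2 = [-3, -2),
R3 = [-2, -1), R4 = [-1, 0). Single Hanning tapers on single windows give
1-Hz native resolution; tapering precedes zero-padding to 2 s (0.5-Hz grid)
so the taper never touches the zeros, and one-sided density scaling divides
by `fs * sum(w^2)`. Spectra are averaged across trials in linear power
within each load before any log transform.

## Spectral parameterization

The model of log10 power over 2–40 Hz is an aperiodic line plus Gaussians:

    log10 P(f) = b - chi*log10 f + sum_k a_k exp(-(f-c_k)^2 / (2 s_k^2))

fit by the fit-flatten-extract sequence (fixed mode, max 6 peaks, peak
threshold 2 SD of the flattened spectrum, peak bandwidth limits [1, 12] Hz
with bandwidth = 2 SD). Numerical choices where the reference algorithm
leaves room:

- **Robust aperiodic fit.** Initial least-squares line in log-log space;
  refit on points whose clipped positive residual lies at or below the 2.5th
  percentile (the standard oscillatory-peak exclusion).
- **Guess refinement.** Each candidate peak (found at the residual maximum,
  width initialized from half-height crossings) is refined by a local
  bounded single-Gaussian fit before subtraction. A raw half-height guess
  under-covers broad peaks; subtracting it leaves shoulders that would be
  detected as spurious secondary peaks.
- **Overlap pruning.** Of two guesses whose ±0.75 SD neighborhoods overlap,
  the smaller is dropped; refit centers are bounded to ±1.5 SD of their
  guess. Together these prevent one broad peak being fit twice.
- **Edge guard.** Candidates whose center is within one SD of a fit-range
  edge are discarded (boundary blow-up protection).
- **Numerical peak floor.** Peaks below 1e-6 log10 units are never fit, so
  float-precision ripple on an exactly aperiodic spectrum yields zero peaks.
- **Stopping SD** is the standard deviation of the current (iteratively
  peak-subtracted) flattened spectrum, recomputed each iteration.
- **Goodness of fit**: R^2 = 1 - SS_res/SS_tot and MAE, both in log10 power.
- Ties between equal residual maxima resolve to the lower frequency.

The noiseless model class is recovered to machine precision; on seeded
model-class spectra with trial-average-level noise (0.01 log10 units) the
median exponent error is below 0.02 (asserted in the tests, alongside an
algorithmically independent peak-masked Theil–Sen cross-check).

## Fit-quality QC

Within each participant x load x segment cell, channels whose R^2 falls
strictly below Q1 - 1.5*IQR across channels are flagged (quartiles by linear
interpolation of order statistics — pinned because the flag set can depend
on the convention) and repaired by Perrin-style spherical-spline
interpolation (order m = 4, regularization 1e-5, 50 Legendre terms, constant
term included so a constant field is reproduced exactly), after which
spectra are recomputed and refit. Electrode coordinates are idealized 10-10
positions computed analytically on the unit sphere; they enter only the
spline weights and the cosmetic ERP scalp falloff.

## Behavioral measures

Hit = "present" response on a probe-present trial; false alarm = "present"
on a probe-absent trial. Whenever a raw rate is 0 or 1, both rates receive
the Snodgrass–Corwin log-linear correction (+0.5 to each count, +1 to each
denominator); edge handling is a genuinely open choice in this literature,
so the correction is applied only at boundaries and flagged in the output.
RT outliers (> mean + 3 sample SD) are computed per participant over
correct trials pooled across loads (pooling granularity is another open
choice; a per-load switch exists). Only correct, non-outlier trials enter ERP averages.

## Neural inefficiency

Slopes are standardized across the full pooled sample (both age groups);
within-group standardization is a documented alternative. The fixation
median split labels participants "steeper" (>= median, ties to steeper) or
"flatter" on fixation exponents averaged across electrodes and loads.

## Bayesian mixed models

`y = X beta + sum_r Z_r u_r + eps`, Gaussian noise, independent normal
random intercepts (participant; electrode where applicable), treatment
coding with references younger / load-1 / fixation. Priors are weakly
informative: intercept N(mean(y), (2.5 SD(y))^2), slopes
N(0, (2.5 SD(y)/SD(x))^2), half-normal(2.5 SD(y)) on all SD components —
the common "weakly informative autoscaled" convention of applied Bayesian
regression packages.

The sampler is a self-contained Gibbs scheme chosen so the package runs
without heavyweight probabilistic-programming dependencies; the contract is
convergence (rank-normalized split-Rhat < 1.01 on all reported parameters),
not a specific MCMC backend:

- **Joint coefficient block.** (beta, all u) are drawn jointly from their
  Gaussian full conditional using precomputed cross-products. Sampling this
  block jointly is essential: between-cluster fixed effects (e.g. age group)
  are strongly correlated with the random intercepts a posteriori, and a
  blocked-by-parts scheme random-walks across that ridge.
- **Variance components** have half-normal SD priors (non-conjugate), so
  log-variances are updated by univariate slice sampling, followed by an
  ancillarity-sufficiency interweaving (ASIS) redraw in the non-centered
  parameterization, which mixes through the funnel when a variance component
  is near zero (the electrode variance in homogeneous simulations).
- Default schedule 4 chains x 2000 post-warmup draws (1000 warmup); the
  source's iteration accounting is internally inconsistent, so a consistent
  config-scalable schedule is used. Chain c is seeded from (seed, c);
  identical data + seed reproduce draws exactly.
- Posterior summaries are self-implemented and cross-checked against arviz
  in the tests: HDI as the shortest contiguous interval containing
  ceil(0.95 n) sorted draws; pd as the posterior share with the median's
  sign (zeros count with the median); ROPE coverage as the percentage of
  draws inside the 95% HDI that fall within ±0.1 SD(y). Existence labels:
  pd > 97.5 / 99 / 99.9 % -> likely / probable / certain; relevance: ROPE
  coverage < 1 % relevant, < 2.5 % probably relevant, > 97.5 % probably
  irrelevant, > 99 % irrelevant, otherwise inconclusive (strict
  inequalities).
- Post hoc contrasts are per-draw differences of predicted cell means with
  equal-weight marginalization over unassigned factors (the original
  marginalization weights are unstated; equal weights match balanced
  designs).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
raw-EEG physics:

- **Aperiodic background**: per trial/channel/phase, colored noise from the
  inverse FFT of the target amplitude spectrum `10^(b - chi_seg log10 f)`
  with uniform random phases. Exponents are piecewise-stationary per task
  phase (retention seconds carry per-segment deltas), matching the analysis'
  stationarity assumption. Every piece is synthesized with a 1-s margin and
  cut centrally, so each analysis window is an interior slice of a longer
  stationary stretch — recorded EEG has energy below a window's fundamental,
  and windows exactly aligned with circular realizations would lack that
  leakage (and bias segment contrasts).
- **Alpha peak**: the target spectrum is multiplied by the log-Gaussian peak
  `10^(a exp(-(f-c)^2/(2w^2)))` — exactly the periodic component the
  parameterizer estimates, so peak ground truth is defined in the estimated
  units.
- **ERPs**: Gaussian bumps (peak 450 ms post-onset, SD 80 ms) at encoding
  and probe onsets, Pz amplitude `p3b_base + slope*load`, exponential scalp
  falloff with unit-sphere distance from Pz (cosmetic; only Pz is analyzed).
- **Behavior**: Bernoulli(accuracy(load)) correctness; RT = intercept +
  slope*load + additive lognormal jitter.
- **Defaults are the stated world**: 24 younger + 30 older participants;
  younger-minus-older fixation exponent offset 0.21 (younger mean 1.50);
  retention deltas R2 = -0.04, R3 = R4 = -0.05; accuracy {0.960, 0.958,
  0.928} for loads {1, 3, 5}, chosen to reproduce ~95% overall accuracy and
  the reported dL drop at load 5 under the H = accuracy = 1 - FA structure;
  probe P3b load slope -0.34 uV/load (reproducing a -1.36 uV load-5 vs
  load-1 difference), encoding slope +0.25 uV/load; RT intercepts 0.55 s
  (younger) / 0.70 s (older), load slope 0.05 s. Between-participant SDs are
  not reported anywhere and are config-exposed (exponent SD 0.20, typical of
  resting aperiodic studies; segment-delta SD 0.01; others in
  `CohortEffects`).
- **RNG**: one named stream per participant derived from the cohort root
  seed, so partial regeneration is stable; epochs and behavior use separate
  substreams. Identical config + seed gives bit-identical arrays and
  byte-identical pipeline outputs.

What the generator does **not** emulate: eye-blink/muscle artifacts, line
noise, electrode drift, volume-conduction covariance between channels
(channels are independent), aperiodic "knee" dynamics, or P3b latency
variability. A green recovery test therefore establishes that the analysis
chain is unbiased and correctly wired for data satisfying its own
assumptions — not that it is robust to artifacts the preprocessing of a real
study would have to remove.

## Parameter recovery and its scaling

`aperiodic_wm.recovery.run_recovery` simulates the 24+30 cohort, runs
spectral estimation, parameterization, and the exponent mixed model (age,
load, segment fixed effects; participant and electrode random intercepts),
and compares posterior medians of the age and R2-vs-fixation contrasts to
the injected truths. For a single-CPU budget it uses 8 channels, 40 trials
per load (a real session yields ~73–80 retained trials of 100 after
artifact rejection anyway), and
2 chains x 2000 draws; trial scaling widens posterior noise slightly but
leaves the contrasts unbiased. The recovery cohort pins realized group and
segment means to the configured truths (`exact_group_means=True`): a single
cohort draw's group-mean difference has sampling SE ≈ 0.2*sqrt(1/24 + 1/30)
≈ 0.055, which would swamp a ±0.03 recovery comparison; fixing the margins
is the standard design when the comparison target is the injected value.
Ordinary simulations keep full sampling variability.

Known estimator property: Hanning-taper leakage on 1/f spectra biases
absolute exponent estimates upward slightly (~0.01 on trial-averaged
noise-free-peak spectra, more on few-trial averages); the bias is nearly
constant across conditions and cancels in the group and segment contrasts
the analysis reports.

## Known limitations

- Only the fixed (no-knee) aperiodic mode is implemented.
- Channels are simulated independently; spline interpolation is therefore
  exercised on fields without realistic spatial correlation (tests use
  constant/symmetric fields where the correct answer is known).
- The Gibbs sampler covers Gaussian likelihoods with random intercepts —
  the model class the analyses need — not random slopes or non-Gaussian
  families.
- pd is reported from finite draws; its Monte-Carlo error at 4000 draws is
  about ±0.7 percentage points near 97.5%.
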