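# Methods

This note documents the models, estimators and design choices behind
`cgmchaos`, in the order the forecasting workflow runs.

## Phase-space model of CGM dynamics

A CGM trace is a scalar series x_t sampled every 5 minutes.  The package
treats it as an observable of a low-dimensional deterministic system
observed with sensor noise.  Takens delay embedding maps the series into
delay vectors

    z_t = [x_t, x_{t+τ}, …, x_{t+(m−1)τ}],

whose dynamics z_{t+1} = F(z_t) inherit the invariants of the underlying
system.  All modelling, denoising and characterization happens on the
resulting phase matrix (T = n − (m−1)τ rows).  Reconstruction of the series
from a phase matrix keeps the first column and reads the trailing (m−1)τ
samples off the later columns of the final rows; this inverse is exact
whenever T ≥ τ.  For T < τ some samples never enter the matrix and the
reconstruction rightfully refuses.

### Embedding parameters

* **Delay τ** — first local minimum of the average mutual information
  (joint-histogram estimator, natural log, Freedman–Diaconis bin count by
  default) for nonlinear models; first drop of the autocorrelation below
  1/e for linear models.
* **Dimension m** — Cao's method.  E1(m) = E(m+1)/E(m) from mean
  nearest-neighbour distance-expansion ratios (maximum norm); m is selected
  where E1 exceeds 0.90 and stays above it for the next dimension.  Cao's
  companion statistic E2 guards against stochastic input: when E2(m) ≈ 1 at
  every m the series is treated as noise-like and m_max is returned with a
  warning.  The 0.90/E2 combination was chosen because E1 of even textbook
  deterministic maps (e.g. the Hénon attractor at n = 5000) plateaus at
  0.94–0.99, so a single hard threshold close to 1 misclassifies them,
  while E2 separates noise far more reliably than any E1 cut.
* Nearest-neighbour searches ignore pairs closer than 1e−9 of the data
  range: exactly periodic noiseless signals produce machine-precision
  recurrences whose distance ratios are pure rounding noise.

### Chaos statistics

* **Correlation dimension D2** — Grassberger–Procaccia.  The correlation
  sum C(r) counts pairs within r, excluding temporal neighbours inside a
  Theiler window of m·τ samples; vectors are deterministically thinned to
  at most 2500.  D2 is the least-squares slope of log C vs log r over the
  contiguous window of radii whose local slopes are most stable (lowest
  coefficient of variation, longer windows preferred); an unstable scaling
  region flags the estimate as low-confidence.
* **Largest Lyapunov exponent λ** — Rosenstein divergence curves.  Each
  vector's nearest neighbour outside the Theiler window is tracked forward;
  S(t) = ⟨log d(t)/d(0)⟩ and λ is the regression slope of S(t) over the
  early part of the curve, auto-truncated before saturation (first third of
  the curve or the point where S reaches 90% of its plateau, whichever is
  earlier).  λ is reported per sample step in natural-log units.
  Validation: λ ≈ ln 2 on the r = 4 logistic map, ≈ 0.42 on Hénon, ≈ 0 on
  periodic signals.

## Glycemic risk and variability

Per-reading risk uses the standard symmetrizing transform
f(BG) = 1.509·((ln BG)^1.084 − 5.381) (BG in mg/dL, zero crossing
≈ 112.5 mg/dL) and risk r = 10 f².  The low/high glucose indices (LGI/HGI)
are the means of the low-side (f < 0) and high-side (f > 0) risks over all
readings — the mean, not a raw sum, because a sum would grow with series
length and detach the indices from their categorical cut-points
(hypoglycemia: minimal < 1.1 ≤ low ≤ 2.5 < moderate ≤ 5 < high;
hyperglycemia: low < 4.5 ≤ moderate ≤ 9 < high; boundary values join the
lower-severity side except where a band is defined strictly "greater
than").

Variability indices: SD, CV = SD/mean, J-index = 0.001(mean + SD)²,
CONGA_n = SD of differences n hours apart (default n = 1 h), MODD = mean
absolute difference of readings one day apart, GVI = arc length of the
trace over the straight chord (time in minutes), PGS = GVI × mean glucose
× fraction of time outside 70–180 mg/dL.  MAGE uses a threshold zig-zag on
a 3-point-smoothed trace: a peak/nadir is confirmed only after a reversal
exceeding one standard deviation, so sub-threshold wiggles cannot fragment
large excursions; MAGE is the mean confirmed peak↔nadir amplitude in both
directions.  The PGS constant structure follows the arc-length literature
definition; its exact printed form varies between sources and is flagged
here as a convention choice.

## Regime-switching predictors

Five autoregressive model families operate on the phase matrix; the
one-step target of row u is the next scalar observation (the new coordinate
of the successor delay vector), so multi-step forecasts iterate the fitted
map autoregressively.

* **LAR** — ordinary least squares on the delay coordinates.
* **AAR** — additive model with one penalized cubic regression spline per
  delay coordinate (statsmodels GLMGam, B-spline bases); a shared smoothing
  penalty is picked from a small log-spaced grid by GCV.
* **NNAR** — single tanh hidden layer, linear output, trained by
  gradient backpropagation (LBFGS) with five seeded restarts; the width q
  is selected by AIC over {1, …, 4} when "auto".  Inputs and targets are
  standardized internally; fixed seeds make refits bit-reproducible.
* **SETAR** — two linear regimes split on Y_t = z_{t−δτ}.  Candidate
  thresholds are the observed Y values between the 10% and 90% quantiles
  (at most 200, evenly thinned), each regime must keep ≥ 10% of the
  observations, and (th, δ) minimize the pooled AIC.
* **LSTAR** — regimes blended by G(Y; γ, c) = 1/(1 + e^{−γ(Y−c)}), the low
  regime weighted (1 − G) and the high regime G.  (c, γ) are found on a
  200 × 40 grid (c spanning the 0.1–0.9 quantiles of Y, γ ∈ [1, 40]) with
  the linear parameters solved by least squares at every grid point, then
  refined locally by Nelder–Mead.

AIC uses the Gaussian conditional likelihood with n = number of one-step
targets and k = free parameters (spline effective dof for AAR, weight count
for NNAR) so the five families are compared on one scale; model selection
takes the lowest AIC, ties broken by MAPE and then by simplicity.

Identifiability caveat: for a *smooth* transition (γ ≈ 10) the location c
is only identified to a few grid-steps at n = 2000 — verified by profiling
the residual sum of squares over c with γ held at truth — whereas sharp
transitions (γ ≥ 20) and hard thresholds (SETAR) are recovered below the
grid resolution.  The parameter-recovery studies therefore use γ = 20 for
the sub-grid-recovery check and report the γ = 10 case with a 3-grid-step
tolerance.  The LSTAR→SETAR step-function-limit comparison holds the
threshold variable fixed (δ = 0 on both sides) and uses a process whose
regimes join continuously at the threshold: with a jump discontinuity the
logistic's finite transition band (width ≈ 1/γ) bounds the achievable
agreement away from zero on unit-scale data.

## Forecasting pipeline

For each forecast origin t (every sample from the end of the first
training window onward):

1. the trailing 8-hour window (96 samples, ending at t) is log-transformed
   and first-differenced — CGM traces fail the augmented Dickey–Fuller
   test on levels and pass after differencing — then standardized with the
   window's own mean/SD;
2. the working series is denoised by phase-space neighbourhood averaging:
   delay-1 embedding, each vector replaced by the mean of all vectors
   within a Euclidean radius, overlapping coordinates averaged back.  The
   radius schedule on standardized data anchors 0.2 for m ≤ 4 and 1e−4 for
   m ≥ 8, log-interpolated between — the small-radius end makes denoising a
   no-op in high dimensions, which is the intended behaviour of a
   curse-of-dimensionality-limited neighbourhood average;
3. m comes from Cao's method on the window (capped at 4 by default); the
   delay is fixed at τ = 1.  A 5-minute-sampled glucose trace is heavily
   oversampled relative to its hours-scale oscillations, and iterated
   6–12-step forecasts degrade sharply (RMSE +40%) when the delay vector
   spans more than the forecast horizon; the AMI/ACF delay estimate remains
   available (`delay_policy="estimate"`) and is used in the dynamical
   characterization;
4. the configured model is fitted to the denoised window and one-step
   predictions are iterated PH/5 times (6 for a 30-minute horizon, 12 for
   60), each step clipped to the training window's observed range — a
   fitted nonlinear map iterated outside its training region can diverge;
5. predicted increments are accumulated from the last observed level,
   inverse-transformed to mg/dL, and the final level is clipped to a
   physiological rate envelope of 2 mg/dL/min × PH around the origin value
   (glucose transients faster than that are not physiologic);
6. the model is refit whenever the origin has advanced one horizon since
   the last fit; between refits the model is reused on current data.

Everything the forecast touches — transform statistics, denoising,
embedding parameters, model coefficients — is computed from samples at or
before the origin, so mutating later samples leaves earlier forecasts
bit-identical (verified by test).

## Evaluation

RMSE, MAE and MAPE on the aligned prediction/realization pairs (MAPE
excludes zero references, with the exclusion count reported).  Clinical
grading uses continuous glucose error-grid analysis: a Clarke-style point
grid whose A/B boundaries shift 10 mg/dL in the direction of rapid
reference trends (|rate| > 2 mg/dL/min), and a rate grid on finite-
difference rates (central differences, one-sided at the ends, clipped to
±4 mg/dL/min) with A: within 1 mg/dL/min of the reference rate, B: within
2, C: spurious trend while the reference is stable, D: missed trend,
E: opposite directions.  Each pair's combined grade is the more severe of
its point and rate zones (A < B < C < D < E), E collapsing into D, giving
the four reported zones; results are stratified by the reference range
(hypo < 70, eu 70–180, hyper > 180 mg/dL).  The collapse is deliberately
conservative: any C-level cell reports C, any D/E-level cell reports D.

## Synthetic CGM generator

No public patient traces accompany the package, so `simulate_cgm` stands in
for them.  The trace is basal level + chaotic core + meal excursions +
risk dips + truncated Gaussian noise:

* **Chaotic core** — the Lorenz x-component with one Lorenz time unit
  mapped to 6 hours of clock time (pseudo-period ≈ 4.5 h), standardized and
  scaled to 22 mg/dL.  With noise off, the sampled core has a positive
  Lyapunov exponent as estimated by this package's own analysis.
* **Meals** — gamma-shaped excursions at 07:30, 12:45 and 19:00, peaking
  1.3 h post-meal; amplitude 45 mg/dL plus 70·hyper_intensity, with a
  sustained 25·hyper_intensity shift.
* **Risk dips** — nocturnal (≈ 02:00) and late-afternoon dips whose depth
  grows with hypo_intensity; at hypo_intensity = 0 a counter-regulatory
  floor keeps every value ≥ 70 mg/dL.
* **Noise** — additive Gaussian, SD 5 mg/dL by default, truncated at ±3 SD;
  all values clipped to (20, 500) mg/dL.

The time scales were calibrated so deterministic rates of change stay
inside the ≈ 2 mg/dL/min envelope reported for real CGM, i.e. 30-minute
changes of realistic size; the noise draw precedes everything else in the
random stream so traces with the same seed but different intensity knobs
are pairwise comparable (this is what makes LGI/HGI strictly monotone in
the knobs).  Preset configurations (`RISK_PRESETS`) reach each documented
LGI/HGI category.

What the generator does **not** emulate: insulin kinetics and announced
boluses, meal-to-meal variability in timing and content, sensor drift,
compression artefacts and dropout patterns, and autocorrelated sensor
noise.  Passing tests on this generator therefore demonstrate the
*machinery* — embedding, fitting, forecasting, grading — under controlled
chaotic dynamics with realistic cadence and amplitude; they are not a
clinical-accuracy claim for real patients.

## Problem sizes and defaults

Chaos oracles run at n = 4000–5000 points; parameter recovery at 20
simulations of n = 2000; the end-to-end experiment at 5 days (1440 samples)
for the headline run and 10 single-day seeds for the horizon-ordering
study.  These sizes put every estimator comfortably inside its asymptotic
regime while keeping a full run of the suite and the acceptance script in
the minutes range on one core.

## Known limitations

* The AAR smoother state is not serialized; a deserialized AAR model can
  report its scores but not predict.
* SETAR/LSTAR support the lagged-value threshold variable Y_t = z_{t−δτ};
  the linear-combination variant is not implemented.
* The sliding forecaster refits from scratch; there is no online parameter
  updating between refits, and the training-window length is fixed rather
  than adapted to the trace's variability.
* D2 and λ estimates on short, noisy windows (under ~500 points) are
  indicative only; the pipeline uses them for embedding choice, not as
  reportable statistics.
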