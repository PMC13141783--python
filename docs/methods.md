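# Methods

This note documents the models, parameter choices and numerical decisions
behind `glycofp`, and the scope of the synthetic-data generator used for
validation. All empirical statements below refer to measurements on
synthetic cohorts produced by `glycofp.simulate` (the test suite computes
them; none are claims about in vivo data).

## Data model

A session is a pair of 1 Hz, uniformly sampled series aligned so that
t = 0 is the oral glucose gavage, spanning −25 to +90 min: a photometry
activity channel with an isosbestic reference, and blood glucose in
mg/dL. `UniformTrace` (values, start time, sampling rate) is the single
container; window arithmetic is exact (windows in seconds map to integer
sample indices at 1 Hz), which is what makes bit-identical reruns
possible.

## Glucose

Preprocessing: MAD despiking (k = 2, on a locally detrended copy so the
excursion itself is not flagged), centered median filter (7 samples),
causal moving average (60 s), boxcar smoothing (120 s) for the
derivative, and baseline subtraction (median over −25 to 0 min), giving
ΔG(t) and a smoothed derivative.

Onset detection: thresholds are derived from the short pre-gavage window
(−5 to 0 min) — a level threshold (baseline + z·SD with z = 3) and a
slope threshold on the smoothed derivative. A sample t ≥ 0 is marked when
either threshold is exceeded; onset is the first time the mark is
sustained for a continuous 60 s. On 200 synthetic sessions at the default
excursion (signal-to-noise well above 5) the median absolute onset error
is below 60 s, with ≤ 5 % false detections on 200 water (dose 0)
sessions.

Excursion metrics: peak ΔG and time (0–90 min), peak derivative
(0–30 min), half-max return (linear interpolation on the unclipped
series), plateau (first ≥ 2 min interval after the peak-rise where
|derivative| ≤ 0.1 × peak rise rate), return-to-baseline, and positive
iAUC (trapezoid, mg/dL·min).

## Photometry

Preprocessing chain, in order:

1. **Reference regression.** The reference channel is low-pass filtered
   (4-min cutoff period, order 3) to isolate the slow non-neural drift it
   proxies (photobleaching, slow motion), then regressed onto the signal
   and the fit subtracted. Two deliberate choices:
   - regressing the *raw* reference would attenuate the coefficient
     (errors-in-variables from reference noise) and leave part of the
     drift in the corrected trace;
   - the coefficients are estimated on a pre-event window (−25 to −5 min)
     that ends before anticipatory activity can begin, then applied to
     the whole trace. A whole-session fit partially absorbs any sustained
     neural response that covaries with the monotone drift.
   Fast shared transients are left to the despiking/median stages.
2. MAD despiking (k = 2, detrended window 31), centered median filter
   (7 samples), causal moving average (60 s; causal so responses stay
   stimulus-aligned).
3. Zero-phase Butterworth low-pass, cutoff period 4 min, order 3
   (`scipy.signal.sosfiltfilt`).
4. Baseline z-score over −25 to 0 min, giving Z(t) with baseline mean 0
   and unit SD.

Response metrics: peak z deflection in 0–15 min (inhibition = minimum),
negative AUC from 0 to the glucose peak time, unclipped total AUC from 0
to session end, baseline aperiodic PSD exponent κ (least-squares line in
log-log space over 0.05–0.5 cycles/min of the Welch PSD), and the
band-power onset detector below.

### Band-power onset detector

A spectrogram of Z(t) (Hann, 20-min windows, 99 % overlap) is reduced to
mean power in the 14–20-min-period band (0.05–0.071 cycles/min). Each
time bin's power is ranked against N pseudo-onset re-alignments of the
same session (excluding a 5-min guard around the true gavage):
p = (1 + #{null ≥ real}) / (N + 1). Onset is the first bin in −10 to
+10 min with p < α.

**Calibration limitation.** The rank-p guarantee
P(p ≤ α) ≤ α + 1/(N+1) assumes the real bin is exchangeable with the
pseudo-onset nulls, which requires the recording to contain many
independent 20-min segments. A 115-min session contains only ~6, so at
that length small-α p-values are anti-conservative (measured on
white-noise sessions: P(p ≤ 0.05) ≈ 0.11 against a bound of ≈ 0.10 for
N = 60), for any implementation of this construction. On 8-h white-noise
recordings (~23 independent windows) the same code is cleanly calibrated
(P(p ≤ 0.05) ≈ 0.037). Onset calls on standard-length sessions should
therefore be read descriptively, not as calibrated hypothesis tests.

## Early-response model

The anticipatory component is modeled per session as an affine transform
of a cross-session template with a small temporal shift:

    F̂ᵢ(t; τ) = β₀ᵢ + β₁ᵢ · template(t − τ),   t ∈ [−25, +1] min

- **Template**: pointwise across-session median of the training sessions'
  z-scored traces over the model window (training doses 1, 2, 2.5 g/kg).
- **Cross-validated lag τ\***: selected on a grid (−1 to +1 min, 0.25-min
  steps) by K-fold CV with subject-stratified folds (template rebuilt from
  K−1 folds, left-out sessions scored by validation MSE; ties break to
  higher validation R², then smaller |τ|). τ\* characterizes the cohort
  and validates that the grid contains the right alignment.
- **Per-session shift τᵢ**: each session's lag is then chosen on the same
  grid by fit-window MSE (same tie-break). Anticipatory onset jitters
  across sessions by about ±1 min; forcing one global lag attenuates β₁
  for misaligned sessions and leaks early-response shape into the late
  residual. `session_metrics.tsv` carries both `tau_min` (per session)
  and `tau_star_min` (cohort).
- **Leakage guard**: no sample after +1 min ever enters a fit — mutating
  all data past +1 min leaves fits bit-identical (asserted in the
  acceptance suite).

Beyond +1 min the prediction holds the template's final value, so the
residual R(t) = Z(t) − F̂(t) over later times reads as deviation from the
early pattern's plateau. Residual summaries per analysis window (0–10,
10–60 min): mean, minimum (depth) and its time. Depth is the preferred
effect-size measure for the later component: a transient dip's rise and
fall nearly cancel in a 50-min mean, while its depth scales directly with
the underlying coupling gain (on synthetic cohorts with generator gains
0.5/1/2×, mean depths ≈ −2.7/−4.5/−8.4 z; with gain 0 the late-window
mean residual is statistically indistinguishable from 0).

## Coupling

Lagged Spearman correlograms between the residual and the glucose
derivative over 0–90 min, lags up to ±20 min (positive lag = photometry
follows glucose). Group inference: per-lag Fisher-z mean of session ρ
(|ρ| clipped to 1 − 10⁻⁶ with a warning), compared against pseudosession
nulls — each session's residual re-paired with other sessions' glucose
derivatives at random circular offsets (minimum 20 min) — with rank
p-values per lag and Benjamini–Hochberg control over the lag family at
α = 0.01. With independent generators the BH-significant lag fraction
averages ≤ 1 % over 100 synthetic cohorts.

On default synthetic cohorts the group residual correlogram peaks within
±30 s of the generator's true +300 s lag, while the anticipatory
component (the model prediction, correlated over the full session since
it is constant after +1 min) peaks at negative, leading lags.

## Cohort statistics

OLS with subject fixed effects and HC3 robust standard errors for every
battery entry (dose vs excursion metrics, photometry metrics vs glycemic
rates, residual depth vs rise/fall rates, β₁ vs rates adjusting for dose
and baseline glucose); with one subject the fixed effects collapse to the
intercept. Also: one-sample t test of spectral onsets against 0 (on
sessions with order index > 1, i.e. animals with prior experience of the
gavage), Wilcoxon signed-rank for paired peak-lag comparisons, and a
seeded shuffled-dose control.

## Synthetic generator (validation scope)

`simulate_bg`: double-exponential glucose excursion with dose-scaled
amplitude (peak ΔG ≈ 60 mg/dL per g/kg), onset ~3.5–4 min post-gavage,
AR(1) noise, occasional handling spikes; water sessions are excursion-free.

`simulate_fp`: neural truth = phase 1 (smoothstep decline of 120 s full
duration starting 4 ± 1 min before gavage, amplitude 2 z, sustained
plateau) + phase 2 (gain times the rectified lagged glucose derivative,
plus a mirrored term during decline, lag 300 s, gains 0.12 z·min/mg/dL
rise and fall). Observation = neural + slow baseline variability
(stationary Ornstein–Uhlenbeck, SD 0.3 z, 120-s correlation time — real
baselines are not white, and the baseline z-scale depends on it) +
photobleaching (exponential, amplitude 2, 15-min time constant — fastest
right after illumination onset) + shared motion artifacts (0.5/min,
2-s decay, 80 % shared with the reference) + white noise (SD 0.3). The
reference carries the bleach and shared artifacts plus its own noise,
not the neural signal.

The generator is a validation harness, not a biophysical model: it
encodes the two-component timing structure, dose scaling, and the
nuisance terms the pipeline must remove, with every parameter
configurable and all randomness drawn from `numpy.random.SeedSequence`
spawns of one master seed (whole cohorts are reproducible
bit-identically).

## Numerical choices

- All filters are from `scipy.signal`; the zero-phase low-pass uses
  `sosfiltfilt` with its default odd-extension padding.
- Rank statistics use `scipy.stats` (average ranks for ties).
- Regressions use `statsmodels` OLS (HC3 covariance).
- Every stochastic step takes an explicit `numpy.random.Generator`;
  the pipeline derives all of them from `RunConfig.seed` via
  `SeedSequence.spawn`, and `run_log.json` records the seed and a
  SHA-256 hash of the resolved configuration. Rerunning with the same
  cohort, seed and config reproduces the results tree bit-identically
  (asserted in the acceptance suite).

## Limitations

- The band-power onset p-values are not calibrated at standard session
  length (see above); they are descriptive there.
- The early-response template is built from training-dose sessions of the
  same cohort; with very few sessions (< 2 covering the model window) the
  model stage is skipped.
- The per-session lag grid spans ±1 min; sessions whose anticipatory
  onset jitters beyond the grid are fit at the grid edge with attenuated
  β₁ (such sessions are visible as β₁ outliers, e.g. `m02_s01` in the
  README example).
- Pseudosession nulls assume sessions are exchangeable under re-pairing;
  strong cohort-wide common structure (e.g. identical protocol timing)
  is preserved by the null and therefore not tested against.
- The generator does not model hardware dropout, non-exponential bleach,
  movement-correlated neural activity, or inter-subject template shape
  differences; conclusions from synthetic validation are about the
  pipeline's correctness, not about biology.
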