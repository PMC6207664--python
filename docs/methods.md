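# Methods

## The measurement problem

A drifting sinusoidal grating (1 cycle/degree, 4 degrees/s, 0.42 Michelson
contrast, 32 cd/m² background) is flashed for a brief, precisely controlled
duration, and the observer reports whether it moved left or right.
Performance as a function of duration yields a *duration threshold* (the
duration supporting 75% correct), and comparing a small (0.5° spatial-SD
Gaussian window) with a large (2°) grating quantifies *surround
suppression*: at high contrast, larger moving stimuli are typically harder
to discriminate. The package implements everything from stimulus timing to
group inference for a two-platform version of this test — a 120 Hz CRT and
a 60 Hz tablet — so platform equivalence can be studied.

## Stimulus timing model

Duration is controlled by a temporal Gaussian envelope on contrast, with
nominal duration defined as 2 × the envelope SD. A display realizes the
envelope as discrete frames. The quantization rule is:

- each frame's contrast is the Gaussian **sampled at the frame's vsync
  time** (the rule a real-time renderer implements: one contrast value is
  computed per frame);
- contrast is forced to exactly 0 for |t| > 2σ from the peak, boundary
  inclusive — the truncation implied by the duration definition itself;
- `peak_offset` (in frame periods) displaces the envelope peak relative to
  the vsync grid. 0 means the peak coincides with a frame; 0.5 is the
  tablet workaround that turns the shortest stimulus from an unusable
  single frame into two equal sub-peak frames, since motion is undefined
  within one frame.

Under this rule the shortest standard stimulus (0.01 s) occupies exactly
3 frames at 120 Hz, 1 frame at 60 Hz, and 2 frames at 60 Hz with the
half-frame displacement. Note that with vsync sampling the two displaced
60 Hz frames and the flanking 120 Hz frames all sample the envelope at
|t| = 1/120 s and therefore carry *equal* contrast; measured on-screen
luminance can differ between display technologies (CRT phosphor transients
vs LCD sample-and-hold), but photometric modeling is out of scope.

Spatial units are degrees of visual angle at a fixed 57 cm viewing
distance; pixel geometry, gamma correction and photometric calibration are
out of scope.

## Study design and the synthetic observer

The default `DesignSpec` is 13 participants × 2 platforms × 2 blocks per
platform × 2 parts of 140 trials; each part is one full factorial crossing
of 7 log-spaced durations (0.01–0.2 s) × 2 sizes × 2 directions × 5 initial
phases, shuffled. Platforms alternate across blocks, and the starting
platform alternates across participants so half the cohort starts on each.

Responses come from a parametric 2AFC observer:

    p(correct) = 0.5 + 0.5 · logistic((log10 d − log10 θ_size·platform) / s) − r(d)

with thresholds θ (default 0.02 s small, 0.05 s large — a suppression index
of log10(2.5) ≈ 0.4, the magnitude typical of healthy observers on this
task), slope s = 0.15 log10 units, and optional platform threshold factors
(multiplicative, hence additive in log10, matching how platforms are
compared). `r(d)` is an optional "reversal" dip — amplitude ×
exp(−(log10 d − log10 d_min)/decay) — that reproduces the below-chance
accuracy some human observers show at the very shortest durations
(plausibly driven by motion of the afterimage). The dip's size is a
convention, not an estimate, and it is off by default.

Cohorts add between-participant variability: a common log10 threshold shift
(SD 0.12) shared by both sizes plus independent size-specific shifts
(SD 0.08), and lognormal slope variability (SD 0.1). The common component
makes thresholds correlate across sizes and platforms within participants,
as real thresholds do. These SDs are design choices (roughly factor
1.3–1.6 individual differences, typical for duration thresholds); they are
not fitted to any dataset.

What the generator does *not* emulate: learning/fatigue across blocks,
serial dependencies, lapses at long durations, phase- or
direction-specific biases, and any genuine display-physics difference
between platforms. Passing tests therefore demonstrate that the analysis
machinery is correct and calibrated for binomially varying responses from
a logistic observer — not that any particular hardware pair is equivalent.

## Fitting

Trials are aggregated per (participant, platform, size) into per-duration
(n, k) counts. By the protocol's exclusion rule (on by default), tablet
trials at the grid's minimum duration are dropped before counting, because
the half-frame workaround produced anomalous performance there.

The psychometric model fixes γ = 0.5 and λ = 0 and estimates locations
μ_small, μ_large (log10 s) and a slope s, either shared (3 parameters) or
per size (4). Two routes:

- **ML** (default): direct maximization of the binomial log likelihood by
  damped Fisher scoring on (μ_small, μ_large, ln s), vectorized over a
  batch axis. Starting values are moment-based (locations from the
  interpolated 0.75 crossing of the empirical proportions, scale from
  0.2 × the log-duration span), with extra starts at 0.5×/2×/4× the scale
  because sparse psychometric likelihoods can be multimodal. Log
  likelihoods omit the binomial constant; only differences are ever used.
- **IRLS**: the equivalent binomial GLM via statsmodels with a custom
  guess-rate-adjusted logit link (η = logit((p − γ)/(1 − γ))), separate
  intercepts per size and shared or separate slopes on log10 duration.
  This is an independent implementation used for cross-validation; the two
  routes agree to well under 10⁻³ log10 units on clean data (enforced by
  tests).

Fits whose scale or locations escape to an effective boundary (scale below
10⁻³ or above 10× the sampled log-duration span, or locations more than
3 spans outside the data) are flagged `converged = False` — this is how
separable/degenerate data surface, rather than as silent garbage.

Model choice per participant × platform: the shared-slope fit is reported
unless the likelihood-ratio test (D = 2ΔLL against χ²₁) rejects at
α = 0.01, in which case the free-slope fit is reported. Goodness of fit is
the binomial deviance 2(LL_saturated − LL_model), with 0·log 0 = 0, and
its p-value comes from a parametric bootstrap of the fitted model.

Internally everything uses log10 durations; thresholds are invariant to the
log base (verified by test).

## Bootstrap

Parametric bootstrap throughout, B = 2000 by default: k* ~ Binomial(n,
p_fit) at every duration, refit with the same model structure (warm-started
at the parent estimate, batched). Non-converged refits are dropped and
counted; rates above 5% log a warning. CIs are equal-tailed percentile
intervals (default 99%) using **Hazen** plotting positions — one fixed,
documented quantile convention, since the convention visibly moves 99%
endpoints at B = 2000. Condition differences are tested by pairing
resamples by index, and declaring significance when the 0.5%–99.5%
interval of the differences excludes zero; the bootstrap deviance p-value
uses the add-one rule p = (1 + #{D* ≥ D_obs})/(B_ok + 1), so p = 0 is
impossible.

## Nonparametric cross-check

A kernel local-linear binomial smoother on the guess-rate-adjusted logit
scale: at each evaluation point a 2-parameter weighted likelihood is
maximized with Gaussian kernel weights; the bandwidth is chosen from a
small grid (multiples 1–5 of the median grid spacing) by leave-one-out
deviance; the threshold is the smallest 0.75 crossing of the smoothed
curve, with NaN as the distinguished "never reaches criterion" value.
Because it maximizes a weighted likelihood rather than transforming
observed proportions, below-chance cells are handled without special
casing. It is a deliberately simple stand-in for the local-linear fitting
tradition of the R *modelfree* package, whose exact bandwidth-selection
internals are not reproduced here; on well-behaved data it agrees with the
logistic threshold within 0.05 log10 units (enforced by test).

## Group statistics

All group analyses run on log10 thresholds: Pearson correlations between
platforms (two-sided t-based p, df = n − 2), a 2×2 within-subject ANOVA
(size × platform) computed via the contrast identity — for two-level
factors each effect's F(1, n−1) is exactly the squared paired t on the
within-participant contrast, cross-checked in tests against an independent
sums-of-squares decomposition and against pingouin — a paired t on the
suppression index across platforms, and geometric means with t-based CIs
(computed in the log domain). Two-sided p-values throughout; no
multiple-testing correction (per-test α conventions: 0.01 for
bootstrap/LRT/deviance decisions, 0.05 elsewhere).

## Numerical and design choices

- Probabilities are clipped to [1e−12, 1 − 1e−12] inside likelihoods;
  the lower asymptote γ = 0.5 keeps log p finite without clipping below.
- Fisher scoring uses a tiny ridge (1e−9 × mean diagonal) and step capping
  (max component 10) for stability on near-degenerate resamples.
- The duration grid is geometric (`np.geomspace`); the envelope truncation
  constant (2 SD) *is* the duration definition, not a tunable.
- Seeds: one master seed per study; per-participant and per-fit streams are
  spawned deterministically (`numpy` `SeedSequence`), so any participant or
  bootstrap can be regenerated in isolation and whole-pipeline outputs are
  byte-identical across reruns.
- Default problem sizes in the test suite (e.g. 80–200 trials/duration,
  100–200 replicates for calibration checks, B = 1000–2000) were chosen as
  the smallest sizes at which the binomial Monte-Carlo error is comfortably
  below the tolerances being asserted.

## Known limitations

- The exact-ML threshold is *not* guaranteed monotone under added correct
  trials at long durations: with λ fixed at 0, top-duration successes also
  steepen the (shared) slope and can nudge a location slightly upward. The
  provable monotonicity (location non-increasing in success counts at fixed
  slope) is what the tests assert.
- The reported platform comparison assumes independent bootstrap streams
  per platform; only index pairing (not all-pairs differencing) is
  implemented.
- No lapse-rate estimation; observers with genuine lapses will bias slopes
  shallow and thresholds long.
- The stimulus model stops at per-frame contrast; luminance-over-time
  waveforms of specific display technologies are not modeled.
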