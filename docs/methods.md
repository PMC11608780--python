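# Methods

## Signals and preprocessing

Skin conductance (µS, 250 Hz) is cleaned by a centered running median of
1-s width (window forced odd; edges use shrinking windows, so a constant
signal is a fixed point exactly) followed by a zero-phase 4th-order
Butterworth low-pass at 1 Hz. The filter family and order are our choice —
only "low-pass at 1 Hz" is a given — and the zero-phase (forward–backward)
application matters: any phase lag would bias the zero-lag pairwise
correlations that the concordance index is built from.

Inter-beat intervals (ms) are screened against a running median over 11
beats; a beat is flagged when it deviates by more than
`threshold × 1.4826 × local MAD`, with the local MAD computed canonically as
the median absolute deviation of the 11 window samples about the window
median and the 1.4826 factor making it a consistent σ estimate. (The
superficially simpler "median of the deviation series" collapses to zero on
locally monotone data, because the running median of such data equals the
center sample.) Flagged beats are replaced by a cubic spline over beat index
through the unflagged neighbours, and the flag–interpolate step iterates to
a fixed point (≤ 10 passes) so that correction is idempotent; more than 50%
flagged raises a data-quality error, mirroring participant exclusion.
Corrected intervals are then cubic-spline interpolated over beat time and
resampled on a uniform 32 Hz grid spanning first to last beat, yielding a
heart-period series in ms.

## The concordance index

Slopes are ordinary-least-squares fits of value against time in 5-s windows
advanced by 1 s. OLS is our resolution of an ambiguity: "average slope"
could also mean the endpoint difference over the span (the mean of first
differences telescopes to exactly that), so `slope_method="endpoint"` is
kept as an alternative; OLS is the default because it is robust to sample
noise within the window. Pairs are aligned on their common time span,
windows of 15 slopes advance by 1 slope, and windows where either side has
zero variance are skipped (Pearson r is undefined there) and reported in
`n_skipped` rather than being scored 0. The index
`ln((Σr⁺ + ε)/(Σ|r⁻| + ε))` uses a symmetric ε = 10⁻⁶ so that negating one
series negates the index exactly and a pair with no negative correlations
stays bounded. The log transform is applied per pair *before* per-participant
averaging.

### The index is not zero-mean under independence

A property worth knowing: for two *independent* signals made of same-shaped
skin-conductance responses (fast rise, slow decay), the index has a small
positive expectation (≈ +0.09 at the default event rate; the per-window
correlation bias is ≈ +0.016). Two SCR tails decaying in the same window
co-vary positively regardless of any shared drive. The implementation is
unbiased on i.i.d. and sign-symmetric series (checked against a brute-force
oracle), so this is a property of the statistic on transient-shaped
physiology, not of the code — and it is precisely why inference rests on the
surrogate test rather than on the raw index.

## Surrogate (permutation) test

Each participant's preprocessed signal is segmented into 1-s epochs,
shuffled independently per participant with a seeded generator, and the full
slope → concordance → participant-average → one-sample-t chain is re-run per
permutation; `p = erfc((|s−μ₀|/σ₀)/√2)` from the null mean and SD. The
shuffle operates on preprocessed signals, with slopes recomputed per
permutation.

Calibration, measured by simulation: on groups of independent white-noise
signals — where epoch shuffling is exactly exchangeable — the test holds its
level (7/100 rejections at α = .05 over 100 seeded runs; Kolmogorov distance
from uniform 0.062). On smooth SCR-shaped signals at coupling 0 the test is
*conservative* (1/100): shuffling 1-s pieces of a 1-Hz-lowpassed signal
destroys the co-decay structure that lifts the observed index, while the
step discontinuities it introduces overdisperse the null t (SD ≈ 1.85 vs
≈ 1.50 observed). Re-preprocessing after shuffling makes the test
anticonservative (≈ 19%) and is not used. Conservative error keeps positive
findings trustworthy; power is high regardless — at coupling 0.8 (n = 8,
120-s signals, 200 permutations) the test rejects in 49/50 seeded runs.

## Behavioral scoring

A press episode at level 4 contributes 1, at level 5 contributes 2; levels
1–3 and episode durations contribute nothing. "Number of responses" is read
as number of press episodes (the protocol is press-and-hold, one press per
feeling change); a seconds-held alternative is available behind
`weight_by_duration` for sensitivity analysis. Knowledge scores are Hamming
weights of the 10-item binary response vectors; knowledge similarity is the
pairwise cosine of those vectors averaged per participant, with pairs
involving an all-zero vector excluded (cosine undefined) and logged.

## Study-level statistics

Two-sample t-tests are pooled-variance, with Cohen's d on the pooled SD and
a 95% CI by noncentral-t inversion (with a normal fallback where scipy's
noncentral CDF underflows, around |t| ≳ 20). JZS Bayes factors integrate the
noncentral-t marginal likelihood against a Cauchy(0, 0.707) effect-size
prior by adaptive quadrature split at the likelihood peak (relative
tolerance 10⁻⁸); the implementation agrees with an independent fine-grid
quadrature and with `pingouin.bayesfactor_ttest` to 10⁻⁶ relative.
Correlation BFs are delegated to pingouin. Overlapping dependent
correlations are compared with the Hittner et al. (2003) modification of
Dunn & Clark's z (the family member is recorded in output metadata, since
several variants exist).

Mediation fits the three standardized OLS equations with the binary group
dummy left 0/1 and all continuous variables z-scored on the full sample
(paths are standardized βs); an optional covariate enters every equation.
The indirect effect is identically `a·b` from the same fitted equations, and
its 95% CI is a seeded percentile bootstrap (default 5000 paired resamples
of complete rows; degenerate resamples with one group absent are redrawn).
Percentile, not bias-corrected, matches the common default of the PROCESS
macro. Fewer than 10 complete cases is refused.

## Synthetic data generator

The generator emulates the study design: two groups of 24, ~10-minute
recordings.

* **Skin conductance** = tonic baseline (5 µS) + Gaussian random-walk drift
  (0.02 µS·s⁻½) + SCR-shaped phasic events + white noise (0.01 µS). The SCR
  kernel is a difference of exponentials (1-s rise, 4-s decay, unit peak),
  amplitudes log-normal around 0.4 µS. Events arrive at 0.05 Hz (3/min, a
  realistic nonspecific-SCR rate). A group-level Poisson event pool is
  shared: each participant keeps a pool event with probability equal to
  their coupling (plus 0.2-s onset jitter) and adds idiosyncratic events at
  the complementary rate, so the marginal SCR rate is coupling-invariant and
  concordance arises through co-fluctuation of slopes. Default coupling:
  0.7 (analytical) vs 0.2 (historical).
* **Heart period**: beats at 800 ± 50 ms, slow smooth modulation (cubic
  spline through N(0,1) knots every 10 s) mixed from a shared and an
  idiosyncratic component with weight 0.5 in both groups (heart-period
  concordance is present but not group-specific), 10-ms beat jitter, and
  isolated artifact beats (doubled or halved, 1/min by default) flagged in
  the ground truth.
* **Ratings**: per-level episode counts are Poisson (level-4 mean
  `liking_base` = 3, level-5 mean half that, plus a few low-pleasure
  episodes); episodes are placed without overlap by pairing sorted uniform
  time points.
* **Knowledge**: per-item Bernoulli with probability 0.35 pre and 0.78 post
  on the learned test (matching observed pre/post score levels of ~3.2 and
  ~7.8 of 10), 0.35 throughout on the other test, with a per-item easiness
  spread of SD 0.15 shared across participants (this shared item structure
  is what makes response vectors overlap).
* **Mediation truth**: with group dummy x, a latent alignment score
  m = a·x + e is drawn with unit marginal variance, and the outcome
  y = b·m + c′·x + e′ likewise. The residual e shifts that participant's
  event-pool coupling (0.15 per SD), so *measured* concordance is a noisy
  monotone correlate of m; y is carried into the post-learning rating stream
  as an integer liking-index change `round(2.7 + 3·y)` (the rounding noise
  attenuates recovered paths by < 2%). Structural-parameter recovery
  therefore runs on (x, m, liking change); the measured concordance enters
  the qualitative end-to-end checks. The empathy covariate loads 0.35 on m.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning (structural draws, each group's signals, ratings, knowledge), so a
fixed seed fixes every artifact exactly.

### What the generator does not emulate

Real EDA nonstationarity (habituation, electrode drift episodes), respiratory
sinus arrhythmia and other structured HRV, floor effects in low-responders,
missing data, and any content-driven temporal structure in the shared
arousal process (events are homogeneous Poisson). Passing tests show the
pipeline's statistics behave as designed under a plausible arousal model —
not that the physiological claims hold for real learners.

## Problem sizes and test design

Simulation-based checks run at reduced but adequate scale: calibration and
power use 8 participants, 120-s signals and 200 permutations over 100/50
seeded runs; parameter recovery uses 20 studies of 24/group with
1000-resample bootstraps; monotonicity of concordance in coupling uses
groups of 6 at 300 s over 20 seeds per coupling level. The
independence-index Monte-Carlo uses 2400-s signals so that 50 replicates
give a standard error (≈ 0.026) small against the quantity being bounded.
At the study-scale mediation effects (a = 0.6, b = 0.5) the indirect-effect
CI excludes zero in only ~60% of replicate studies — consistent with the
original design's borderline interval — so the end-to-end pattern check uses
a = 0.8, b = 0.7, where replication power is essentially full (23/25), and
the study-scale configuration is exercised by the recovery tests instead.

## Known limitations

The concordance index's positive offset under independence means raw PSC
values are not comparable across signal classes with different transient
shapes; only surrogate-calibrated statements are. The erfc p-value assumes
an approximately normal surrogate null. The mediation decomposition on the
measured concordance can show suppression (unstable c′/b split) when the
group gap in PSC is large enough to make the dummy and the mediator nearly
collinear, as the worked example illustrates; the total effect and `c′+a·b`
remain stable. Bootstrap CIs are percentile and first-order accurate only.
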