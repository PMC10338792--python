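# Methods

## The event-time representation

A reaction-time trial series is a sequence of latencies Y(n), n = 1..N,
in operational (trial-number) time.  The event-time transform treats
each latency as a duration: latencies are rounded to the nearest integer
millisecond (minimum one sample, so sub-half-millisecond abstract-unit
waiting times still occupy one grid cell), each duration is filled with
a constant value of magnitude 1 whose sign is drawn by an independent
fair coin per interval, and the intervals are concatenated on a uniform
1-ms grid.  Inter-trial gaps (post-response and pre-onset periods) are
discarded, so X(t) is a concatenation of event durations, not continuous
clock time.  Because the signs are random, X(t) is an ensemble; every
scaling index reported for X(t) is the mean over independent sign
realizations (default 100), with its SD.

## DFA

The scaling index α is estimated by standard first-order detrended
fluctuation analysis: integrate the mean-subtracted signal to a profile;
partition the profile into consecutive non-overlapping windows of length
w (trailing remainder discarded); remove a least-squares line per
window; F(w) is the RMS residual over covered points; α is the OLS slope
of log₁₀ F(w) against log₁₀ w.  Choices worth stating:

- **RMS, not mean square.**  F(w) is the *root* mean square residual;
  without the root all slopes double.
- **Mean subtraction** before integration is retained for
  level-independence of the profile.  For first-order detrending it
  provably does not change F(w) (it shifts the profile by an affine
  function of time, which the per-window line removes exactly), so both
  internal code paths agree to rounding error.
- **Window grid**: 16 log-spaced integer sizes from 4 (trial domain) or
  16 (event domain) up to N/4, duplicates dropped; the slope is fitted
  on the full grid unless a `fit_range` is set.  These are conventions,
  exposed in `DFAConfig`.
- **Anchors** (verified in the test suite): i.i.d. input → α = 0.5;
  integrated i.i.d. input → α = 1.5; globally affine profiles → F ≡ 0.

### The block algorithm

X(t) is piecewise constant, so its profile is piecewise affine.  The
event-domain engine (`eventdfa._blockdfa`) evaluates every per-window
line fit and residual sum in closed form over the pieces obtained by
intersecting windows with intervals, at cost O(N/w + n_intervals) per
window size instead of O(N).  This matters because heavy-tailed waiting
times with μ ≤ 2 routinely produce series of 10⁷–10⁸ samples.  The
block path is exact: the suite verifies agreement with a naive
triple-loop reference (and with the materialized reshape path) to
better than 10⁻⁹ relative error.

## Waiting-time model and calibration

Renewal waiting times with temporal-complexity index μ are generated by
the idealized Manneville map τ = T·(y^(−1/(μ−1)) − 1), y ~ U(0,1),
whose density ψ(τ) = (μ−1)·T^(μ−1)/(τ+T)^μ is normalized with survival
(T/(T+t))^(μ−1).  For 1 < μ < 3 the process is complex (crucial
events); μ = 2 separates infinite from finite mean waiting time and is
the 1/f point (β = 1).

The calibration module measures the ensemble event-time α of simulated
renewal series across a μ grid and fits the line that is well
approximated by μ = 4 − 2α; the identities β = 3 − μ = 2α − 1 connect
to the spectral index.  Two simulation choices are deliberate:

- **Abstract time units (T = 1).**  Waiting times enter the event grid
  at O(1) samples per event.  The α(μ) relation is a statement about
  scales *above* the mean waiting time; if the simulated durations are
  instead scaled to empirical millisecond magnitudes (hundreds of
  samples per event), every DFA window up to N/4 sits inside or near
  single intervals, the measured slope saturates near the ballistic
  value (≈1.2 regardless of μ), and the calibration line disappears.
- **Sample-length matching.**  Simulated trajectories are built to a
  target *sample length* — 176,400 samples for the session regime
  (≈360 trials × ~490 ms mean latency) and 6× that for the appended
  regime — by drawing events until the rounded durations reach the
  target and trimming the last interval.  This pins the comparison to
  the empirical X(t) lengths while letting the event count float with
  μ, and bounds runtime and memory for the infinite-mean regime.

With these choices the simulated mean α recovers (4 − μ)/2 within
±0.065 for μ ∈ {1.6, 2.0, 2.4, 2.8} at both regimes (tolerance ±0.1 in
the acceptance suite).  Residual deviations are the known finite-length
transients: upward bias near μ = 3 (slow convergence of the
superdiffusive moment) and downward bias near the ballistic edge μ → 1.
Direct spectral estimation of β from short empirical series is out of
scope by design; the event-time route exists precisely because short
series defeat periodogram slopes.

## Shuffling controls

Permuting the trial order destroys temporal correlations in Y(n)
(trial-domain α of the shuffled series ≈ 0.5) but leaves the duration
multiset, hence the statistics of X(t), unchanged.  The surrogate
module reports α_Y and α_X for original and shuffled series (default 20
permutations; medians and IQRs alongside means).  Two caveats
established numerically: the α_X ensemble *distribution* is strictly
order-invariant only when durations are bounded (e.g. pruned-range
latencies); for unbounded μ ≤ 2 tails the position of a single dominant
interval moves the mean by up to ~0.05 at N ≈ 2000 events — within the
invariance band used for acceptance, but visible to a two-sample KS
test.

## Study pipeline

Per subject × condition the pipeline computes, at the single-session
and the six-sessions-appended time scales: the commission-error rate
(responses to friendly targets, computed before pruning), the
trial-domain α_Y of the pruned latencies (100 ms < RT < 1500 ms, strict
bounds; non-response trials dropped; commission-trial latencies
retained), and the ensemble event-time α_X.  Summaries follow the
field's reporting conventions: medians with 0.25/0.75 quantiles (linear
interpolation) by condition; Wilcoxon matched-pairs signed-rank tests
of the low/high contrast (zero differences dropped, mid-ranks,
tie-corrected variance, no continuity correction — the normal
approximation, cross-checked in the tests against an exact enumeration
and against scipy); and per-condition OLS of commission errors on each
scaling index with Estimate/SE/t/p/adjusted R² (statsmodels).  No
multiple-testing correction is applied.  Session-level paired tests
default to within-subject means across sessions (n = subjects);
pairing subject × session observations (n = subjects × sessions) is
available via `session_pairing="session"`.

## Synthetic cohort

The generator emulates the study design: 30 subjects × 6 sessions × 2
time-stress conditions × 360 trials, 324 enemy : 36 friendly targets
per session, 2–5% omissions on enemy trials, latencies strictly inside
(100, 1500) ms.  Latency = Gaussian perceptual-motor base
(320 ± 40 ms) + Manneville decision time (T = 300 ms; condition index
μ_low = 2.5, μ_high = 2.6, per-subject shift U(−0.1, 0.1) shared across
conditions), rejection-sampled below the subject's exposure cap.  The
cap is the time-stress manipulation (842.78 ± 216.65 ms low,
547.96 ± 223.20 ms high); a subject's caps are correlated across
conditions (ρ = 0.8), emulating the per-subject psychophysical
thresholding that makes the low-stress cap exceed the high-stress cap
within nearly every subject.  T and the base were fixed once by
quadrature so the truncated means land near the reported 529/441 ms
condition means.

Commission probability is logistic in *both* the implied complexity
index (4 − μ)/2 (coupling −3) and the exposure cap (−0.30 per 100 ms),
with intercept 0.95 targeting condition rates near 0.17/0.33.  The
exposure term is essential, not cosmetic: for bounded millisecond-scale
durations the measurable α_X variation across subjects and conditions
is driven by the duration *scale* (≈ +0.01 α per +100 ms of exposure),
not by μ (dα/dμ ≈ 0.01 per unit μ under truncation), so a commission
model coupled only to μ would decouple performance from the measurable
index and no regression structure would exist.  With both couplings the
default cohort reproduces the target sign structure: median α_X(low) >
α_X(high) with Wilcoxon p < 10⁻⁵, strongly negative commission-on-α_X
slopes, and a near-null trial-domain contrast.

**What the cohort does not emulate.**  Real latency sequences are not
conditionally i.i.d.; the generator produces no long-range order in
Y(n), so trial-domain α_Y sits near 0.5 rather than the ~0.6 seen in
real data, and the absolute α_X magnitudes (≈1.13 session, ≈0.97
appended) are scale-regime quantities, not the (4 − μ)/2 values of the
abstract-unit calibration — under (100, 1500) ms truncation the
waiting-time index is not identifiable from α_X, which is why the α↔μ
inversion is validated on the calibration simulations rather than on
the cohort.  Passing pipeline tests therefore demonstrate the
machinery and the direction/significance structure, not recovery of μ
from bounded empirical-style data.  Learning across sessions, spatial
target layout and exposure-duration adaptivity are not modeled.

## Numerical and statistical conventions

- One master seed drives every stochastic stage; per-realization
  streams derive from it deterministically, so fixed seeds give
  byte-identical pipeline outputs.
- Degenerate inputs raise typed errors: pruning with lo ≥ hi, commission
  rate without friendly trials, all-zero Wilcoxon differences, constant
  regression predictors, F(w) = 0 inside a fit range, windows too large
  for the profile.
- Subjects/conditions with fewer than `min_trials` (default 64) pruned
  trials are excluded with a logged warning.
- Problem sizes in the test and acceptance suites (20 seeds × 100 sign
  realizations for the 1/f anchor; 20 draws × 5 realizations per μ for
  calibration; 10 cohorts for the pipeline checks; ensemble 25 for
  cohort-scale runs) were chosen as the smallest giving Monte-Carlo
  error comfortably below the stated tolerances.
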