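# eventdfa

Temporal complexity of reaction-time series via **event-time detrended
fluctuation analysis (DFA)**.

## The problem

Sequences of reaction-time latencies from Go/NoGo tasks carry structure
beyond their marginal distribution: inverse-power-law (1/f-like)
variability that indexes the flexibility of the underlying
perceptual-motor process.  The conventional analysis treats the latency
series Y(n) as a signal in *operational time* (trial number n) and
estimates a scaling index α by DFA.  For short, ecologically realistic
tasks (a few hundred trials per condition) that estimate is unstable and
insensitive.

`eventdfa` implements the *event-time* alternative: each latency is
treated as a **duration** on a 1-ms grid, each duration is filled with a
constant value of magnitude 1 and a random sign (fair coin per
interval), and the filled intervals are concatenated — inter-trial gaps
are discarded — to form the event-time signal X(t).  DFA of X(t),
ensemble-averaged over the random sign assignments, yields a scaling
index α that:

- connects to the temporal-complexity index μ of the underlying renewal
  (crucial-event) process through the simulated calibration
  **μ = 4 − 2α**, and to the spectral index of S(f) ∝ f^−β via
  **β = 3 − μ = 2α − 1** (α = 1 is the 1/f-noise point);
- is insensitive to trial order — shuffling the trials collapses the
  trial-domain index to α ≈ 0.5 (randomness) but leaves the event-time
  index unchanged, the operational signature of renewal statistics;
- separates task conditions (time stress) and predicts performance
  (commission errors) where the trial-domain index does not.

DFA itself follows the standard recipe: integrate the mean-subtracted
signal to a profile S, partition into non-overlapping windows of length
w, remove a least-squares line per window, and fit the slope α of
log₁₀ F(w) vs log₁₀ w, where F(w) is the RMS residual over covered
points.

The package bundles the full study-level pipeline (latency pruning to
100 ms < RT < 1500 ms, session concatenation, commission-error rates,
Wilcoxon matched-pairs contrasts, commission-on-α regressions), an
idealized Manneville-map waiting-time simulator
τ = T·(y^(−1/(μ−1)) − 1), the α↔μ calibration machinery, shuffling
controls, and a synthetic-cohort generator (30 subjects × 6 sessions ×
2 time-stress conditions × 360 trials) so every stage is testable
without any external dataset.

## Worked example

```python
import numpy as np
from eventdfa import (
    MannevilleParams, draw_waiting_times, ensemble_event_alpha,
    mu_from_alpha, beta_from_alpha,
)

rng = np.random.default_rng(1)
tau = draw_waiting_times(MannevilleParams(mu=2.0, T=1.0), 2160, rng)
ens = ensemble_event_alpha(tau, n_realizations=100, rng=rng)
print(f"alpha = {ens.mean:.3f} +/- {ens.sd:.3f}")
print(f"implied mu   = {mu_from_alpha(ens.mean):.2f}")
print(f"implied beta = {beta_from_alpha(ens.mean):.2f}")
```

prints

```
alpha = 1.051 +/- 0.030
implied mu   = 1.90
implied beta = 1.10
```

i.e. waiting times generated at the 1/f point (μ = 2) are read back from
the event-time representation as α ≈ 1 with the implied μ ≈ 2 and
β ≈ 1, from only 2160 events.  The same analysis on a cohort trial table:

```python
from eventdfa import CohortDesign, generate_cohort, StudyAnalysis, StudyConfig

table = generate_cohort(CohortDesign(), np.random.default_rng(7))
results = StudyAnalysis(table, StudyConfig(ensemble_size=50)).fit(seed=7)
print(results.summary())
```

reports, among other tables, the low/high time-stress contrast of the
event-time index (Wilcoxon Z = 4.64, p < 10⁻⁵, low > high) and strongly
negative commission-on-α_X regression slopes, while the trial-domain
index shows only a marginal contrast — the qualitative pattern the
event-time representation is designed to expose.

A CLI mirrors the library: `eventdfa simulate | analyze | transform |
dfa | calibrate | shuffle-test` (see `eventdfa --help`).

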