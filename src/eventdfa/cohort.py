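"""Synthetic Go/NoGo cohort emulating the study design.

Generates per-trial reaction-time tables for a cohort performing a
shooting-task Go/NoGo under two time-stress conditions, shaped like the
original design: 30 subjects x 6 sessions x 2 conditions x 360 trials,
a 0.90/0.10 enemy/friendly target mix (324:36 per session), latencies
strictly inside (100, 1500) ms, a few percent omissions on enemy trials,
and commission errors (responses to friendly targets) negatively coupled
to the subject's implied temporal-complexity index and to the exposure
duration.

Generative model per subject s and condition c:

* latency = base + tau, with base ~ N(320, 40) ms (perceptual-motor
  floor) and tau an idealized-Manneville waiting time with index
  mu_{s,c} = mu_c + subject shift (shift ~ U(-0.1, 0.1), shared across
  conditions) and time constant T_ms; draws are rejected until
  latency < exposure cap.
* the exposure cap (target exposure duration) is the time-stress
  manipulation: cap_{s,c} = mean_c + sd_c * (rho * z_s +
  sqrt(1 - rho^2) * z_{s,c}), clipped into (300, 1490) ms.  The shared
  subject component z_s (rho = 0.8) emulates the per-subject
  psychophysical thresholding of the original task, which makes the
  low-stress cap exceed the high-stress cap within nearly every subject.
* commission probability = logistic(b0 + b_alpha * alpha_implied +
  b_exp * (cap - 700)/100), with alpha_implied = (4 - mu_{s,c})/2.  Both
  couplings are negative: more temporal complexity and longer exposure
  each reduce commission errors, mirroring the study's observed
  condition effect and the negative slope of commission on the
  event-time scaling index.

Everything is driven by a single seeded generator; a JSON sidecar
records the design parameters next to any written fixture.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ParameterError
from .manneville import MannevilleParams, draw_waiting_times
from .trials import TRIAL_COLUMNS, write_trial_table

__all__ = ["CohortDesign", "generate_cohort", "write_fixture_csv"]


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of the synthetic cohort generator (defaults = study shape)."""

    n_subjects: int = 30
    n_sessions: int = 6
    trials_per_condition: int = 360  # per session
    friendly_fraction: float = 0.10
    mu_low: float = 2.5
    mu_high: float = 2.6
    subject_mu_jitter: float = 0.1
    #: target exposure duration (ms): mean and SD per condition
    exposure_mean_low: float = 842.78
    exposure_sd_low: float = 216.65
    exposure_mean_high: float = 547.96
    exposure_sd_high: float = 223.20
    #: cross-condition correlation of a subject's exposure caps
    exposure_subject_rho: float = 0.8
    #: latency model: base ~ N(base_mean, base_sd) plus Manneville tau
    base_mean_ms: float = 320.0
    base_sd_ms: float = 40.0
    latency_T_ms: float = 300.0
    #: commission logistic: b0 + b_alpha * alpha_implied + b_exp * (cap-700)/100
    commission_intercept: float = 0.95
    commission_coupling: float = -3.0
    exposure_coupling: float = -0.30
    omission_range: Tuple[float, float] = (0.02, 0.05)
    rt_bounds: Tuple[float, float] = (100.0, 1500.0)

    def __post_init__(self) -> None:
        for mu in (self.mu_low, self.mu_high):
            if not 1.0 < mu < 3.0:
                raise ParameterError(f"mu must lie in (1, 3), got {mu}")
        if not 0.0 < self.friendly_fraction < 1.0:
            raise ParameterError("friendly_fraction must lie in (0, 1)")
        if self.commission_coupling >= 0:
            raise ParameterError("commission_coupling must be negative")
        lo, hi = self.omission_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ParameterError("invalid omission_range")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _draw_latencies(
    n: int,
    mu: float,
    cap: float,
    design: CohortDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-sample n latencies strictly inside (lo, min(cap, hi))."""
    lo, hi = design.rt_bounds
    upper = min(cap, hi)
    params = MannevilleParams(mu=mu, T=design.latency_T_ms)
    out = np.empty(0)
    while out.size < n:
        m = max(2 * (n - out.size), 64)
        base = rng.normal(design.base_mean_ms, design.base_sd_ms, size=m)
        base = np.clip(base, lo + 100.0, None)
        rt = base + draw_waiting_times(params, m, rng)
        rt = rt[(rt > lo) & (rt < upper)]
        out = np.concatenate([out, rt])
    return out[:n]


def generate_cohort(
    design: CohortDesign = CohortDesign(),
    rng: Optional[np.random.Generator] = None,
    return_truth: bool = False,
):
    """Generate the cohort trial table (and optionally the ground truth).

    Returns a frame with the standard trial-table columns; with
    ``return_truth=True`` also a per subject x condition frame of the
    latent parameters (mu, implied alpha, exposure cap, commission
    probability, omission rates).
    """
    if rng is None:
        rng = np.random.default_rng()
    d = design
    n_trials = d.trials_per_condition
    n_friendly = int(round(d.friendly_fraction * n_trials))

    rows = []
    truth_rows = []
    z_subject = rng.standard_normal(d.n_subjects)
    mu_shift = rng.uniform(-d.subject_mu_jitter, d.subject_mu_jitter, d.n_subjects)
    for s in range(d.n_subjects):
        subject = f"S{s + 1:02d}"
        for cond, mu_c, cap_mean, cap_sd in (
            ("low", d.mu_low, d.exposure_mean_low, d.exposure_sd_low),
            ("high", d.mu_high, d.exposure_mean_high, d.exposure_sd_high),
        ):
            rho = d.exposure_subject_rho
            z = rho * z_subject[s] + np.sqrt(1 - rho * rho) * rng.standard_normal()
            cap = float(np.clip(cap_mean + cap_sd * z, 300.0, 1490.0))
            mu_sc = float(np.clip(mu_c + mu_shift[s], 1.05, 2.95))
            alpha_implied = (4.0 - mu_sc) / 2.0
            p_comm = float(
                expit(
                    d.commission_intercept
                    + d.commission_coupling * alpha_implied
                    + d.exposure_coupling * (cap - 700.0) / 100.0
                )
            )
            omis = rng.uniform(*d.omission_range, size=d.n_sessions)
            truth_rows.append(
                {
                    "subject": subject,
                    "condition": cond,
                    "mu": mu_sc,
                    "alpha_implied": alpha_implied,
                    "exposure_cap_ms": cap,
                    "p_commission": p_comm,
                    "omission_rates": omis.mean(),
                }
            )
            for sess in range(1, d.n_sessions + 1):
                friendly = np.zeros(n_trials, dtype=bool)
                friendly[rng.permutation(n_trials)[:n_friendly]] = True
                responded = np.empty(n_trials, dtype=bool)
                responded[~friendly] = rng.random(n_trials - n_friendly) >= omis[sess - 1]
                responded[friendly] = rng.random(n_friendly) < p_comm
                rt = np.full(n_trials, np.nan)
                n_resp = int(responded.sum())
                rt[responded] = _draw_latencies(n_resp, mu_sc, cap, d, rng)
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subject,
                            "session": sess,
                            "condition": cond,
                            "trial": np.arange(1, n_trials + 1),
                            "rt_ms": rt,
                            "target_type": np.where(friendly, "friendly", "enemy"),
                            "responded": responded.astype(np.int64),
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)[TRIAL_COLUMNS]
    if return_truth:
        return table, pd.DataFrame(truth_rows)
    return table


def write_fixture_csv(
    table: pd.DataFrame, path, design: Optional[CohortDesign] = None
) -> None:
    """Write the cohort table as a schema-conforming CSV fixture.

    When ``design`` is given, the generator parameters are recorded in a
    JSON sidecar at ``<path>.params.json``.
    """
    write_trial_table(table, path)
    if design is not None:
        design.to_json(f"{path}.params.json")
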