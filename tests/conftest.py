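"""Shared fixtures and independent reference implementations."""

import numpy as np
import pandas as pd
import pytest


def naive_window_fluctuation(profile, w, order=1):
    """Triple-loop reference for F(w): independent of the package paths.

    Walks window by window, fits the polynomial with np.polyfit per
    window, and accumulates squared residuals point by point.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    n_win = n // w
    ss = 0.0
    count = 0
    for q in range(n_win):
        seg = profile[q * w : (q + 1) * w]
        t = np.arange(w, dtype=float)
        coef = np.polyfit(t, seg, order)
        for j in range(w):
            fitted = np.polyval(coef, t[j])
            ss += (seg[j] - fitted) ** 2
            count += 1
    return np.sqrt(ss / count)


@pytest.fixture(scope="session")
def naive_F():
    return naive_window_fluctuation


def make_trial_frame(rts, target_types=None, responded=None, session=1):
    """Build a TrialSeries backing frame from plain lists.

    ``rts`` may contain None for non-response trials.
    """
    n = len(rts)
    if target_types is None:
        target_types = ["enemy"] * n
    if responded is None:
        responded = [rt is not None for rt in rts]
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "rt_ms": [np.nan if rt is None else float(rt) for rt in rts],
            "target_type": target_types,
            "responded": responded,
            "session": session,
        }
    )


@pytest.fixture(scope="session")
def trial_frame_factory():
    return make_trial_frame
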