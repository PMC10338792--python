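"""Idealized Manneville-map generator of renewal waiting times.

The idealized map transforms uniform variates y in (0, 1) into waiting
times

    tau = T * (y**(-1/(mu-1)) - 1),

which are i.i.d. draws from the normalized inverse-power-law density

    psi(tau) = (mu - 1) * T**(mu-1) / (tau + T)**mu,   tau >= 0,

with survival function (T / (T + t))**(mu-1).  The index mu is the
temporal-complexity index: for 1 < mu < 3 the renewal process is complex
(crucial events); mu = 2 separates infinite (mu < 2) from finite (mu > 2)
mean waiting time and maps to the 1/f-noise point of the spectrum; for
mu > 3 the dynamics is ordinary.  T sets the microscopic time scale and is
dimensionless (grid units) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, ParameterError

__all__ = [
    "MannevilleParams",
    "waiting_time_from_uniform",
    "draw_waiting_times",
    "waiting_time_pdf",
    "waiting_time_survival",
]


@dataclass(frozen=True)
class MannevilleParams:
    """Parameters (mu, T) of the idealized Manneville waiting-time law."""

    mu: float
    T: float = 1.0

    def __post_init__(self) -> None:
        if not self.mu > 1:
            raise ParameterError(f"mu must be > 1, got {self.mu}")
        if not self.T > 0:
            raise ParameterError(f"T must be > 0, got {self.T}")

    @property
    def is_complex_regime(self) -> bool:
        """True when 1 < mu < 3 (crucial-event / complexity regime)."""
        return 1.0 < self.mu < 3.0

    @property
    def mean_waiting_time(self) -> float:
        """T / (mu - 2) for mu > 2; infinite otherwise."""
        return self.T / (self.mu - 2.0) if self.mu > 2.0 else np.inf


def waiting_time_from_uniform(y, params: MannevilleParams):
    """Deterministic map y in (0, 1) -> tau (the inverse-CDF transform)."""
    y = np.asarray(y, dtype=np.float64)
    if np.any(y <= 0) or np.any(y >= 1):
        raise InvalidInputError("uniform variates must lie strictly in (0, 1)")
    return params.T * (y ** (-1.0 / (params.mu - 1.0)) - 1.0)


def draw_waiting_times(
    params: MannevilleParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n i.i.d. waiting times tau_i.

    Uniform variates are drawn on the open interval (0, 1): the generator
    stream is mapped 1 - U[0, 1) so y = 0 (infinite tau) cannot occur, and
    the measure-zero y = 1 edge is redrawn.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    y = 1.0 - rng.random(n)
    bad = y >= 1.0
    while np.any(bad):  # pragma: no cover - probability 2**-53 per draw
        y[bad] = 1.0 - rng.random(int(bad.sum()))
        bad = y >= 1.0
    return waiting_time_from_uniform(y, params)


def waiting_time_pdf(tau, params: MannevilleParams):
    """Density psi(tau) = (mu-1) T^(mu-1) / (tau + T)^mu for tau >= 0."""
    tau = np.asarray(tau, dtype=np.float64)
    if np.any(tau < 0):
        raise InvalidInputError("tau must be >= 0")
    mu, T = params.mu, params.T
    return (mu - 1.0) * T ** (mu - 1.0) / (tau + T) ** mu


def waiting_time_survival(t, params: MannevilleParams):
    """P(tau > t) = (T / (T + t))**(mu - 1) for t >= 0."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    return (params.T / (params.T + t)) ** (params.mu - 1.0)
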