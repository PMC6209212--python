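"""Nonlinear mating/mortality reaction dynamics and aggregate analytics.

The pointwise (diffusion-free) dynamics of the three genotype densities are

    du_k/dt = (eps/N - gamma/C) * S_k(u) - delta * u_k,   k = 1, 2, 3,

where ``N = u1 + u2 + u3``, ``S_k`` is the Punnett mating sum of
:meth:`drivespread.genetics.GenotypeFrequencies.mating_sums`, ``eps`` the
adult emergence rate, ``gamma = eps - delta1`` the intrinsic growth rate,
``C`` the carrying capacity and ``delta = delta1 + delta2`` the linear death
rate.  Because the mating sums add up to ``N**2``, the total population obeys
the logistic-with-harvesting law

    dN/dt = gamma * N * (1 - N/C) - delta2 * N,

with positive equilibrium ``N* = C (1 - delta2/gamma)``; this algebraic
identity is the main internal consistency check of the module.

Time integration uses the classical fixed-step fourth-order Runge-Kutta
scheme; closed-form solutions of the aggregate law serve as oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genetics import GenotypeFrequencies, allele_frequency

__all__ = [
    "ModelParameters",
    "IntegrationError",
    "reaction_rhs",
    "rk4_step",
    "rk4_integrate",
    "logistic_closed_form",
    "equilibrium_population",
    "vital_rates_from_daily",
    "VitalRates",
    "trajectory_table",
]

#: Tolerance below which negative densities produced by roundoff are clipped.
_NEGATIVE_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when a trajectory becomes non-finite or significantly negative."""


@dataclass(frozen=True)
class ModelParameters:
    """Vital rates of the mosquito population (weekly timescale).

    Parameters
    ----------
    epsilon
        Emergence rate into adulthood (week^-1).  Default 5.1.
    delta1
        Natural (density-independent) mortality component (week^-1).
        Default 3.9.
    delta2
        Harvest-like density-independent mortality, e.g. predation and
        human action (week^-1).  Default 0.5.
    C
        Carrying capacity (individuals, or individuals per km for spatial
        densities).  Default 2500.

    ``gamma = epsilon - delta1`` and ``delta = delta1 + delta2`` are derived
    exactly; with the defaults ``gamma = 1.2`` and ``delta = 4.4``.
    """

    epsilon: float = 5.1
    delta1: float = 3.9
    delta2: float = 0.5
    C: float = 2500.0

    def __post_init__(self) -> None:
        if min(self.epsilon, self.delta1, self.delta2, self.C) <= 0:
            raise ValueError("all vital rates and the carrying capacity must be positive")
        if self.gamma <= self.delta2:
            raise ValueError(
                "intrinsic growth gamma = epsilon - delta1 must exceed delta2 "
                "for a positive equilibrium"
            )

    @property
    def gamma(self) -> float:
        """Intrinsic growth rate (week^-1)."""
        return self.epsilon - self.delta1

    @property
    def delta(self) -> float:
        """Total linear death rate entering the genotype equations (week^-1)."""
        return self.delta1 + self.delta2


def _rhs(u: np.ndarray, params: ModelParameters, freqs: GenotypeFrequencies) -> np.ndarray:
    """Unchecked right-hand side; accepts shape (3,) or (3, n)."""
    u = np.asarray(u, dtype=float)
    S = freqs.mating_sums(u)
    N = u.sum(axis=0)
    # Birth term defined as 0 where N = 0: the mating sums vanish like N^2.
    safe_N = np.where(N > 0.0, N, 1.0)
    rate = np.where(N > 0.0, params.epsilon / safe_N - params.gamma / params.C, 0.0)
    return rate * S - params.delta * u


def reaction_rhs(
    u: np.ndarray, params: ModelParameters, freqs: GenotypeFrequencies
) -> np.ndarray:
    """Time derivative of the genotype densities at a single point.

    Raises ``ValueError`` on negative input densities.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("densities must be nonnegative")
    return _rhs(u, params, freqs)


def rk4_step(
    u: np.ndarray, dt: float, params: ModelParameters, freqs: GenotypeFrequencies
) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of size ``dt``."""
    k1 = _rhs(u, params, freqs)
    k2 = _rhs(u + 0.5 * dt * k1, params, freqs)
    k3 = _rhs(u + 0.5 * dt * k2, params, freqs)
    k4 = _rhs(u + dt * k3, params, freqs)
    return u + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _sanitize(u: np.ndarray, step: int) -> np.ndarray:
    """Clip roundoff negatives to zero; abort on blow-up or real negativity."""
    if not np.all(np.isfinite(u)):
        raise IntegrationError(f"non-finite state at step {step}")
    scale = max(1.0, float(np.max(np.abs(u))))
    if np.any(u < -_NEGATIVE_TOL * scale):
        raise IntegrationError(f"significantly negative density at step {step}")
    return np.where(u < 0.0, 0.0, u)


def rk4_integrate(
    u0: np.ndarray,
    params: ModelParameters,
    freqs: GenotypeFrequencies,
    t_span: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the reaction system over ``[0, t_span]`` with fixed step ``dt``.

    Returns ``(times, states)`` where ``states[m]`` is the state at
    ``times[m]``; the initial condition is included.  Negative densities
    within roundoff of zero are clipped; larger ones raise
    :class:`IntegrationError`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(t_span / dt))
    if n_steps < 1 or abs(n_steps * dt - t_span) > 1e-9 * max(1.0, t_span):
        raise ValueError("t_span must be a positive integer multiple of dt")
    u = np.asarray(u0, dtype=float)
    if np.any(u < 0):
        raise ValueError("initial densities must be nonnegative")
    times = dt * np.arange(n_steps + 1)
    states = np.empty((n_steps + 1,) + u.shape)
    states[0] = u
    for n in range(n_steps):
        u = _sanitize(rk4_step(u, dt, params, freqs), n + 1)
        states[n + 1] = u
    return times, states


def logistic_closed_form(N0: float, params: ModelParameters, t: float | np.ndarray):
    """Analytic solution of ``dN/dt = gamma N (1 - N/C) - delta2 N``.

    Equivalent to a pure logistic with rate ``r = gamma - delta2`` and
    capacity ``K = C (1 - delta2/gamma)``.
    """
    if np.any(np.asarray(N0) < 0):
        raise ValueError("N0 must be nonnegative")
    r = params.gamma - params.delta2
    K = equilibrium_population(params)
    growth = np.exp(r * np.asarray(t, dtype=float))
    return K * N0 * growth / (K + N0 * (growth - 1.0))


def equilibrium_population(params: ModelParameters) -> float:
    """Positive equilibrium ``N* = C (1 - delta2/gamma)`` of the aggregate law."""
    if params.gamma <= params.delta2:
        raise ValueError("no positive equilibrium: gamma must exceed delta2")
    return params.C * (1.0 - params.delta2 / params.gamma)


def _round_sig(x: float, n: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


class VitalRates(NamedTuple):
    """Weekly rates derived from a daily finite rate of increase."""

    weekly_finite: float
    gamma: float
    weekly_finite_reported: float  # 3 significant figures
    gamma_reported: float  # 2 significant figures


def vital_rates_from_daily(daily_rate: float) -> VitalRates:
    """Convert a daily finite rate of increase to weekly rates.

    The weekly finite rate is ``daily_rate**7`` and the weekly intrinsic
    rate of increase is its natural logarithm.  Both the unrounded values
    and the conventional reporting precision (3 and 2 significant figures)
    are returned.
    """
    if daily_rate <= 0:
        raise ValueError("daily rate must be positive")
    weekly = daily_rate**7
    gamma = math.log(weekly)
    return VitalRates(weekly, gamma, _round_sig(weekly, 3), _round_sig(gamma, 2))


def trajectory_table(times: np.ndarray, states: np.ndarray) -> pd.DataFrame:
    """Tabulate a pointwise trajectory as time, u1, u2, u3, N, q."""
    states = np.asarray(states, dtype=float)
    N = states.sum(axis=1)
    q = np.array(
        [
            allele_frequency(*row).q if row.sum() > 0 else np.nan
            for row in states
        ]
    )
    return pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "u1": states[:, 0],
            "u2": states[:, 1],
            "u3": states[:, 2],
            "N": N,
            "q": q,
        }
    )
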