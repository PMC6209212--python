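"""Monte Carlo uncertainty quantification over random diffusion coefficients.

Dispersal heterogeneity is modelled by drawing the diffusion coefficient of
each realization from a uniform law ``kappa ~ U(s_i, s_f)``; by default one
draw is shared by the three genotypes (there is no evidence of differential
flight capacity), with an independent-per-genotype mode available.  The
ensemble mean uses the sample average and the variance the population
(``1/N_s``) estimator of the fluctuations around it.  A nested-prefix
relative-error curve in the spatial L2 norm at the final time provides the
sample-size convergence diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splitting import SimulationResult, simulate

__all__ = [
    "DiffusionLaw",
    "EnsembleResult",
    "sample_kappa",
    "run_ensemble",
    "cumulative_variance",
    "relative_error_curve",
]

logger = logging.getLogger(__name__)

_COUPLINGS = ("shared", "independent")


@dataclass(frozen=True)
class DiffusionLaw:
    """Uniform law for the random diffusion coefficients (km^2/week).

    ``shared`` coupling draws one coefficient per realization applied to
    all three genotypes; ``independent`` draws three i.i.d. coefficients.
    """

    s_i: float = 0.01
    s_f: float = 0.05
    coupling: str = "shared"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.s_i < self.s_f:
            raise ValueError("need 0 < s_i < s_f")
        if self.coupling not in _COUPLINGS:
            raise ValueError(f"coupling must be one of {_COUPLINGS}")


def sample_kappa(law: DiffusionLaw, k: int) -> np.ndarray:
    """Diffusion coefficients of realization ``k``, shape ``(3,)``.

    Each realization uses its own RNG stream derived from ``(seed, k)``,
    so draws are reproducible and independent of evaluation order.
    """
    rng = np.random.default_rng([int(law.seed), int(k)])
    if law.coupling == "shared":
        return np.full(3, rng.uniform(law.s_i, law.s_f))
    return rng.uniform(law.s_i, law.s_f, size=3)


@dataclass
class EnsembleResult:
    """Monte Carlo statistics of an ensemble of splitting runs."""

    N_s: int
    times: np.ndarray
    mesh: object
    kappas: np.ndarray  # (N_s, 3)
    mean: np.ndarray  # (n_times, 3, n_nodes)
    variance: np.ndarray  # same shape; population (1/N_s) estimator
    realizations: np.ndarray | None = None  # (N_s, n_times, 3, n_nodes)

    def mean_field_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise KeyError(f"time {t} not among output times {self.times}")
        return self.mean[i]


def run_ensemble(
    scenario,
    law: DiffusionLaw | None = None,
    N_s: int | None = None,
    unbiased: bool = False,
    retain_realizations: bool = False,
) -> EnsembleResult:
    """Run ``N_s`` realizations of a scenario and accumulate moments.

    The mean is the sample average over realizations and the variance the
    ``1/N_s`` population estimator of the squared fluctuation around it
    (``1/(N_s - 1)`` with ``unbiased=True``).  Statistics are accumulated
    in streaming form; set ``retain_realizations`` to also keep every
    realization's output fields.
    """
    law = law if law is not None else scenario.diffusion
    N_s = N_s if N_s is not None else scenario.N_s
    if N_s < 2:
        raise ValueError("need at least two realizations")
    s1 = s2 = None
    kappas = np.empty((N_s, 3))
    kept = [] if retain_realizations else None
    result: SimulationResult | None = None
    for k in range(N_s):
        kappa = sample_kappa(law, k)
        kappas[k] = kappa
        try:
            result = simulate(scenario, kappa)
        except Exception as exc:
            raise RuntimeError(f"realization {k} failed: {exc}") from exc
        if s1 is None:
            s1 = np.zeros_like(result.fields)
            s2 = np.zeros_like(result.fields)
        s1 += result.fields
        s2 += result.fields**2
        if kept is not None:
            kept.append(result.fields)
        logger.debug("realization %d/%d done (kappa=%s)", k + 1, N_s, kappa)
    mean = s1 / N_s
    norm = N_s - 1 if unbiased else N_s
    variance = np.maximum(s2 / norm - (N_s / norm) * mean**2, 0.0)
    return EnsembleResult(
        N_s=N_s,
        times=result.times.copy(),
        mesh=result.mesh,
        kappas=kappas,
        mean=mean,
        variance=variance,
        realizations=np.asarray(kept) if kept is not None else None,
    )


def cumulative_variance(result: EnsembleResult) -> np.ndarray:
    """Running sum of the variance field over the output times.

    Returns an array shaped like ``result.variance`` whose entry at output
    time ``T`` is ``sum_{t_m <= T} sigma^2(x, t_m)`` — nondecreasing in
    ``T`` at every node.
    """
    return np.cumsum(result.variance, axis=0)


def _l2_norm(f: np.ndarray, x: np.ndarray) -> float:
    return float(np.sqrt(np.trapezoid(f * f, x)))


def relative_error_curve(
    scenario,
    law: DiffusionLaw | None = None,
    N_r: int = 150,
    moment: str = "mean",
) -> pd.DataFrame:
    """Sample-size convergence diagnostic for the wild-population moment.

    For each ``N_s < N_r`` computes the relative change, in the spatial L2
    norm at the final output time, between the wild-population moment
    estimated from the first ``N_s`` and the first ``N_s + 1``
    realizations (nested prefixes of one fixed realization sequence).
    Returns a table with columns ``N_s`` and ``E_rel``; entries where the
    normalizing moment has zero norm are flagged NaN.
    """
    if moment not in ("mean", "variance"):
        raise ValueError("moment must be 'mean' or 'variance'")
    if N_r < 3:
        raise ValueError("need N_r >= 3")
    ens = run_ensemble(scenario, law=law, N_s=N_r, retain_realizations=True)
    # wild population at the final output time, per realization: (N_r, n_nodes)
    w = ens.realizations[:, -1, 0, :]
    x = ens.mesh.nodes
    counts = np.arange(1, N_r + 1)[:, None]
    prefix_mean = np.cumsum(w, axis=0) / counts
    if moment == "mean":
        m = prefix_mean
    else:
        prefix_sq = np.cumsum(w**2, axis=0) / counts
        m = np.maximum(prefix_sq - prefix_mean**2, 0.0)
    ns = np.arange(2, N_r)
    errs = np.full(ns.size, np.nan)
    for i, n in enumerate(ns):
        denom = _l2_norm(m[n], x)  # moment with n+1 samples (0-based row n)
        if denom > 0:
            errs[i] = _l2_norm(m[n - 1] - m[n], x) / denom
    return pd.DataFrame({"N_s": ns, "E_rel": errs})
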