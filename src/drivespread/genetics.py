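"""Offspring genotype frequencies and allele-frequency analytics.

The model tracks three mosquito compartments distinguished by zygosity at the
transgene locus: wild ``(w, w)``, heterozygous ``(w, g)`` and homozygous
transgenic ``(g, g)``, indexed 1, 2, 3.  Random mating between compartments
``i`` and ``j`` produces offspring of each genotype with Punnett-square
frequencies ``a_ij`` (wild), ``b_ij`` (heterozygous) and ``c_ij``
(homozygous); for every cross ``a_ij + b_ij + c_ij = 1``.

Two inheritance modes are supported:

* ``mendelian`` — the classical Punnett fractions.
* ``mcr`` — a mutagenic-chain-reaction (CRISPR homing) drive that converts
  heterozygous offspring to homozygous in the germline with efficiency
  ``f``: every heterozygous fraction is scaled by ``(1 - f)`` and the
  converted share ``f * b_ij`` is moved to the homozygous row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "PAIRS",
    "PAIR_MULTIPLICITY",
    "GenotypeFrequencies",
    "AlleleState",
    "mendelian_frequencies",
    "mcr_frequencies",
    "allele_frequency",
    "hardy_weinberg_proportions",
]

#: Unordered mating pairs (i, j) with i <= j; 1 = wild, 2 = het, 3 = hom.
PAIRS: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (1, 3), (2, 2), (2, 3), (3, 3))

#: Multiplicity of each unordered pair in the double mating sum
#: sum_i sum_j x_ij u_i u_j = sum_{i<=j} m_ij x_ij u_i u_j.
PAIR_MULTIPLICITY: np.ndarray = np.array([1.0, 2.0, 2.0, 1.0, 2.0, 1.0])

_MENDEL_A = np.array([1.0, 0.5, 0.0, 0.25, 0.0, 0.0])
_MENDEL_B = np.array([0.0, 0.5, 1.0, 0.5, 0.5, 0.0])
_MENDEL_C = np.array([0.0, 0.0, 0.0, 0.25, 0.5, 1.0])

_GENOTYPE_LABELS = ("wild", "heterozygous", "homozygous")


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Offspring-frequency table for the six unordered crosses.

    Attributes
    ----------
    a, b, c
        Length-6 arrays of wild / heterozygous / homozygous offspring
        fractions, ordered as :data:`PAIRS`.
    mode
        ``"mendelian"`` or ``"mcr"``.
    f
        Drive conversion efficiency in ``[0, 1]`` (0 for Mendelian).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    mode: str
    f: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (6,):
                raise ValueError(f"{name} must have shape (6,), got {arr.shape}")
            if np.any(arr < -1e-15) or np.any(arr > 1 + 1e-15):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            object.__setattr__(self, name, arr)
        total = self.a + self.b + self.c
        if not np.allclose(total, 1.0, rtol=0.0, atol=1e-12):
            raise ValueError("offspring fractions must sum to 1 for every cross")
        if self.mode not in ("mendelian", "mcr"):
            raise ValueError(f"unknown inheritance mode {self.mode!r}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("conversion efficiency f must lie in [0, 1]")

    def mating_sums(self, u: np.ndarray) -> np.ndarray:
        """Quadratic mating sums ``S_k = sum_{i<=j} m_ij x^k_ij u_i u_j``.

        ``u`` has shape ``(3,)`` or ``(3, n)``; the result has the same
        shape, one row per offspring genotype.  Summing the three rows gives
        ``(u1 + u2 + u3)**2`` exactly (Punnett normalization).
        """
        u = np.asarray(u, dtype=float)
        u1, u2, u3 = u[0], u[1], u[2]
        prods = np.stack([u1 * u1, u1 * u2, u1 * u3, u2 * u2, u2 * u3, u3 * u3])
        weighted = prods * PAIR_MULTIPLICITY.reshape((6,) + (1,) * (u.ndim - 1))
        return np.stack(
            [
                np.einsum("p,p...->...", self.a, weighted),
                np.einsum("p,p...->...", self.b, weighted),
                np.einsum("p,p...->...", self.c, weighted),
            ]
        )

    def table(self) -> pd.DataFrame:
        """Return the 3 x 6 frequency table (rows: genotype, columns: cross)."""
        cols = [f"{i}{j}" for i, j in PAIRS]
        return pd.DataFrame(
            [self.a, self.b, self.c], index=list(_GENOTYPE_LABELS), columns=cols
        )


class AlleleState(NamedTuple):
    """Allele frequencies and total population size.

    ``p`` is the wild-allele frequency, ``q = 1 - p`` the transgene
    frequency, ``N`` the total population (count or density, context
    dependent).
    """

    p: float
    q: float
    N: float


def mendelian_frequencies() -> GenotypeFrequencies:
    """Classical Punnett-square offspring frequencies (no drive)."""
    return GenotypeFrequencies(
        a=_MENDEL_A.copy(), b=_MENDEL_B.copy(), c=_MENDEL_C.copy(),
        mode="mendelian", f=0.0,
    )


def mcr_frequencies(f: float) -> GenotypeFrequencies:
    """Drive-biased offspring frequencies with conversion efficiency ``f``.

    Heterozygous offspring are converted to homozygous with probability
    ``f``: ``b -> (1 - f) b`` and ``c -> c + f b``.  ``f = 0`` reproduces
    Mendelian inheritance exactly.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"conversion efficiency f must lie in [0, 1], got {f}")
    return GenotypeFrequencies(
        a=_MENDEL_A.copy(),
        b=(1.0 - f) * _MENDEL_B,
        c=_MENDEL_C + f * _MENDEL_B,
        mode="mcr" if f > 0 else "mendelian",
        f=f,
    )


def frequencies_for(inheritance: str, f: float = 0.14) -> GenotypeFrequencies:
    """Frequency table for a named inheritance mode."""
    if inheritance == "mendelian":
        return mendelian_frequencies()
    if inheritance == "mcr":
        return mcr_frequencies(f)
    raise ValueError(f"unknown inheritance mode {inheritance!r}")


def allele_frequency(u1: float, u2: float, u3: float) -> AlleleState:
    """Allele frequencies of a genotype census.

    Each heterozygote carries one transgene copy and each homozygote two,
    so ``q = (u2 + 2 u3) / (2 N)`` with ``N = u1 + u2 + u3``.
    """
    if u1 < 0 or u2 < 0 or u3 < 0:
        raise ValueError("population counts must be nonnegative")
    N = u1 + u2 + u3
    if N == 0:
        raise ValueError("allele frequency undefined for an empty population")
    q = (u2 + 2.0 * u3) / (2.0 * N)
    return AlleleState(p=1.0 - q, q=q, N=N)


def hardy_weinberg_proportions(state: AlleleState) -> tuple[float, float, float]:
    """Genotype proportions ``(p^2, 2pq, q^2)`` at Hardy-Weinberg equilibrium."""
    p, q = state.p, state.q
    return (p * p, 2.0 * p * q, q * q)
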