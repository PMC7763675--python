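"""Forward release models and the rate-constant/diffusivity conversion.

Three models for the cumulative release percentage R(t) from a spherical
carrier are provided:

* the exact series solution of the transient diffusion equation in a
  sphere (surface-diffusion desorption),

      R(t) = 100 * (1 - (6/pi^2) * sum_{i>=1} exp(-D i^2 pi^2 t / r^2) / i^2),

* its long-time single-exponential approximation with freely adjustable
  amplitude and rate, R(t) = 100 * (1 - A exp(-k t)), and

* the bimodal (two-population) exponential model

      R(t) = 100 * [phi (1 - exp(-K1 t)) + (1 - phi) (1 - exp(-K2 t))],

  in which fractions phi and 1-phi of the drug diffuse with distinct
  first-order rate constants.

Rate constants K (d^-1) map to diffusivities D (m^2/s) through the
linear-driving-force approximation for a sphere, K = 15 D / r^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .curves import SECONDS_PER_DAY, SphericalCarrier
from .errors import ValidationError

__all__ = [
    "SeriesParams",
    "SingleTermParams",
    "BimodalParams",
    "series_release_fraction",
    "single_term_release_fraction",
    "bimodal_release_fraction",
    "diffusivity_from_rate",
    "rate_from_diffusivity",
    "canonicalize",
    "FIRST_TERM_AMPLITUDE",
]

#: Amplitude of the leading term of the exact series, 6/pi^2.
FIRST_TERM_AMPLITUDE = 6.0 / math.pi**2

#: Hard cap on the number of series terms.
MAX_SERIES_TERMS = 10_000


@dataclass(frozen=True)
class SeriesParams:
    """Exact-series model parameter: the surface diffusion coefficient D, m^2/s."""

    diffusivity: float

    def __post_init__(self) -> None:
        if not (self.diffusivity > 0 and math.isfinite(self.diffusivity)):
            raise ValidationError(f"diffusivity must be > 0, got {self.diffusivity}")


@dataclass(frozen=True)
class SingleTermParams:
    """Single-exponential approximation: amplitude A in (0, 1], rate k in d^-1.

    With A = 6/pi^2 and k = D pi^2 / r^2 this is exactly the first term of
    the series solution; letting both parameters float is the usual
    long-time approximation.  Note R(0) = 100 (1 - A) > 0 whenever A < 1:
    the approximation cannot represent the initial diffusion burst.
    """

    prefactor: float
    rate: float

    def __post_init__(self) -> None:
        if not (0 < self.prefactor <= 1):
            raise ValidationError(f"prefactor must be in (0, 1], got {self.prefactor}")
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise ValidationError(f"rate must be > 0, got {self.rate}")


@dataclass(frozen=True)
class BimodalParams:
    """Two-population exponential model parameters.

    Attributes
    ----------
    phi
        Fraction of the drug in the fast population, in [0, 1].
    k1, k2
        First-order rate constants of the fast and slow populations,
        d^-1.  The canonical ordering is k1 >= k2 (see
        :func:`canonicalize`); construction does not enforce it, since
        the model is symmetric under (phi, k1, k2) -> (1-phi, k2, k1).
    """

    phi: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (0 <= self.phi <= 1):
            raise ValidationError(f"phi must be in [0, 1], got {self.phi}")
        for name, k in (("k1", self.k1), ("k2", self.k2)):
            if not (k > 0 and math.isfinite(k)):
                raise ValidationError(f"{name} must be > 0, got {k}")

    @property
    def is_canonical(self) -> bool:
        return self.k1 >= self.k2


def canonicalize(params: BimodalParams) -> BimodalParams:
    """Resolve the label symmetry so that k1 >= k2 (fast mode first).

    The release curve is unchanged: swapping the two populations and
    replacing phi by 1 - phi is a pure relabelling.  Idempotent.
    """
    if params.is_canonical:
        return params
    return BimodalParams(phi=1.0 - params.phi, k1=params.k2, k2=params.k1)


def _validated_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise ValidationError(f"times must be one-dimensional, got shape {t.shape}")
    if not np.all(np.isfinite(t)):
        raise ValidationError("times contain non-finite values")
    if np.any(t < 0):
        raise ValidationError("times must all be >= 0")
    return t


def _series_partial_sum(tau: float, rel_tol: float, max_terms: int) -> float:
    """Adaptive partial sum of sum_i exp(-i^2 pi^2 tau) / i^2.

    Terms are added until the remaining tail can no longer change the
    running sum by ``rel_tol`` relative, or ``max_terms`` is reached.
    The tail after term i is bounded by term_i * i (the exponential
    factor decreases and sum_{j>i} 1/j^2 < 1/i), so stopping when
    term_i * i < rel_tol * sum bounds the truncation error rigorously;
    a bare next-term test would under-truncate at small tau where
    thousands of slowly-decaying terms remain.  tau is the dimensionless
    time D*t/r^2.
    """
    pi2 = math.pi**2
    total = 0.0
    for i in range(1, max_terms + 1):
        term = math.exp(-(i * i) * pi2 * tau) / (i * i)
        total += term
        if term * i < rel_tol * total:
            break
    return total


def series_release_fraction(
    params: SeriesParams,
    carrier: SphericalCarrier,
    times,
    rel_tol: float = 1e-10,
) -> np.ndarray:
    """Exact sphere-diffusion release percentage R(t) at the given times (days).

    The infinite series is truncated adaptively once the next term
    changes the sum by less than ``rel_tol`` relative (hard cap 10,000
    terms).  t = 0 short-circuits to exactly 0: any finite truncation of
    the full series (which sums to pi^2/6) would otherwise report a
    spurious positive release.
    """
    if not (0 < rel_tol <= 1e-3):
        raise ValidationError(f"rel_tol must be in (0, 1e-3], got {rel_tol}")
    t = _validated_times(times)
    tau = params.diffusivity * (t * SECONDS_PER_DAY) / carrier.radius**2
    out = np.zeros(t.shape)
    for j, tau_j in enumerate(tau):
        if tau_j == 0.0:
            continue
        s = _series_partial_sum(tau_j, rel_tol, MAX_SERIES_TERMS)
        out[j] = 100.0 * (1.0 - FIRST_TERM_AMPLITUDE * s)
    return out


def single_term_release_fraction(params: SingleTermParams, times) -> np.ndarray:
    """Single-exponential release percentage R(t) = 100 (1 - A exp(-k t))."""
    t = _validated_times(times)
    return 100.0 * (1.0 - params.prefactor * np.exp(-params.rate * t))


def bimodal_release_fraction(params: BimodalParams, times) -> np.ndarray:
    """Two-population release percentage at the given times (days)."""
    t = _validated_times(times)
    fast = 1.0 - np.exp(-params.k1 * t)
    slow = 1.0 - np.exp(-params.k2 * t)
    return 100.0 * (params.phi * fast + (1.0 - params.phi) * slow)


#: Linear-driving-force geometric factor for a sphere (K = 15 D / r^2).
LDF_SPHERE_FACTOR = 15.0


def diffusivity_from_rate(rate: float, carrier: SphericalCarrier) -> float:
    """Convert a first-order rate constant K (d^-1) to a diffusivity D (m^2/s).

    Uses the linear-driving-force approximation for a sphere,
    D = K r^2 / 15, with K converted from d^-1 to s^-1.
    """
    if not (rate > 0 and math.isfinite(rate)):
        raise ValidationError(f"rate must be > 0, got {rate}")
    rate_per_s = rate / SECONDS_PER_DAY
    return rate_per_s * carrier.radius**2 / LDF_SPHERE_FACTOR


def rate_from_diffusivity(diffusivity: float, carrier: SphericalCarrier) -> float:
    """Convert a diffusivity D (m^2/s) to a first-order rate constant K (d^-1).

    Exact inverse of :func:`diffusivity_from_rate`.
    """
    if not (diffusivity > 0 and math.isfinite(diffusivity)):
        raise ValidationError(f"diffusivity must be > 0, got {diffusivity}")
    rate_per_s = LDF_SPHERE_FACTOR * diffusivity / carrier.radius**2
    return rate_per_s * SECONDS_PER_DAY
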