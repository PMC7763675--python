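"""Least-squares fitting of release models and model comparison.

Fit quality is scored by the root-mean-square deviation between model
and experimental release percentages over the N non-trivial points,

    S = sqrt( sum_i (R_model,i - R_exp,i)^2 / N ),

where non-trivial means R < 99 % (points on the final plateau carry no
kinetic information).  S is both the reported statistic and the model
selection score.

Optimisation is bounded trust-region least squares
(:func:`scipy.optimize.least_squares`) launched from a deterministic
multi-start grid: population fractions 0.1..0.9 in steps of 0.2, rate
constants log-spaced over 1e-3..10 d^-1 (5 values).  The grid is first
screened by residual sum of squares and local optimisation is run from
the best ``n_best_starts`` points; the best converged optimum wins, ties
broken by smaller fast rate constant.  Parameters are fitted in their
natural units under box constraints (no transforms), so the reported
values are directly the physical ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .curves import ReleaseCurve, SphericalCarrier
from .errors import FitConvergenceError, UninformativeCurveError, ValidationError
from .models import (
    BimodalParams,
    SeriesParams,
    SingleTermParams,
    bimodal_release_fraction,
    canonicalize,
    diffusivity_from_rate,
    series_release_fraction,
    single_term_release_fraction,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "ModelComparison",
    "filter_nontrivial",
    "s_statistic",
    "fit_bimodal",
    "fit_single_term",
    "fit_series",
    "compare_models",
    "fast_slow_diffusivities",
    "diffusivity_percent_change",
]

#: Default non-trivial threshold: points with release >= 99 % are dropped.
NONTRIVIAL_THRESHOLD = 99.0

_PHI_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
_RATE_GRID = tuple(np.logspace(-3, 1, 5))  # d^-1
_AMP_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)
# Diffusivity starts bracket the nano-carrier regime generously.
_DIFFUSIVITY_GRID = tuple(np.logspace(-26, -16, 11))  # m^2/s

_RATE_BOUNDS = (1e-9, 1e4)  # d^-1
_DIFFUSIVITY_BOUNDS = (1e-32, 1e-8)  # m^2/s


@dataclass(frozen=True)
class FitOptions:
    """Options shared by all model fits.

    Attributes
    ----------
    filter_threshold
        Release percentage above which points are considered trivial and
        excluded before fitting (default 99).
    n_best_starts
        Number of grid starts, ranked by initial residual sum of
        squares, from which local optimisation is actually launched.
    seed
        Echoed into the result for provenance; the fit itself is fully
        deterministic.
    """

    filter_threshold: float = NONTRIVIAL_THRESHOLD
    n_best_starts: int = 12
    max_nfev: int = 2000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_best_starts < 1:
            raise ValidationError("n_best_starts must be >= 1")
        if self.max_nfev < 10:
            raise ValidationError("max_nfev must be >= 10")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit on the filtered points of a curve."""

    model_id: str
    params: object
    s_value: float
    n_points: int
    residuals: np.ndarray  # model - experiment, release-%
    n_starts: int
    converged: bool
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        res = np.asarray(self.residuals, dtype=float)
        res.flags.writeable = False
        object.__setattr__(self, "residuals", res)


@dataclass(frozen=True)
class ModelComparison:
    """Per-model fits on one identically filtered curve, ranked by S."""

    curve: ReleaseCurve  # the filtered curve all models were fitted to
    results: dict  # model_id -> FitResult
    failures: dict  # model_id -> error message, for fits that errored
    ranking: tuple  # model_ids, ascending S
    diffusivities: dict  # model_id -> diffusivity record, if radius known

    @property
    def best(self) -> FitResult:
        return self.results[self.ranking[0]]


def filter_nontrivial(
    curve: ReleaseCurve, threshold: float = NONTRIVIAL_THRESHOLD
) -> ReleaseCurve:
    """Keep only the non-trivial points (release < threshold), order preserved.

    Points at or beyond the threshold sit on the exhaustion plateau and
    would otherwise dominate the unweighted deviation statistic without
    constraining the kinetics.
    """
    keep = curve.release < threshold
    if not np.any(keep):
        raise UninformativeCurveError(
            f"no points with release < {threshold} %: curve is uninformative"
        )
    if np.all(keep):
        return curve
    return ReleaseCurve(times=curve.times[keep], release=curve.release[keep])


def s_statistic(model_release, experimental_release) -> float:
    """Root of mean squared deviations between model and experiment, in release-%."""
    model = np.asarray(model_release, dtype=float)
    exp = np.asarray(experimental_release, dtype=float)
    if model.shape != exp.shape or model.ndim != 1:
        raise ValidationError(
            f"model and experimental vectors must be 1-D of equal length, "
            f"got {model.shape} vs {exp.shape}"
        )
    if model.size == 0:
        raise ValidationError("empty vectors have no deviation statistic")
    return float(np.sqrt(np.mean((model - exp) ** 2)))


def _multistart_least_squares(
    predict: Callable[[np.ndarray], np.ndarray],
    observed: np.ndarray,
    starts: Sequence[np.ndarray],
    bounds: tuple,
    options: FitOptions,
    tie_key: Callable[[np.ndarray], float],
):
    """Screen the grid by SSE, polish the best starts, return the winner.

    Returns (x_best, sse_best, n_starts, converged).  Among optima whose
    SSE is within 1e-9 relative of the best, the one with the smallest
    ``tie_key`` wins (deterministic tie-break).
    """

    def residual(x: np.ndarray) -> np.ndarray:
        return predict(x) - observed

    sse0 = np.array([float(np.sum(residual(np.asarray(x)) ** 2)) for x in starts])
    order = np.argsort(sse0, kind="stable")[: options.n_best_starts]

    candidates = []
    any_success = False
    for idx in order:
        x0 = np.clip(np.asarray(starts[idx], dtype=float), bounds[0], bounds[1])
        # Solve in per-start scaled units u = x / |x0|: physical scales here
        # span ~20 decades (diffusivities ~1e-22 m^2/s) and scipy's
        # trust-region code silently clamps unscaled iterates smaller than
        # ~1e-10 onto an absolute feasibility margin.
        scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
        try:
            sol = least_squares(
                lambda u: residual(u * scale),
                x0=x0 / scale,
                bounds=(bounds[0] / scale, bounds[1] / scale),
                x_scale="jac",
                max_nfev=options.max_nfev,
            )
        except Exception:  # singular Jacobian etc.: skip this start
            continue
        any_success = any_success or bool(sol.success)
        candidates.append((float(np.sum(sol.fun**2)), sol.x * scale))

    if not candidates:
        raise FitConvergenceError("all optimisation starts failed")

    best_sse = min(c[0] for c in candidates)
    tol = 1e-9 * max(best_sse, 1e-300)
    near_best = [c for c in candidates if c[0] <= best_sse + tol]
    sse, x = min(near_best, key=lambda c: tie_key(c[1]))
    return x, sse, len(starts), any_success


def _prepare(curve: ReleaseCurve, options: FitOptions, min_points: int, n_free: int):
    filtered = filter_nontrivial(curve, options.filter_threshold)
    if len(filtered) < max(min_points, n_free + 1):
        raise ValidationError(
            f"need at least {max(min_points, n_free + 1)} non-trivial points, "
            f"have {len(filtered)}"
        )
    return filtered


def fit_bimodal(curve: ReleaseCurve, options: Optional[FitOptions] = None) -> FitResult:
    """Fit the two-population exponential model to a release curve.

    Minimises the unweighted sum of squared deviations over
    (phi, K1, K2) with phi in [0, 1] and positive rates; the result is
    canonicalized so K1 >= K2.  When the data are effectively
    single-exponential the model is degenerate (phi near a boundary or
    K1 ~ K2); that is reported as-is, not treated as an error.
    """
    options = options or FitOptions()
    filtered = _prepare(curve, options, min_points=4, n_free=3)
    t, y = filtered.times, filtered.release

    def predict(x: np.ndarray) -> np.ndarray:
        phi, k1, k2 = x
        return 100.0 * (
            phi * (1.0 - np.exp(-k1 * t)) + (1.0 - phi) * (1.0 - np.exp(-k2 * t))
        )

    starts = [
        np.array([phi, k1, k2])
        for phi, k1, k2 in itertools.product(_PHI_GRID, _RATE_GRID, _RATE_GRID)
        if k1 >= k2
    ]
    lo, hi = _RATE_BOUNDS
    bounds = (np.array([0.0, lo, lo]), np.array([1.0, hi, hi]))

    def tie_key(x: np.ndarray) -> float:
        return canonicalize(BimodalParams(*x)).k1

    x, sse, n_starts, converged = _multistart_least_squares(
        predict, y, starts, bounds, options, tie_key
    )
    params = canonicalize(BimodalParams(phi=float(x[0]), k1=float(x[1]), k2=float(x[2])))
    residuals = bimodal_release_fraction(params, t) - y
    return FitResult(
        model_id="bimodal",
        params=params,
        s_value=s_statistic(residuals + y, y),
        n_points=len(filtered),
        residuals=residuals,
        n_starts=n_starts,
        converged=converged,
        seed=options.seed,
    )


def fit_single_term(
    curve: ReleaseCurve, options: Optional[FitOptions] = None
) -> FitResult:
    """Fit the single-exponential approximation R = 100 (1 - A exp(-k t))."""
    options = options or FitOptions()
    filtered = _prepare(curve, options, min_points=3, n_free=2)
    t, y = filtered.times, filtered.release

    def predict(x: np.ndarray) -> np.ndarray:
        a, k = x
        return 100.0 * (1.0 - a * np.exp(-k * t))

    starts = [np.array([a, k]) for a, k in itertools.product(_AMP_GRID, _RATE_GRID)]
    lo, hi = _RATE_BOUNDS
    bounds = (np.array([1e-6, lo]), np.array([1.0, hi]))

    x, sse, n_starts, converged = _multistart_least_squares(
        predict, y, starts, bounds, options, tie_key=lambda x: x[1]
    )
    params = SingleTermParams(prefactor=float(x[0]), rate=float(x[1]))
    residuals = single_term_release_fraction(params, t) - y
    return FitResult(
        model_id="single_term",
        params=params,
        s_value=s_statistic(residuals + y, y),
        n_points=len(filtered),
        residuals=residuals,
        n_starts=n_starts,
        converged=converged,
        seed=options.seed,
    )


def fit_series(
    curve: ReleaseCurve,
    carrier: SphericalCarrier,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Fit the exact sphere-diffusion series solution (one free parameter, D).

    The carrier radius must be known; the adaptive series evaluation is
    the forward model.  Multi-start over eleven log-spaced decades of D
    makes the 1-D fit robust to initialisation many orders of magnitude
    off the optimum.
    """
    options = options or FitOptions()
    filtered = _prepare(curve, options, min_points=2, n_free=1)
    t, y = filtered.times, filtered.release

    def predict(x: np.ndarray) -> np.ndarray:
        return series_release_fraction(SeriesParams(diffusivity=float(x[0])), carrier, t)

    starts = [np.array([d]) for d in _DIFFUSIVITY_GRID]
    bounds = (np.array([_DIFFUSIVITY_BOUNDS[0]]), np.array([_DIFFUSIVITY_BOUNDS[1]]))

    x, sse, n_starts, converged = _multistart_least_squares(
        predict, y, starts, bounds, options, tie_key=lambda x: x[0]
    )
    params = SeriesParams(diffusivity=float(x[0]))
    residuals = series_release_fraction(params, carrier, t) - y
    return FitResult(
        model_id="series",
        params=params,
        s_value=s_statistic(residuals + y, y),
        n_points=len(filtered),
        residuals=residuals,
        n_starts=n_starts,
        converged=converged,
        seed=options.seed,
    )


def fast_slow_diffusivities(
    result: FitResult, carrier: SphericalCarrier
) -> tuple[float, float]:
    """Diffusivities (D_fast, D_slow) in m^2/s from a bimodal fit.

    D_fast = K1 r^2 / 15 and D_slow = K2 r^2 / 15 (with the d^-1 to s^-1
    conversion applied), requiring the canonical ordering K1 >= K2.
    """
    if result.model_id != "bimodal" or not isinstance(result.params, BimodalParams):
        raise ValidationError("fast/slow diffusivities require a bimodal fit result")
    params = result.params
    if not params.is_canonical:
        params = canonicalize(params)
    return (
        diffusivity_from_rate(params.k1, carrier),
        diffusivity_from_rate(params.k2, carrier),
    )


def diffusivity_percent_change(
    result_a: FitResult,
    carrier_a: SphericalCarrier,
    result_b: FitResult,
    carrier_b: SphericalCarrier,
) -> tuple[float, float]:
    """Percent change 100 (D_b / D_a - 1) of the fast and slow diffusivities.

    Compares formulation b against formulation a, each with its own
    particle radius.
    """
    fast_a, slow_a = fast_slow_diffusivities(result_a, carrier_a)
    fast_b, slow_b = fast_slow_diffusivities(result_b, carrier_b)
    return (100.0 * (fast_b / fast_a - 1.0), 100.0 * (slow_b / slow_a - 1.0))


def compare_models(
    curve: ReleaseCurve,
    carrier: Optional[SphericalCarrier] = None,
    options: Optional[FitOptions] = None,
) -> ModelComparison:
    """Fit every applicable model on the identically filtered curve; rank by S.

    The series model is only attempted when a carrier radius is
    supplied.  Per-model failures are collected in ``failures`` rather
    than aborting the comparison.  When a radius is available the
    fitted rate constants are also converted to diffusivities.
    """
    options = options or FitOptions()
    filtered = filter_nontrivial(curve, options.filter_threshold)

    fitters: dict[str, Callable[[], FitResult]] = {
        "bimodal": lambda: fit_bimodal(filtered, options),
        "single_term": lambda: fit_single_term(filtered, options),
    }
    if carrier is not None:
        fitters["series"] = lambda: fit_series(filtered, carrier, options)

    results: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for model_id, fitter in fitters.items():
        try:
            results[model_id] = fitter()
        except (ValidationError, FitConvergenceError) as exc:
            failures[model_id] = f"{type(exc).__name__}: {exc}"

    if not results:
        raise FitConvergenceError(
            "no model could be fitted: " + "; ".join(failures.values())
        )

    ranking = tuple(sorted(results, key=lambda m: results[m].s_value))

    diffusivities: dict[str, dict] = {}
    if carrier is not None:
        for model_id, res in results.items():
            if model_id == "bimodal":
                d_fast, d_slow = fast_slow_diffusivities(res, carrier)
                diffusivities[model_id] = {"D_fast": d_fast, "D_slow": d_slow}
            elif model_id == "single_term":
                diffusivities[model_id] = {
                    "D": diffusivity_from_rate(res.params.rate, carrier)
                }
            elif model_id == "series":
                diffusivities[model_id] = {"D": res.params.diffusivity}

    return ModelComparison(
        curve=filtered,
        results=results,
        failures=failures,
        ranking=ranking,
        diffusivities=diffusivities,
    )
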