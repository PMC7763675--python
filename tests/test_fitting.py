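"""Model fitting, the deviation statistic S, and model comparison."""

import dataclasses
import math

import numpy as np
import pytest

from relkin import (
    BimodalParams,
    FitOptions,
    ReleaseCurve,
    SeriesParams,
    SingleTermParams,
    SphericalCarrier,
    UninformativeCurveError,
    ValidationError,
    bimodal_release_fraction,
    compare_models,
    diffusivity_percent_change,
    fast_slow_diffusivities,
    filter_nontrivial,
    fit_bimodal,
    fit_series,
    fit_single_term,
    s_statistic,
    series_release_fraction,
    simulate_release,
    single_term_release_fraction,
)
from relkin.synthetic import SyntheticSpec


def curve_from_bimodal(params, times):
    return ReleaseCurve(times, bimodal_release_fraction(params, times))


class TestFilterNontrivial:
    def test_drops_plateau_points(self):
        curve = ReleaseCurve([1, 2, 3, 4, 5], [10, 50, 98.5, 99.5, 100])
        kept = filter_nontrivial(curve)
        np.testing.assert_array_equal(kept.release, [10, 50, 98.5])
        np.testing.assert_array_equal(kept.times, [1, 2, 3])

    def test_identity_when_all_nontrivial(self):
        curve = ReleaseCurve([1, 2, 3], [10, 50, 90])
        assert filter_nontrivial(curve) is curve

    def test_all_trivial_is_an_error(self):
        curve = ReleaseCurve([1, 2], [99.5, 100])
        with pytest.raises(UninformativeCurveError):
            filter_nontrivial(curve)


class TestSStatistic:
    def test_identical_vectors(self):
        assert s_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_residuals(self):
        assert s_statistic([12.0, 22.0, 32.0], [10.0, 20.0, 30.0]) == pytest.approx(2.0)

    def test_two_point_arithmetic(self):
        # residuals [3, 4]: sqrt(25/2)
        assert s_statistic([13.0, 24.0], [10.0, 20.0]) == pytest.approx(
            math.sqrt(12.5), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            s_statistic([1.0, 2.0], [1.0])


class TestFitBimodal:
    TRUE = BimodalParams(phi=0.29, k1=1.74, k2=0.123)

    def test_noiseless_recovery(self):
        times = np.arange(0.5, 15.5, 0.5)
        fit = fit_bimodal(curve_from_bimodal(self.TRUE, times))
        assert fit.params.phi == pytest.approx(self.TRUE.phi, rel=1e-4)
        assert fit.params.k1 == pytest.approx(self.TRUE.k1, rel=1e-4)
        assert fit.params.k2 == pytest.approx(self.TRUE.k2, rel=1e-4)
        assert fit.s_value < 1e-6
        assert fit.converged

    def test_single_exponential_limit_is_degenerate_not_an_error(self):
        times = np.arange(0.5, 15.5, 0.5)
        single = ReleaseCurve(times, 100.0 * (1.0 - np.exp(-0.4 * times)))
        fit = fit_bimodal(single)
        assert fit.s_value < 1e-6
        # degeneracy: either the fractions collapse or the rates coincide
        assert (
            fit.params.phi > 0.99
            or fit.params.phi < 0.01
            or abs(fit.params.k1 / fit.params.k2 - 1) < 1e-3
        )

    def test_noisy_s_matches_noise_scale(self):
        spec = SyntheticSpec(
            model_id="bimodal",
            true_params=self.TRUE,
            schedule=np.arange(0.0, 15.5, 0.5),
            noise_sd=2.0,
            seed=424242,
        )
        fit = fit_bimodal(simulate_release(spec))
        assert 0.5 * 2.0 <= fit.s_value <= 2.0 * 2.0

    def test_result_invariants(self):
        times = np.arange(0.5, 15.5, 0.5)
        fit = fit_bimodal(curve_from_bimodal(self.TRUE, times))
        assert fit.params.k1 >= fit.params.k2
        assert fit.n_points == len(times)
        assert fit.s_value**2 * fit.n_points == pytest.approx(
            float(np.sum(fit.residuals**2)), rel=1e-9, abs=1e-30
        )

    def test_deterministic(self):
        spec = SyntheticSpec(
            model_id="bimodal",
            true_params=self.TRUE,
            schedule=np.arange(0.0, 15.5, 0.5),
            noise_sd=2.0,
            seed=7,
        )
        curve = simulate_release(spec)
        a = fit_bimodal(curve, FitOptions(seed=1))
        b = fit_bimodal(curve, FitOptions(seed=1))
        assert a.params == b.params
        assert a.s_value == b.s_value

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_bimodal(ReleaseCurve([1, 2, 3], [10, 20, 30]))

    def test_quick_recovery_sweep_at_sigma_two(self):
        """Median relative parameter error stays small under 2 % noise."""
        errors = {"phi": [], "k1": [], "k2": []}
        for seed in range(12):
            spec = SyntheticSpec(
                model_id="bimodal",
                true_params=self.TRUE,
                schedule=np.arange(0.0, 15.5, 0.5),
                noise_sd=2.0,
                seed=5000 + seed,
            )
            fit = fit_bimodal(simulate_release(spec))
            errors["phi"].append(abs(fit.params.phi / self.TRUE.phi - 1))
            errors["k1"].append(abs(fit.params.k1 / self.TRUE.k1 - 1))
            errors["k2"].append(abs(fit.params.k2 / self.TRUE.k2 - 1))
        for name, errs in errors.items():
            assert np.median(errs) < 0.15, f"median {name} error {np.median(errs):.3f}"


class TestFitSingleTerm:
    def test_exact_recovery_on_single_exponential(self):
        times = np.arange(0.5, 12.5, 0.5)
        true = SingleTermParams(prefactor=0.85, rate=0.6)
        curve = ReleaseCurve(times, single_term_release_fraction(true, times))
        fit = fit_single_term(curve)
        assert fit.s_value < 1e-8
        assert fit.params.prefactor == pytest.approx(0.85, rel=1e-5)
        assert fit.params.rate == pytest.approx(0.6, rel=1e-5)

    def test_misfit_on_widely_separated_bimodal(self):
        times = np.arange(0.0, 15.5, 0.5)
        wide = BimodalParams(phi=0.4, k1=2.5, k2=0.1)  # K1/K2 = 25
        curve = curve_from_bimodal(wide, times)
        single = fit_single_term(curve)
        both = fit_bimodal(curve)
        assert single.s_value > 1.0
        assert single.s_value > 100 * max(both.s_value, 1e-8)

    def test_two_point_curve_is_an_error(self):
        with pytest.raises(ValidationError):
            fit_single_term(ReleaseCurve([1, 2], [20, 40]))


class TestFitSeries:
    CARRIER = SphericalCarrier(12.5e-9)

    def test_noiseless_recovery(self):
        d_true = 6e-22
        times = np.arange(0.25, 4.25, 0.25)
        curve = ReleaseCurve(
            times, series_release_fraction(SeriesParams(d_true), self.CARRIER, times)
        )
        fit = fit_series(curve, self.CARRIER)
        assert fit.params.diffusivity == pytest.approx(d_true, rel=1e-4)
        assert fit.converged

    def test_multistart_reaches_optimum_from_far_grid(self):
        """The start grid spans ~10 decades; recovery cannot depend on a
        good initial guess (the nearest grid point is ~1e6 off)."""
        d_true = 3.3e-22
        times = np.arange(0.25, 4.25, 0.25)
        curve = ReleaseCurve(
            times, series_release_fraction(SeriesParams(d_true), self.CARRIER, times)
        )
        fit = fit_series(curve, self.CARRIER)
        assert fit.params.diffusivity == pytest.approx(d_true, rel=1e-4)

    def test_series_cannot_match_pure_exponential(self):
        times = np.arange(0.0, 15.5, 0.5)
        curve = ReleaseCurve(times, 100.0 * (1.0 - np.exp(-0.3 * times)))
        fit = fit_series(curve, SphericalCarrier(69e-9))
        both = fit_bimodal(curve)
        assert both.s_value < 1e-6
        assert fit.s_value > 1.0  # fixed term amplitudes: structural misfit


class TestCompareModels:
    def test_ranking_on_paper_like_data(self, scenarios):
        spec = dataclasses.replace(scenarios["Fe-BTC-PTX"], noise_sd=2.0, seed=99)
        comparison = compare_models(simulate_release(spec), spec.carrier)
        assert comparison.ranking == ("bimodal", "series", "single_term")

    def test_identical_filtering_across_models(self, scenarios):
        spec = scenarios["mPEG-PCL-Fe-BTC-PTX"]
        comparison = compare_models(simulate_release(spec), spec.carrier)
        n = {res.n_points for res in comparison.results.values()}
        assert len(n) == 1

    def test_no_carrier_skips_series(self):
        times = np.arange(0.0, 15.5, 0.5)
        curve = curve_from_bimodal(BimodalParams(0.3, 1.5, 0.1), times)
        comparison = compare_models(curve)
        assert set(comparison.results) == {"bimodal", "single_term"}
        assert comparison.diffusivities == {}

    def test_bimodal_never_beaten_by_single_term(self, scenarios):
        # nested models: the single exponential is the phi->1 limit
        for spec in scenarios.values():
            curve = simulate_release(spec)
            comparison = compare_models(curve, spec.carrier)
            assert (
                comparison.results["bimodal"].s_value
                <= comparison.results["single_term"].s_value + 1e-6
            )

    def test_empty_after_filter_is_structured_error(self):
        curve = ReleaseCurve([1, 2, 3, 4], [99.1, 99.5, 99.9, 100])
        with pytest.raises(UninformativeCurveError):
            compare_models(curve)


class TestDiffusivityHelpers:
    def test_published_percent_changes(self):
        plain = fit_result_stub(BimodalParams(phi=0.254, k1=1.0, k2=0.04))
        composite = fit_result_stub(BimodalParams(phi=0.29, k1=1.74, k2=0.123))
        fast, slow = diffusivity_percent_change(
            plain,
            SphericalCarrier(69e-9),
            composite,
            SphericalCarrier(71.5e-9),
        )
        assert fast == pytest.approx(86, abs=2)
        assert slow == pytest.approx(230, rel=0.02)

    def test_identical_results_give_zero_change(self):
        result = fit_result_stub(BimodalParams(phi=0.3, k1=1.0, k2=0.1))
        carrier = SphericalCarrier(50e-9)
        fast, slow = diffusivity_percent_change(result, carrier, result, carrier)
        assert fast == 0.0 and slow == 0.0

    def test_fast_slow_ordering(self):
        result = fit_result_stub(BimodalParams(phi=0.3, k1=2.0, k2=0.5))
        d_fast, d_slow = fast_slow_diffusivities(result, SphericalCarrier(50e-9))
        assert d_fast > d_slow

    def test_requires_bimodal_result(self):
        times = np.arange(0.5, 12.5, 0.5)
        curve = ReleaseCurve(
            times,
            single_term_release_fraction(SingleTermParams(0.9, 0.5), times),
        )
        single = fit_single_term(curve)
        with pytest.raises(ValidationError):
            fast_slow_diffusivities(single, SphericalCarrier(50e-9))


def fit_result_stub(params: BimodalParams):
    """A minimal bimodal FitResult for conversion helpers (no fitting)."""
    from relkin.fitting import FitResult

    times = np.arange(0.5, 15.5, 0.5)
    release = bimodal_release_fraction(params, times)
    return FitResult(
        model_id="bimodal",
        params=params,
        s_value=0.0,
        n_points=len(times),
        residuals=np.zeros_like(times),
        n_starts=1,
        converged=True,
    )
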