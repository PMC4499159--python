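"""Four-parameter logistic fitting: identifiability, oracles, edge cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from berquant import (
    BindingSystem,
    FourParamLogistic,
    SyntheticConfig,
    dna_affinity_effect,
    fit_four_parameter,
    four_param_logistic,
    generate_titration,
    predict_four_parameter,
    summarize_replicates,
)
from berquant.curves import TitrationCurve


def _curve_from_params(f0, f_inf, ec50, hill_n, grid=None):
    cfg = SyntheticConfig(
        ec50=ec50, hill_n=hill_n, f0=f0, fold_change=f_inf / f0, cv=0.0,
        **({"concentrations": grid} if grid else {}),
    )
    curve, _ = generate_titration(cfg)
    return curve


class TestZeroNoiseIdentifiability:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        f0=st.floats(50, 500),
        fold=st.floats(1.9, 2.8),
        ec50=st.floats(23, 670),
        hill_n=st.floats(1.0, 2.4),
    )
    def test_recovers_generating_quadruple(self, f0, fold, ec50, hill_n):
        curve = _curve_from_params(f0, f0 * fold, ec50, hill_n)
        fit = fit_four_parameter(curve)
        assert fit.ok
        for got, want in [
            (fit.f0, f0),
            (fit.f_inf, f0 * fold),
            (fit.ec50, ec50),
            (fit.hill_n, hill_n),
        ]:
            assert abs(got - want) / want < 1e-6

    def test_worked_example(self):
        curve = _curve_from_params(100.0, 280.0, 84.0, 1.8)
        fit = fit_four_parameter(curve)
        assert fit.ec50 == pytest.approx(84.0, rel=1e-8)
        assert fit.hill_n == pytest.approx(1.8, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)


class TestPredict:
    def test_half_maximal_at_ec50(self, noiseless_curve):
        curve, truth = noiseless_curve
        fit = fit_four_parameter(curve)
        f_at_ec50 = predict_four_parameter(fit, fit.ec50)
        assert f_at_ec50 == pytest.approx((fit.f0 + fit.f_inf) / 2, rel=1e-12)

    def test_zero_and_saturating_limits(self, noiseless_curve):
        curve, _ = noiseless_curve
        fit = fit_four_parameter(curve)
        assert predict_four_parameter(fit, 0.0) == pytest.approx(fit.f0)
        assert predict_four_parameter(fit, 1e9) == pytest.approx(fit.f_inf, rel=1e-4)

    def test_refit_of_predicted_curve_is_idempotent(self, noiseless_curve):
        curve, _ = noiseless_curve
        fit = fit_four_parameter(curve)
        grid = curve.concentrations
        refit_curve = TitrationCurve.from_measurements(
            grid,
            [(v,) for v in predict_four_parameter(fit, grid)],
            probe_name="p",
            partner_name="q",
        )
        refit = fit_four_parameter(refit_curve)
        assert refit.ec50 == pytest.approx(fit.ec50, rel=1e-6)
        assert refit.hill_n == pytest.approx(fit.hill_n, rel=1e-6)

    def test_negative_concentration_rejected(self, noiseless_curve):
        curve, _ = noiseless_curve
        fit = fit_four_parameter(curve)
        with pytest.raises(ValueError):
            predict_four_parameter(fit, [-1.0])


class TestOptimizerQuality:
    def test_sse_beats_grid_search_oracle(self, rng):
        """On a fixed noisy curve the optimizer must at least match an
        exhaustive 20^4 grid search bracketing the truth."""
        cfg = SyntheticConfig(ec50=84, hill_n=1.8, fold_change=2.8, cv=0.02)
        curve, _ = generate_titration(cfg, rng)
        fit = fit_four_parameter(curve)
        c, y = curve.concentrations, curve.mean_intensities
        best = np.inf
        for f0 in np.linspace(80, 120, 20):
            for f_inf in np.linspace(220, 340, 20):
                for ec50 in np.linspace(42, 168, 20):
                    for n in np.linspace(0.9, 3.6, 20):
                        sse = float(
                            np.sum((y - four_param_logistic(c, f0, f_inf, ec50, n)) ** 2)
                        )
                        if sse < best:
                            best = sse
        assert fit.sse <= best

    def test_exact_isotherm_fit_recovers_kd_without_depletion(self):
        """With the probe far below Kd, the empirical EC50 approaches the
        thermodynamic Kd and the Hill slope approaches 1."""
        kd, probe = 100.0, 0.4
        system = BindingSystem(kd=kd, probe_total=probe, mode="exact-1:1")
        grid = np.concatenate([[0.0], np.logspace(0, 4, 14)])
        f = system.fluorescence(grid)
        curve = TitrationCurve.from_measurements(
            grid, [(v,) for v in f], probe_name="p", partner_name="q",
            probe_concentration=probe,
        )
        fit = fit_four_parameter(curve)
        assert abs(fit.ec50 - kd) / kd < 0.02
        assert abs(fit.hill_n - 1.0) < 0.05


class TestEdgeCases:
    def test_no_binding_detected_withholds_parameters(self):
        curve = _curve_from_params(100.0, 105.0, 84.0, 1.8)  # 1.05-fold rise
        fit = fit_four_parameter(curve)
        assert fit.converged and not fit.binding_detected
        assert np.isnan(fit.ec50) and np.isnan(fit.hill_n)
        assert "no binding detected" in fit.message

    def test_short_curve_refused(self):
        curve = TitrationCurve.from_measurements(
            [0, 10, 100, 1000], [(100,), (150,), (200,), (220,)],
            probe_name="p", partner_name="q",
        )
        with pytest.raises(ValueError, match="at least 6"):
            fit_four_parameter(curve)

    def test_missing_zero_point_refused(self):
        curve = TitrationCurve.from_measurements(
            [1, 3, 10, 30, 100, 300, 1000],
            [(110,), (120,), (150,), (190,), (230,), (260,), (275,)],
            probe_name="p", partner_name="q",
        )
        with pytest.raises(ValueError, match="zero-concentration"):
            fit_four_parameter(curve)

    def test_sklearn_estimator_contract(self, noiseless_curve):
        curve, _ = noiseless_curve
        est = FourParamLogistic(no_binding_fold_threshold=1.2)
        assert est.get_params()["no_binding_fold_threshold"] == 1.2
        est.set_params(no_binding_fold_threshold=1.1)
        est.fit(curve.concentrations, curve.mean_intensities)
        assert est.ec50_ == pytest.approx(84.0, rel=1e-6)
        assert est.score(curve.concentrations, curve.mean_intensities) > 0.999


class TestReplicateSummary:
    def test_mean_and_sd(self, noiseless_curve):
        curve, _ = noiseless_curve
        from dataclasses import replace

        base = fit_four_parameter(curve)
        fits = [replace(base, ec50=v) for v in (110.0, 120.0, 130.0)]
        summ = summarize_replicates(fits)
        assert summ["ec50"].mean == pytest.approx(120.0)
        assert summ["ec50"].sd == pytest.approx(10.0)
        assert summ["ec50"].n_replicates == 3

    def test_single_fit_withholds_sd(self, noiseless_curve):
        curve, _ = noiseless_curve
        summ = summarize_replicates([fit_four_parameter(curve)])
        assert summ["ec50"].sd is None

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_replicates([])

    def test_monte_carlo_sd_same_order_as_reported(self, rng):
        """Replicate-fit scatter at the calibrated noise level should be of
        the same order as the ~12% SDs typical of such titrations."""
        cfg = SyntheticConfig(ec50=120.0, hill_n=1.0, fold_change=2.2, cv=0.02)
        fits = [fit_four_parameter(generate_titration(cfg, rng)[0]) for _ in range(40)]
        summ = summarize_replicates(fits)
        assert 14 / 4 < summ["ec50"].sd < 14 * 4


class TestDnaAffinityEffect:
    def test_identity(self):
        assert dna_affinity_effect(84.0, 84.0) == pytest.approx(1.0)

    def test_two_fold_weakening(self):
        assert dna_affinity_effect(168.0, 84.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("bad", [(0.0, 84.0), (84.0, -1.0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            dna_affinity_effect(*bad)

    def test_simulated_ratio_recovers_truth(self, rng):
        cfg = SyntheticConfig(ec50=84.0, hill_n=1.8, fold_change=2.8, cv=0.02)
        cfg2 = SyntheticConfig(ec50=168.0, hill_n=1.8, fold_change=2.8, cv=0.02)
        ratios = []
        for _ in range(40):
            f1 = fit_four_parameter(generate_titration(cfg, rng)[0])
            f2 = fit_four_parameter(generate_titration(cfg2, rng)[0])
            ratios.append(dna_affinity_effect(f2.ec50, f1.ec50))
        r = np.asarray(ratios)
        se = r.std(ddof=1) / np.sqrt(r.size)
        assert abs(r.mean() - 2.0) < 3 * se + 0.01
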