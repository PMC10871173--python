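import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rspmf.neurons import TransferCurve
from rspmf.rsp import (
    RSPParams,
    RefractorySoftPlusModel,
    fit_baselines,
    fit_refractory_softplus,
    normalized_rms_error,
    refractory_softplus,
    refractory_softplus_derivative,
    softplus,
)

TYPICAL = RSPParams(alpha=0.0108, beta=2.47, sigma0=3.42, t_ref=1.91)


def synthetic_curve(params: RSPParams, q: float, S: int = 60, noise_sd: float = 0.0,
                    seed: int = 0, d_max: float = 100.0) -> TransferCurve:
    rates_in = np.linspace(0.0, d_max, S) / q**2
    rates = refractory_softplus(rates_in, params, q)
    if noise_sd > 0:
        rates = np.maximum(
            rates + np.random.default_rng(seed).normal(0.0, noise_sd, S), 0.0
        )
    return TransferCurve(rates_in, rates, q=q, eta=0.8, duration=100.0)


class TestSoftPlus:
    def test_value_at_zero(self):
        for beta in (0.5, 1.0, 7.0):
            assert softplus(0.0, beta) == pytest.approx(math.log(2.0) / beta)

    def test_cutoff_accuracy(self):
        """The ramp cutoff at beta*x = 20 is exact to ~1e-10 relative error."""
        rel_err = math.log1p(math.exp(20.0)) / 20.0 - 1.0
        assert rel_err == pytest.approx(1.03e-10, rel=0.05)
        # and the implementation switches to the exact ramp there
        assert softplus(21.0, 1.0) == 21.0

    def test_left_asymptote(self):
        assert softplus(-50.0, 1.0) == pytest.approx(math.exp(-50.0), rel=1e-6)

    @given(x=st.floats(-30, 30), beta=st.floats(0.1, 50))
    def test_positive_and_above_ramp(self, x, beta):
        val = softplus(x, beta)
        if beta * x > -700:  # below this the true value underflows doubles
            assert val > 0
        assert val >= max(x, 0.0) - 1e-12


class TestRefractorySoftPlus:
    def test_closed_form_at_offset(self):
        p = TYPICAL
        R = (p.sigma0 / 5.0) ** 2  # q*sqrt(R) == sigma0 at q=5
        expected = 1000.0 / (p.t_ref + p.beta / (p.alpha * math.log(2.0)))
        assert refractory_softplus(R, p, 5.0) == pytest.approx(expected, rel=1e-9)

    def test_refractory_ceiling(self):
        p = TYPICAL
        assert refractory_softplus(1e9, p, 5.0) == pytest.approx(
            1000.0 / p.t_ref, rel=1e-3
        )

    def test_relu_asymptote_without_refractoriness(self):
        p = RSPParams(alpha=0.01, beta=5.0, sigma0=1.0, t_ref=0.0)
        R = 400.0  # q*sqrt(R) = 20 >> sigma0
        expected = 1000.0 * p.alpha * (1.0 * math.sqrt(R) - p.sigma0)
        assert refractory_softplus(R, p, 1.0) == pytest.approx(expected, rel=1e-3)

    @given(
        alpha=st.floats(1e-3, 0.1),
        beta=st.floats(0.2, 20.0),
        sigma0=st.floats(-2.0, 8.0),
        t_ref=st.floats(0.1, 5.0),
    )
    def test_monotone_and_bounded(self, alpha, beta, sigma0, t_ref):
        """S_ref is strictly increasing in R and capped at 1000/t_ref Hz."""
        p = RSPParams(alpha, beta, sigma0, t_ref)
        grid = np.linspace(0.0, 200.0, 400)
        rates = refractory_softplus(grid, p, 1.0)
        assert np.all(np.diff(rates) > 0)
        assert np.all(rates > 0)
        assert np.all(rates <= 1000.0 / t_ref + 1e-9)

    def test_derivative_matches_finite_difference(self):
        p = TYPICAL
        for R in (0.5, 1.0, 2.5):
            h = 1e-6
            fd = (
                refractory_softplus(R + h, p, 5.0) - refractory_softplus(R - h, p, 5.0)
            ) / (2 * h)
            assert refractory_softplus_derivative(R, p, 5.0) == pytest.approx(
                fd, rel=1e-5
            )


class TestFitting:
    def test_exact_recovery_from_noiseless_curve(self):
        curve = synthetic_curve(TYPICAL, q=5.0)
        fit = fit_refractory_softplus(curve)
        assert fit.converged
        assert fit.nrmse < 1e-6
        recovered = fit.params.as_array()
        assert np.allclose(recovered, TYPICAL.as_array(), rtol=1e-4)

    def test_recovery_under_rate_noise(self):
        """2% multiplicative-scale noise leaves t_ref within half a millisecond."""
        mx = refractory_softplus(4.0, TYPICAL, 5.0)
        curve = synthetic_curve(TYPICAL, q=5.0, S=200, noise_sd=0.02 * mx, seed=4)
        fit = fit_refractory_softplus(curve)
        assert abs(fit.params.t_ref - TYPICAL.t_ref) < 0.5

    def test_lif_fit_quality_moderate_budget(self, lif_curve_small):
        fit = fit_refractory_softplus(lif_curve_small)
        assert fit.converged
        assert fit.nrmse < 0.05

    def test_five_point_curve_fits_to_a_few_percent(self, lif_curve_small):
        sub = lif_curve_small.subsample(5)
        fit = fit_refractory_softplus(sub)
        assert normalized_rms_error(fit.params, lif_curve_small) < 0.08

    def test_all_zero_curve_flagged(self):
        curve = TransferCurve(
            np.linspace(0, 4, 10), np.zeros(10), q=5.0, eta=0.8, duration=1.0
        )
        fit = fit_refractory_softplus(curve)
        assert not fit.converged

    def test_too_few_points_rejected(self):
        curve = TransferCurve(
            np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]),
            q=1.0, eta=0.5, duration=1.0,
        )
        with pytest.raises(ValueError):
            RefractorySoftPlusModel(curve)

    def test_summary_mentions_all_parameters(self, lif_curve_small):
        fit = fit_refractory_softplus(lif_curve_small)
        text = fit.summary()
        for name in ("alpha", "beta", "sigma0", "t_ref", "nrmse"):
            assert name in text

    def test_json_roundtrip(self, tmp_path, lif_curve_small):
        import json

        fit = fit_refractory_softplus(lif_curve_small)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["t_ref_ms"] == pytest.approx(fit.params.t_ref)
        assert payload["q_mV"] == 1.0


class TestNRMSE:
    def test_zero_for_generating_params(self):
        curve = synthetic_curve(TYPICAL, q=5.0)
        assert normalized_rms_error(TYPICAL, curve) == pytest.approx(0.0, abs=1e-12)

    def test_three_point_toy_closed_form(self):
        # observations (0, 0, 30); predictions from a constant-30 surrogate:
        # rms = sqrt((900+900+0)/3)/30 = sqrt(600)/30
        obs = np.array([0.0, 0.0, 30.0])
        pred = np.full(3, 30.0)
        expected = math.sqrt(np.mean((pred - obs) ** 2)) / 30.0
        assert expected == pytest.approx(math.sqrt(600.0) / 30.0)

    @given(scale=st.floats(0.1, 10.0))
    def test_scale_invariance(self, scale):
        """Jointly rescaling rates and predictions leaves the metric unchanged."""
        curve = synthetic_curve(TYPICAL, q=5.0, S=30, noise_sd=1.0, seed=9)
        base = normalized_rms_error(TYPICAL, curve)
        scaled = TransferCurve(
            curve.rates_in, curve.rates_out * scale, q=curve.q,
            eta=curve.eta, duration=curve.duration,
        )
        pred = refractory_softplus(curve.rates_in, TYPICAL, curve.q)
        rms = math.sqrt(np.mean((pred * scale - scaled.rates_out) ** 2))
        assert rms / (scale * curve.rates_out.max()) == pytest.approx(base, rel=1e-9)

    def test_all_zero_curve_rejected(self):
        curve = TransferCurve(
            np.linspace(0, 4, 10), np.zeros(10), q=5.0, eta=0.8, duration=1.0
        )
        with pytest.raises(ValueError):
            normalized_rms_error(TYPICAL, curve)


class TestBaselines:
    def test_relu_exact_on_linear_curve(self):
        x_in = np.linspace(0.0, 100.0, 30)
        rates = 2.0 * np.maximum(np.sqrt(x_in) - 1.0, 0.0)
        curve = TransferCurve(x_in, rates, q=1.0, eta=0.5, duration=1.0)
        fits = fit_baselines(curve)
        assert fits["relu"].nrmse < 1e-8

    def test_rsp_beats_relu_on_lif_curve(self, lif_curve_small):
        rsp = fit_refractory_softplus(lif_curve_small)
        base = fit_baselines(lif_curve_small)
        assert rsp.nrmse <= base["relu"].nrmse

    def test_sigmoid_saturates_in_extrapolation(self, lif_curve_small):
        """A sigmoid fitted to the left half underpredicts the right half."""
        curve = lif_curve_small
        half = len(curve) // 2
        left = TransferCurve(
            curve.rates_in[:half], curve.rates_out[:half], q=curve.q,
            eta=curve.eta, duration=curve.duration,
        )
        sig = fit_baselines(left)["sigmoid"]
        pred_right = sig.predict(curve.rates_in[half:])
        obs_right = curve.rates_out[half:]
        mx = obs_right.max()
        right_err = np.sqrt(np.mean((pred_right - obs_right) ** 2)) / mx
        assert right_err > 2 * sig.nrmse
        assert pred_right.max() < obs_right.max()
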