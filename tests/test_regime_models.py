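import numpy as np
import pytest

import cgmchaos as cc
from cgmchaos.chaos_analysis import EmbeddingSpec, embed
from cgmchaos.regime_models import (
    DegenerateRegimeError,
    LstarGrid,
    _design_and_targets,
    fit_aar,
    fit_lar,
    fit_lstar,
    fit_nnar,
    fit_setar,
    predict_matrix,
    predict_one_step,
    select_model,
)


def ar2_series(n=1200, noise=0.1, seed=42, shift=5.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n + 100)
    e = rng.standard_normal(n + 100) * noise
    for t in range(2, len(x)):
        x[t] = 0.3 + 0.5 * x[t - 1] + 0.3 * x[t - 2] + e[t]
    return x[100:] + shift


def setar_series(n=2000, th=0.0, seed=0, noise=0.1):
    """Two clearly distinct regimes switching on the previous value."""
    rng = np.random.default_rng(seed)
    x = np.zeros(n + 100)
    for t in range(1, len(x)):
        if x[t - 1] <= th:
            x[t] = 0.6 + 0.8 * x[t - 1] + noise * rng.standard_normal()
        else:
            x[t] = -0.4 - 0.5 * x[t - 1] + noise * rng.standard_normal()
    return x[100:]


def lstar_series(n=2000, c=0.0, gamma=10.0, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    x = np.zeros(n + 100)
    for t in range(1, len(x)):
        G = 1.0 / (1.0 + np.exp(-gamma * (x[t - 1] - c)))
        low = 0.6 + 0.8 * x[t - 1]
        high = -0.4 - 0.5 * x[t - 1]
        x[t] = (1 - G) * low + G * high + noise * rng.standard_normal()
    return x[100:]


class TestLar:
    def test_noiseless_recurrence_recovered_exactly(self):
        x = np.zeros(300)
        x[0], x[1] = 1.0, 0.5
        for t in range(2, 300):
            x[t] = 0.4 + 0.6 * x[t - 1] + 0.3 * x[t - 2]
        mdl = fit_lar(embed(x, EmbeddingSpec(m=2, tau=1)))
        # columns are in ascending time: [lag 2, lag 1]
        assert mdl.parameters["intercept"] == pytest.approx(0.4, abs=1e-8)
        assert np.allclose(mdl.parameters["coefficients"], [0.3, 0.6], atol=1e-8)

    def test_iid_targets_give_null_slopes(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(3000)
        mdl = fit_lar(embed(x, EmbeddingSpec(m=3, tau=1)))
        # OLS slope standard error ~ 1/sqrt(n)
        assert np.abs(mdl.parameters["coefficients"]).max() < 3.0 / np.sqrt(3000)

    def test_constant_series(self):
        mdl = fit_lar(embed(np.full(50, 7.0), EmbeddingSpec(m=2, tau=1)))
        assert predict_one_step(mdl, np.array([7.0, 7.0])) == pytest.approx(7.0)

    def test_collinear_design_raises(self):
        x = np.arange(100.0)  # perfectly collinear lags
        with pytest.raises(np.linalg.LinAlgError):
            fit_lar(embed(x, EmbeddingSpec(m=3, tau=1)))


class TestAar:
    def test_linear_truth_matches_lar(self):
        x = ar2_series()
        pm = embed(x, EmbeddingSpec(m=2, tau=1))
        lar, aar = fit_lar(pm), fit_aar(pm)
        X, y = _design_and_targets(pm)
        rmse_lar = np.sqrt(np.mean((predict_matrix(lar, X) - y) ** 2))
        rmse_aar = np.sqrt(np.mean((predict_matrix(aar, X) - y) ** 2))
        assert abs(rmse_aar - rmse_lar) <= 0.01 * rmse_lar

    def test_constant_series_predicts_constant(self):
        mdl = fit_aar(embed(np.full(60, 3.0), EmbeddingSpec(m=2, tau=1)))
        assert predict_one_step(mdl, np.array([3.0, 3.0])) == pytest.approx(3.0)

    def test_quadratic_truth_beats_lar(self):
        rng = np.random.default_rng(7)
        x = np.zeros(1500)
        x[0] = 0.3
        for t in range(1, 1500):
            x[t] = 0.9 * x[t - 1] ** 2 - 0.5 + 0.02 * rng.standard_normal()
        x += 5.0
        pm = embed(x, EmbeddingSpec(m=1, tau=1))
        assert fit_aar(pm).fit_mape < fit_lar(pm).fit_mape


class TestNnar:
    def test_refit_is_bit_reproducible(self):
        pm = embed(ar2_series(400), EmbeddingSpec(m=2, tau=1))
        a = fit_nnar(pm, q=2, seed=3)
        b = fit_nnar(pm, q=2, seed=3)
        assert np.array_equal(a.parameters["hidden_weights"], b.parameters["hidden_weights"])
        assert a.fit_mape == b.fit_mape

    def test_linear_truth_close_to_lar(self):
        x = ar2_series()
        pm = embed(x, EmbeddingSpec(m=2, tau=1))
        lar, nn = fit_lar(pm), fit_nnar(pm, seed=0)
        assert abs(nn.fit_mape - lar.fit_mape) <= 0.05 * lar.fit_mape

    def test_auto_width_stays_small_on_simple_data(self):
        pm = embed(ar2_series(800), EmbeddingSpec(m=2, tau=1))
        mdl = fit_nnar(pm, q="auto", seed=1)
        assert mdl.parameters["q"] <= 4


class TestSetar:
    def test_parameter_recovery(self):
        pm = embed(setar_series(seed=1), EmbeddingSpec(m=2, tau=1))
        mdl = fit_setar(pm)
        p = mdl.parameters
        assert abs(p["threshold"] - 0.0) < 0.1
        # most-recent-lag coefficient of each regime (ascending columns)
        assert p["low_coefficients"][-1] == pytest.approx(0.8, abs=0.1)
        assert p["high_coefficients"][-1] == pytest.approx(-0.5, abs=0.1)

    def test_identical_regimes_lose_to_lar_on_aic(self):
        pm = embed(ar2_series(noise=0.1, seed=8), EmbeddingSpec(m=2, tau=1))
        lar, setar = fit_lar(pm), fit_setar(pm)
        assert select_model([lar, setar]).kind == "LAR"

    def test_regime_occupancy_at_least_10_percent(self):
        pm = embed(setar_series(seed=2), EmbeddingSpec(m=2, tau=1))
        mdl = fit_setar(pm)
        from cgmchaos.regime_models import _threshold_column

        X, _ = _design_and_targets(pm)
        Yt = X[:, _threshold_column(2, mdl.parameters["delta"])]
        frac = np.mean(Yt <= mdl.parameters["threshold"])
        assert 0.10 <= frac <= 0.90

    def test_degenerate_threshold_variable_raises(self):
        with pytest.raises((DegenerateRegimeError, np.linalg.LinAlgError)):
            fit_setar(embed(np.full(100, 1.0), EmbeddingSpec(m=2, tau=1)))


class TestLstar:
    def test_default_grid_shape(self):
        g = LstarGrid()
        assert g.n_thresholds == 200
        assert g.n_smoothing == 40
        assert g.n_points == 8000
        assert g.gamma_range == (1.0, 40.0)
        assert g.c_quantile_range == (0.1, 0.9)
        assert g.min_regime_fraction == 0.10

    def test_parameter_recovery(self):
        pm = embed(lstar_series(seed=4), EmbeddingSpec(m=2, tau=1))
        mdl = fit_lstar(pm)
        p = mdl.parameters
        assert abs(p["c"] - 0.0) < 3 * p["c_grid_resolution"]
        assert 5.0 <= p["gamma"] <= 15.0  # within 50% of 10

    def test_prediction_at_c_is_regime_average(self):
        pm = embed(lstar_series(seed=5), EmbeddingSpec(m=2, tau=1))
        mdl = fit_lstar(pm)
        p = mdl.parameters
        vec = np.array([0.1, p["c"]])  # threshold variable (delta=0) at c
        low = p["low_intercept"] + p["low_coefficients"] @ vec
        high = p["high_intercept"] + p["high_coefficients"] @ vec
        assert predict_one_step(mdl, vec) == pytest.approx((low + high) / 2)

    def test_large_gamma_limit_matches_setar(self):
        # regimes continuous at the threshold, glucose-like scale: the
        # logistic's transition band is negligible and LSTAR(gamma=40)
        # reproduces the hard-threshold model
        rng = np.random.default_rng(9)
        x = np.zeros(2100)
        for t in range(1, 2100):
            if x[t - 1] <= 0.0:
                x[t] = 6.0 + 0.8 * x[t - 1] + rng.standard_normal()
            else:
                x[t] = 6.0 - 0.5 * x[t - 1] + rng.standard_normal()
        pm = embed(x[100:], EmbeddingSpec(m=2, tau=1))
        setar = fit_setar(pm, delta=0)
        lstar = fit_lstar(pm, gamma_fixed=40.0)
        X, y = _design_and_targets(pm)
        rel = np.sqrt(np.mean((predict_matrix(setar, X) - predict_matrix(lstar, X)) ** 2))
        assert rel <= 0.02 * np.std(y)


class TestSelection:
    def test_lower_aic_wins(self):
        pm = embed(ar2_series(300), EmbeddingSpec(m=2, tau=1))
        a = fit_lar(pm)
        b = fit_lar(pm)
        a.fit_aic, a.fit_mape = -1418.52, 0.002
        b.fit_aic, b.fit_mape = -1440.71, 0.002
        assert select_model([a, b]) is b

    def test_aic_tie_broken_by_mape(self):
        pm = embed(ar2_series(300), EmbeddingSpec(m=2, tau=1))
        a, b = fit_lar(pm), fit_lar(pm)
        a.fit_aic = b.fit_aic = -100.0
        a.fit_mape, b.fit_mape = 0.002, 0.001
        assert select_model([a, b]) is b

    def test_single_candidate_returned(self):
        pm = embed(ar2_series(300), EmbeddingSpec(m=2, tau=1))
        mdl = fit_lar(pm)
        assert select_model([mdl]) is mdl

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class TestPredictOneStep:
    def test_dimension_mismatch_rejected(self):
        mdl = fit_lar(embed(ar2_series(300), EmbeddingSpec(m=2, tau=1)))
        with pytest.raises(ValueError):
            predict_one_step(mdl, np.array([1.0, 2.0, 3.0]))

    def test_setar_branches_on_threshold(self):
        pm = embed(setar_series(seed=3), EmbeddingSpec(m=2, tau=1))
        mdl = fit_setar(pm)
        p = mdl.parameters
        below = np.array([0.0, p["threshold"] - 0.5])
        expected = p["low_intercept"] + p["low_coefficients"] @ below
        assert predict_one_step(mdl, below) == pytest.approx(expected)

    def test_constant_model_predicts_intercept(self):
        mdl = fit_lar(embed(ar2_series(300), EmbeddingSpec(m=2, tau=1)))
        mdl.parameters["intercept"] = 1.0
        mdl.parameters["coefficients"] = np.zeros(2)
        assert predict_one_step(mdl, np.array([123.0, -5.0])) == 1.0


def test_nesting_property_on_linear_truth():
    """All five model families contain the linear map: in-sample MAPEs agree."""
    pm = embed(ar2_series(), EmbeddingSpec(m=2, tau=1))
    lar = fit_lar(pm)
    others = [
        fit_aar(pm),
        fit_nnar(pm, seed=0),
        fit_setar(pm),
        fit_lstar(pm),
    ]
    for mdl in others:
        assert abs(mdl.fit_mape - lar.fit_mape) <= 0.05 * lar.fit_mape, mdl.kind
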