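"""Calibration loss, analytic gradients and parameter fitting."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import spearmanr

from radflow import (CalibrationData, GRMParameters, SGDConfig, ValidationError,
                     fit, generate_localities, generate_migration_truth,
                     haversine_matrix, loss, loss_and_gradient, model_flows,
                     normalize_table, predicted_delta, radiation_flows,
                     intervening_mass, run_realizations, SyntheticScenario)
from radflow.features import NormalizedFeatureTable


def make_data(scenario, feature_names=None, method="logistic_z"):
    localities, features = generate_localities(scenario)
    _, advanced = generate_migration_truth(localities, features, scenario)
    if feature_names:
        features = features.select(feature_names)
    norm = normalize_table(features, method)
    return CalibrationData(advanced, norm, haversine_matrix(advanced),
                          scenario.base_year, scenario.base_year + scenario.timestep_years,
                          scenario.birth_rate, scenario.death_rate), scenario


def brute_predicted_delta(params, data):
    """O(n^2) double-loop oracle for the population-balance prediction."""
    f = data.features.values
    u = np.maximum(f @ params.weights, 1e-9)
    p = data.localities.population(data.base_year)
    n = len(p)
    alpha = params.alpha_for(n)
    d = data.distances.values
    delta = np.empty(n)
    flows = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = sum(u[k] for k in range(n) if k not in (i, j) and d[i, k] < d[i, j])
            flows[i, j] = alpha[i] * p[i] * u[i] * u[j] / ((u[i] + s) * (u[i] + u[j] + s))
    growth = (1 + data.birth_rate - data.death_rate) ** data.timestep - 1
    for i in range(n):
        delta[i] = growth * p[i] + flows[:, i].sum() - flows[i, :].sum()
    return delta


class TestPredictedDelta:
    def test_no_migration_balanced_rates_zero(self):
        sc = SyntheticScenario(n_localities=8, seed=2, birth_rate=0.01, death_rate=0.01)
        data, _ = make_data(sc)
        params = GRMParameters(list(data.features.feature_names),
                               np.ones(len(data.features.feature_names)),
                               np.full(8, logit(1e-12)))
        assert np.allclose(predicted_delta(params, data), 0.0, atol=1e-6)

    def test_brute_force_oracle_four_localities(self):
        sc = SyntheticScenario(n_localities=4, seed=5)
        data, _ = make_data(sc)
        rng = np.random.default_rng(1)
        params = GRMParameters(list(data.features.feature_names),
                               rng.normal(0, 1, len(data.features.feature_names)),
                               rng.normal(-2, 0.5, 4))
        assert np.allclose(predicted_delta(params, data),
                           brute_predicted_delta(params, data), rtol=1e-9)

    def test_brute_force_oracle_larger_instance(self):
        sc = SyntheticScenario(n_localities=17, seed=8)
        data, _ = make_data(sc)
        rng = np.random.default_rng(2)
        params = GRMParameters(list(data.features.feature_names),
                               rng.normal(0, 0.5, len(data.features.feature_names)),
                               rng.normal(-3, 0.5, 17))
        assert np.allclose(predicted_delta(params, data),
                           brute_predicted_delta(params, data), rtol=1e-9)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        sc = SyntheticScenario(n_localities=10, seed=3)
        data, scenario = make_data(sc)
        # truth parameters reproduce the generated deltas exactly
        w = np.array([scenario.true_weights[n] for n in data.features.feature_names])
        params = GRMParameters(list(data.features.feature_names), w,
                               logit(scenario.alpha_vector()))
        rel = loss(params, data) / np.mean(data.observed_delta ** 2)
        assert rel < 1e-18

    def test_hand_residuals(self):
        # residuals [3, -4] -> MSE (9+16)/2 = 12.5; checked through the public op
        sc = SyntheticScenario(n_localities=2, seed=0)
        data, scenario = make_data(sc)
        w = np.array([scenario.true_weights[n] for n in data.features.feature_names])
        params = GRMParameters(list(data.features.feature_names), w,
                               logit(scenario.alpha_vector()))
        delta_hat = predicted_delta(params, data)
        shifted = data.localities.with_population(
            2010, data.localities.population(2007) + delta_hat - np.array([3.0, -4.0]))
        data2 = CalibrationData(shifted, data.features, data.distances, 2007, 2010,
                                scenario.birth_rate, scenario.death_rate)
        assert loss(params, data2) == pytest.approx(12.5, rel=1e-6)

    def test_loss_nonnegative(self):
        sc = SyntheticScenario(n_localities=6, seed=9)
        data, _ = make_data(sc)
        rng = np.random.default_rng(0)
        for _ in range(5):
            params = GRMParameters(list(data.features.feature_names),
                                   rng.normal(0, 1, len(data.features.feature_names)),
                                   rng.normal(-2, 1, 6))
            assert loss(params, data) >= 0


class TestGradient:
    @pytest.mark.parametrize("n,k_features", [(5, 3), (9, 5)])
    def test_matches_central_finite_differences(self, n, k_features):
        sc = SyntheticScenario(n_localities=n, seed=n,
                               amenity_types=("school", "shop", "tourism")[:k_features - 2])
        data, _ = make_data(sc)
        k = len(data.features.feature_names)
        rng = np.random.default_rng(0)
        w = rng.normal(0, 0.5, k)
        a_pre = rng.normal(-2.5, 0.3, n)
        params = GRMParameters(list(data.features.feature_names), w, a_pre)
        _, gw, ga = loss_and_gradient(params, data)
        h = 1e-5

        def fd(vec, idx, which):
            out = []
            for sign in (+1, -1):
                v = vec.copy()
                v[idx] += sign * h
                p = (GRMParameters(params.feature_names, v, a_pre) if which == "w"
                     else GRMParameters(params.feature_names, w, v))
                out.append(loss(p, data))
            return (out[0] - out[1]) / (2 * h)

        for idx in range(k):
            num = fd(w, idx, "w")
            assert gw[idx] == pytest.approx(num, rel=1e-4)
        for idx in range(n):
            num = fd(a_pre, idx, "a")
            assert ga[idx] == pytest.approx(num, rel=1e-4)

    def test_shared_alpha_gradient(self):
        sc = SyntheticScenario(n_localities=6, seed=1)
        data, _ = make_data(sc)
        k = len(data.features.feature_names)
        w = np.full(k, 0.4)
        params = GRMParameters(list(data.features.feature_names), w, np.asarray(-2.0))
        _, _, ga = loss_and_gradient(params, data)
        h = 1e-5
        lp = loss(GRMParameters(params.feature_names, w, np.asarray(-2.0 + h)), data)
        lm = loss(GRMParameters(params.feature_names, w, np.asarray(-2.0 - h)), data)
        assert float(ga) == pytest.approx((lp - lm) / (2 * h), rel=1e-4)


class TestFit:
    def test_rm_configuration_reproduces_radiation_flows(self):
        # single population feature, no normalization, frozen unit weight
        sc = SyntheticScenario(n_localities=12, seed=4)
        data, _ = make_data(sc, feature_names=["population"], method="none")
        cfg = SGDConfig(learning_rate=0.05, epochs=30, seed=0, optimizer="adam",
                        freeze_weights=True)
        res = fit(data, cfg)
        assert np.array_equal(res.params.weights, [1.0])
        pop = data.localities.population(2007)
        s = intervening_mass(pop, data.distances)
        expected = radiation_flows(res.params.alpha_for(12) * pop, pop, s)
        got = model_flows(res.params, data)
        assert got.mass_type == "population"
        assert np.array_equal(got.values, expected.values)

    def test_loss_decreases(self):
        sc = SyntheticScenario(n_localities=20, seed=0)
        data, _ = make_data(sc)
        res = fit(data, SGDConfig(learning_rate=0.05, epochs=50, seed=0, optimizer="adam"))
        assert res.final_loss < res.loss_history[0]

    def test_plain_sgd_also_decreases(self):
        sc = SyntheticScenario(n_localities=15, seed=2)
        data, _ = make_data(sc)
        res = fit(data, SGDConfig(learning_rate=1e-9, epochs=40, seed=0, optimizer="sgd"))
        assert res.final_loss < res.loss_history[0]

    def test_alpha_stays_in_unit_interval(self):
        sc = SyntheticScenario(n_localities=10, seed=7)
        data, _ = make_data(sc)
        res = fit(data, SGDConfig(learning_rate=0.2, epochs=40, seed=1, optimizer="adam"))
        a = res.params.alpha
        assert ((a > 0) & (a < 1)).all()

    def test_noiseless_truth_delta_mse_below_one_percent_of_variance(self):
        sc = SyntheticScenario(n_localities=60, seed=12)
        data, _ = make_data(sc)
        res = fit(data, SGDConfig(learning_rate=0.05, epochs=300, seed=0, optimizer="adam"))
        assert res.final_loss < 0.01 * data.observed_delta.var()

    def test_weight_recovery_single_seed(self):
        sc = SyntheticScenario(n_localities=120, seed=3)
        w = dict(sc.true_weights)
        w["population"] = w["population_density"] = 0.0
        sc.true_weights = w
        localities, features = generate_localities(sc)
        _, advanced = generate_migration_truth(localities, features, sc)
        amen = features.select(list(sc.amenity_types))
        norm = normalize_table(amen, "logistic_z")
        data = CalibrationData(advanced, norm, haversine_matrix(advanced), 2007, 2010,
                               sc.birth_rate, sc.death_rate)
        res = fit(data, SGDConfig(learning_rate=0.05, epochs=500, seed=0,
                                  optimizer="adam", shared_alpha=True))
        true_w = np.array([w[a] for a in sc.amenity_types])
        rho = spearmanr(true_w, res.params.weights).statistic
        assert rho >= 0.8

    def test_mini_batching_runs(self):
        sc = SyntheticScenario(n_localities=16, seed=5)
        data, _ = make_data(sc)
        res = fit(data, SGDConfig(learning_rate=0.05, epochs=20, seed=0,
                                  optimizer="adam", batch_size=4))
        assert len(res.loss_history) == 20

    def test_params_json_round_trip(self):
        sc = SyntheticScenario(n_localities=8, seed=6)
        data, _ = make_data(sc)
        res = fit(data, SGDConfig(learning_rate=0.05, epochs=5, seed=0, optimizer="adam"))
        back = GRMParameters.from_json(res.params.to_json())
        assert np.array_equal(back.weights, res.params.weights)
        assert np.array_equal(back.alpha_pre, res.params.alpha_pre)


class TestRunRealizations:
    def _data(self):
        sc = SyntheticScenario(n_localities=12, seed=1)
        return make_data(sc)[0]

    def test_single_realization_equals_fit(self):
        data = self._data()
        cfg = SGDConfig(learning_rate=0.05, epochs=10, seed=3, optimizer="adam")
        single = fit(data, cfg)
        batch = run_realizations(data, cfg, 1)
        assert np.array_equal(single.params.weights, batch[0].params.weights)

    def test_deterministic_and_spread(self):
        data = self._data()
        cfg = SGDConfig(learning_rate=0.05, epochs=10, seed=0, optimizer="adam")
        a = run_realizations(data, cfg, 4)
        b = run_realizations(data, cfg, 4)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.params.weights, rb.params.weights)
        first_weight = [r.params.weights[0] for r in a]
        assert np.std(first_weight) > 0

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SGDConfig(learning_rate=0.0)
        with pytest.raises(ValidationError):
            SGDConfig(epochs=0)
        with pytest.raises(ValidationError):
            SGDConfig(optimizer="newton")
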