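import numpy as np
import pytest

from befstress.estimation import (
    CommunityGLVModel,
    ObjectiveConfig,
    fit_monocultures,
    logistic,
    mape_objective,
)


class TestMapeObjective:
    def test_perfect_prediction_is_zero(self):
        obs = np.array([[100.0, 50.0], [200.0, 80.0]])
        assert mape_objective(obs, obs) == 0

    def test_single_day_worked_example(self):
        # abundance weights (2/3, 1/3), errors (10%, 20%)
        s = mape_objective([[100.0, 50.0]], [[90.0, 60.0]])
        assert s == pytest.approx(2 / 3 * 0.10 + 1 / 3 * 0.20)
        assert s == pytest.approx(0.13333333333333333)

    def test_invariant_to_weight_rescaling(self):
        obs = np.array([[100.0, 50.0], [200.0, 80.0]])
        pred = obs * np.array([[1.1], [0.9]])
        s1 = mape_objective(obs, pred, [0.5, 1.0])
        s2 = mape_objective(obs, pred, [1.0, 2.0])
        assert s1 == pytest.approx(s2)

    def test_invariant_to_measurement_units(self):
        obs = np.array([[100.0, 50.0], [200.0, 80.0]])
        pred = np.array([[90.0, 60.0], [150.0, 100.0]])
        assert mape_objective(obs, pred) == pytest.approx(
            mape_objective(1e3 * obs, 1e3 * pred)
        )

    def test_any_positive_nondecreasing_weighting_keeps_perfect_fit_zero(self):
        obs = np.array([[10.0, 1.0]] * 4)
        for w in ([1, 1, 1, 1], [0.5, 0.5, 1, 1], [0.1, 0.2, 0.8, 3.0]):
            assert mape_objective(obs, obs, w) == 0


class TestMonocultureFits:
    def test_recovers_logistic_parameters(self, tiny_dataset):
        truth, design, data = tiny_dataset
        mono = fit_monocultures(data, design)
        for c in (0.0, 250.0):
            t = truth.levels[c]
            assert np.allclose(mono.mu[c], t.mu, rtol=1e-3)
            assert np.allclose(mono.K[c], t.K, rtol=1e-3)

    def test_missing_monoculture_errors(self, tiny_dataset):
        _, design, data = tiny_dataset
        sp = design.species_pool[0]
        with pytest.raises(ValueError, match="monoculture"):
            fit_monocultures(data[data["species"] != sp], design)


@pytest.fixture(scope="module")
def tiny_model(request):
    tiny = request.getfixturevalue("tiny_dataset")
    truth, design, data = tiny
    model = CommunityGLVModel(data, design, scenario="S1")
    return truth, model


class TestPenalizedObjective:
    def test_benign_parameters_equal_plain_objective(self, tiny_model):
        truth, model = tiny_model
        theta = model.spec.pack(truth)
        assert model.penalized_objective(theta, theta) == pytest.approx(
            model.objective(truth)
        )

    def _penalized_data(self):
        """Dataset whose observations sit far below any in-bounds prediction,
        forcing the raw MAPE above the 100% cap."""
        from befstress.synthetic import SyntheticConfig, gen_dataset, gen_ground_truth

        cfg = SyntheticConfig(n_species=2, seed=7, generating_scenario="S1")
        truth, design = gen_ground_truth(cfg, assemblage_counts={1: 2, 2: 1})
        data = gen_dataset(truth, design, noise_cv=0.0, seed=7)
        data = data.copy()
        data["biovolume"] *= 1e-4  # observations 10^4 below the model's range
        return data, design

    def test_penalty_base_exact_at_initial_point(self):
        data, design = self._penalized_data()
        model = CommunityGLVModel(data, design, scenario="S1")
        theta0 = (model.spec.lower + model.spec.upper) / 2
        val = model.penalized_objective(theta0, theta0)
        assert val == pytest.approx(model.config.penalty_base)

    def test_penalty_monotone_in_distance_from_start(self):
        data, design = self._penalized_data()
        model = CommunityGLVModel(data, design, scenario="S1")
        lo, hi = model.spec.lower, model.spec.upper
        theta0 = (lo + hi) / 2
        near = theta0 + 0.05 * (hi - lo)
        far = theta0 + 0.2 * (hi - lo)
        v0 = model.penalized_objective(theta0, theta0)
        v1 = model.penalized_objective(near, theta0)
        v2 = model.penalized_objective(far, theta0)
        assert v0 < v1 < v2

    def test_non_finite_vector_rejected(self, tiny_model):
        truth, model = tiny_model
        theta = model.spec.pack(truth)
        theta[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            model.penalized_objective(theta, theta)


class TestFitting:
    def test_fit_deterministic_per_seed(self, tiny_dataset):
        _, design, data = tiny_dataset
        fits = [
            CommunityGLVModel(data, design, scenario="S1").fit(
                n_restarts=2, maxfun=600, seed=5
            )
            for _ in range(2)
        ]
        assert fits[0].restart_table.equals(fits[1].restart_table)
        assert np.array_equal(fits[0].restart_params, fits[1].restart_params)

    def test_percentile_envelope_ordered_and_contains_best(self, tiny_dataset):
        _, design, data = tiny_dataset
        fit = CommunityGLVModel(data, design, scenario="S1").fit(
            n_restarts=3, maxfun=800, seed=2
        )
        lo, hi = fit.percentiles()
        assert np.all(lo <= hi)
        best = fit.best_theta
        assert np.all(best >= lo - 1e-9) and np.all(best <= hi + 1e-9)

    def test_summary_mentions_scenario_and_objective(self, tiny_dataset):
        _, design, data = tiny_dataset
        fit = CommunityGLVModel(data, design, scenario="S1").fit(
            n_restarts=2, maxfun=400, seed=2
        )
        text = fit.summary()
        assert "S1" in text and "objective" in text

    def test_model_mismatch_ordering_s4_data(self, small_noisy):
        """On data generated with interactions, fitting the interaction
        scenario at equal budget beats the no-interaction scenario."""
        truth, design, data = small_noisy
        mono = fit_monocultures(data, design)
        fit1 = CommunityGLVModel(
            data, design, scenario="S1", monoculture_estimates=mono
        ).fit(n_restarts=2, maxfun=3000, seed=4)
        model4 = CommunityGLVModel(
            data, design, scenario="S4", monoculture_estimates=mono
        )
        fit4 = model4.fit(n_restarts=2, maxfun=3000, seed=4,
                          initial=model4.spec.pack(truth))
        assert fit4.best_objective < fit1.best_objective


class TestObjectiveConfig:
    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveConfig(day_weights={7: 0.0, 28: 1.0})

    def test_logistic_helper_limits(self):
        assert logistic(0.0, 1e5, 0.5, 1e7) == pytest.approx(1e5)
        assert logistic(1e4, 1e5, 0.5, 1e7) == pytest.approx(1e7)
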