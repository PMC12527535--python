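import numpy as np
import pandas as pd
import pytest

from causalmeta import (
    AnalysisSpec,
    ExternalCovariates,
    MultiSourceDataset,
    clip_probabilities,
    fit_nuisances,
    super_learn,
)
from causalmeta.nuisance import (
    fit_external_model,
    fit_outcome_model,
    fit_source_model,
    fit_treatment_model,
)


class TestSuperLearn:
    def test_single_learner_gets_weight_one(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        fit = super_learn(Z, y, "continuous", ["mean"], seed=0)
        np.testing.assert_array_equal(fit.weights, [1.0])

    def test_constant_labels_predict_the_constant(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(60, 3))
        y = np.full(60, 5.0)
        fit = super_learn(Z, y, "continuous", ["glm", "mean"], V=5, seed=0)
        np.testing.assert_allclose(fit.predict(Z), 5.0, atol=1e-6)

    def test_linear_signal_dominates_intercept_learner(self):
        """With a strong linear signal and tiny noise, direct CV-risk
        computation shows linear regression dominates the intercept-only
        learner, so the stack puts nearly all weight on it."""
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(500, 2))
        y = 1.0 + 2.0 * Z[:, 0] - Z[:, 1] + 0.1 * rng.normal(size=500)
        fit = super_learn(Z, y, "continuous", ["glm", "mean"], V=10, seed=3)
        # independent oracle: CV risks must separate by orders of magnitude
        assert fit.cv_risks[fit.learner_names.index("mean")] > \
            50 * fit.cv_risks[fit.learner_names.index("glm")]
        assert fit.weights[fit.learner_names.index("glm")] >= 0.9

    def test_stack_cv_risk_never_above_best_single_learner(self):
        rng = np.random.default_rng(3)
        for family, make_y in (
            ("continuous", lambda z: z[:, 0] + rng.normal(size=len(z))),
            ("binary", lambda z: (rng.uniform(size=len(z)) <
                                  1 / (1 + np.exp(-z[:, 0]))).astype(float)),
        ):
            Z = rng.normal(size=(300, 3))
            y = make_y(Z)
            fit = super_learn(Z, y, family, ["glm", "mean", "ridge"], V=5, seed=1)
            assert fit.cv_risk_stack <= fit.cv_risks.min() + 1e-8

    def test_select_mode_puts_weight_one_on_cv_best(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(200, 2))
        y = 3.0 * Z[:, 0] + rng.normal(size=200)
        fit = super_learn(Z, y, "continuous", ["glm", "mean"], V=5,
                          mode="select", seed=0)
        assert sorted(fit.weights) == [0.0, 1.0]
        assert fit.weights[np.argmin(fit.cv_risks)] == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(150, 2))
        y = Z[:, 0] + rng.normal(size=150)
        f1 = super_learn(Z, y, "continuous", ["glm", "ridge"], V=5, seed=42)
        f2 = super_learn(Z, y, "continuous", ["glm", "ridge"], V=5, seed=42)
        np.testing.assert_array_equal(f1.weights, f2.weights)
        np.testing.assert_array_equal(f1.predict(Z), f2.predict(Z))

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            super_learn(np.zeros((10, 1)), np.zeros(10), "continuous", [])


class TestOutcomeModel:
    def test_constant_outcome_recovered_in_both_arms(self, tiny_data):
        data = MultiSourceDataset(Y=np.full(tiny_data.n, 5.0), S=tiny_data.S,
                                  A=tiny_data.A, X=tiny_data.X, EM=tiny_data.EM)
        fits = fit_nuisances(data, None, AnalysisSpec())
        np.testing.assert_allclose(fits.g0, 5.0, atol=1e-8)
        np.testing.assert_allclose(fits.g1, 5.0, atol=1e-8)

    def test_linear_treatment_effect_recovered(self):
        """Y = 1 + 2A + X1 + noise: the fitted arm difference averages 2."""
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(size=n)
        a = rng.integers(0, 2, size=n)
        y = 1 + 2 * a + x + 0.5 * rng.normal(size=n)
        data = MultiSourceDataset(Y=y, S=np.repeat("s", n), A=a,
                                  X=pd.DataFrame({"x": x}))
        fits = fit_nuisances(data, None, AnalysisSpec())
        assert abs(np.mean(fits.g1 - fits.g0) - 2.0) < 0.1

    def test_arm_missing_from_training_rows_is_an_error(self, tiny_data):
        from causalmeta.data_model import encode_design
        Z, _ = encode_design(tiny_data.X, tiny_data.EM)
        only_treated = np.flatnonzero(tiny_data.A.to_numpy() == 1)
        with pytest.raises(ValueError, match="arm"):
            fit_outcome_model(tiny_data, AnalysisSpec(), Z, only_treated)


class TestSourceModel:
    def test_no_signal_recovers_marginal_shares(self):
        rng = np.random.default_rng(7)
        n = 5000
        s = np.where(rng.uniform(size=n) < 0.7, "s1", "s2")
        data = MultiSourceDataset(
            Y=rng.normal(size=n), S=s, A=rng.integers(0, 2, size=n),
            X=pd.DataFrame({"x": rng.normal(size=n)}))
        fits = fit_nuisances(data, None, AnalysisSpec())
        share = (s == "s1").mean()
        assert abs(fits.eta[:, 0].mean() - share) < 0.03

    def test_single_source_eta_is_ones(self):
        rng = np.random.default_rng(8)
        n = 60
        data = MultiSourceDataset(
            Y=rng.normal(size=n), S=np.repeat("only", n),
            A=np.tile([0, 1], 30), X=pd.DataFrame({"x": rng.normal(size=n)}))
        fits = fit_nuisances(data, None, AnalysisSpec(eps=0.001))
        np.testing.assert_allclose(fits.eta, 0.999)  # ones, then clipped

    def test_rows_sum_to_one_before_clipping(self, small_study):
        data, _, _ = small_study
        from causalmeta.data_model import encode_design
        Z, _ = encode_design(data.X, data.EM)
        model = fit_source_model(data, AnalysisSpec(), Z)
        eta = model.predict(Z)
        np.testing.assert_allclose(eta.sum(axis=1), 1.0, atol=1e-8)

    def test_absent_source_in_training_rows_is_an_error(self, tiny_data):
        from causalmeta.data_model import encode_design
        Z, _ = encode_design(tiny_data.X, tiny_data.EM)
        rows = np.flatnonzero(tiny_data.S.to_numpy() != "C")
        with pytest.raises(ValueError, match="'C'"):
            fit_source_model(tiny_data, AnalysisSpec(), Z, rows)

    @pytest.mark.parametrize("source_model", ["multinomial_penalized", "nnet"])
    def test_alternative_source_learners_produce_valid_rows(
            self, small_study, source_model):
        data, _, _ = small_study
        from causalmeta.data_model import encode_design
        Z, _ = encode_design(data.X, data.EM)
        model = fit_source_model(
            data, AnalysisSpec(source_model=source_model), Z)
        eta = model.predict(Z)
        assert eta.shape == (data.n, 3)
        np.testing.assert_allclose(eta.sum(axis=1), 1.0, atol=1e-6)


class TestTreatmentModel:
    def test_randomized_half_half_recovered(self):
        rng = np.random.default_rng(9)
        n = 3000
        data = MultiSourceDataset(
            Y=rng.normal(size=n),
            S=np.repeat(["s1", "s2"], n // 2),
            A=rng.integers(0, 2, size=n),
            X=pd.DataFrame({"x": rng.normal(size=n)}))
        fits = fit_nuisances(data, None, AnalysisSpec())
        assert abs(fits.e1.mean() - 0.5) < 0.03

    def test_joint_and_separate_agree_when_source_is_irrelevant(self):
        rng = np.random.default_rng(10)
        n = 5000
        x = rng.normal(size=n)
        s = np.where(rng.uniform(size=n) < 0.5, "s1", "s2")
        p = 1 / (1 + np.exp(-(0.5 * x)))
        a = (rng.uniform(size=n) < p).astype(int)
        data = MultiSourceDataset(Y=rng.normal(size=n), S=s, A=a,
                                  X=pd.DataFrame({"x": x}))
        e_joint = fit_nuisances(
            data, None, AnalysisSpec(treatment_model_type="joint")).e1
        e_sep = fit_nuisances(
            data, None, AnalysisSpec(treatment_model_type="separate")).e1
        assert np.mean(np.abs(e_joint - e_sep)) < 0.05

    def test_single_arm_source_is_an_error_under_separate(self):
        rng = np.random.default_rng(11)
        n = 40
        a = np.concatenate([np.ones(20, dtype=int), np.tile([0, 1], 10)])
        data = MultiSourceDataset(
            Y=rng.normal(size=n), S=np.repeat(["s1", "s2"], 20), A=a,
            X=pd.DataFrame({"x": rng.normal(size=n)}))
        with pytest.raises(ValueError, match="'s1'"):
            fit_nuisances(data, None,
                          AnalysisSpec(treatment_model_type="separate"))


class TestExternalModel:
    def test_identical_populations_give_half(self):
        rng = np.random.default_rng(12)
        n = 2500
        x = rng.normal(size=n)
        data = MultiSourceDataset(
            Y=rng.normal(size=n), S=np.repeat("s", n),
            A=rng.integers(0, 2, size=n), X=pd.DataFrame({"x": x}))
        external = ExternalCovariates(
            X=pd.DataFrame({"x": rng.normal(size=n)}))
        fits = fit_nuisances(data, external, AnalysisSpec(target="external"))
        assert abs(fits.q.mean() - 0.5) < 0.03

    def test_duplicated_rows_give_sample_fraction(self):
        rng = np.random.default_rng(13)
        n = 600
        x = rng.normal(size=n)
        data = MultiSourceDataset(
            Y=rng.normal(size=n), S=np.repeat("s", n),
            A=rng.integers(0, 2, size=n), X=pd.DataFrame({"x": x}))
        external = ExternalCovariates(X=pd.DataFrame({"x": x[:200]}))
        fits = fit_nuisances(data, external, AnalysisSpec(target="external"))
        assert abs(fits.q.mean() - 200 / 800) < 0.03

    def test_probabilities_clipped_into_bounds(self, small_study):
        data, external, _ = small_study
        fits = fit_nuisances(data, external,
                             AnalysisSpec(target="external", eps=0.05))
        for arr in (fits.q, fits.e1, fits.eta):
            assert arr.min() >= 0.05 - 1e-12
            assert arr.max() <= 0.95 + 1e-12


class TestClip:
    @pytest.mark.parametrize("p, eps, expect, count", [
        ([0.0], 0.01, [0.01], 1),
        ([0.5], 0.01, [0.5], 0),
        ([0.0, 0.5, 1.0], 0.01, [0.01, 0.5, 0.99], 2),
    ])
    def test_clip_examples(self, p, eps, expect, count):
        clipped, n = clip_probabilities(np.array(p), eps)
        np.testing.assert_allclose(clipped, expect)
        assert n == count

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            clip_probabilities(np.array([0.5]), 0.6)
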