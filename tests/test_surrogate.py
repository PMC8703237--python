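"""Surrogate engine: AUC, prediction, penalty path, CV/LOBOV evaluation."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metabosurr as ms
from metabosurr.surrogate import (SurrogateModel, fit_enet_logistic,
                                  lambda_grid, _fit_path)
from oracles import brute_force_auc


class TestAuc:
    def test_worked_example(self):
        assert ms.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert ms.auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert ms.auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ms.auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5, allow_nan=False),
                              st.booleans()),
                    min_size=4, max_size=40))
    def test_matches_brute_force_pairwise_oracle(self, pairs):
        scores = [round(s, 1) for s, _ in pairs]  # coarse grid forces ties
        labels = [int(l) for _, l in pairs]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert ms.auc(scores, labels) == \
            pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


class TestPredict:
    def _model(self, coef, intercept=0.0, names=None):
        coef = np.asarray(coef, dtype=float)
        return SurrogateModel(name="m", intercept=intercept, coef=coef,
                              marker_names=names or
                              [f"x{i}" for i in range(len(coef))],
                              alpha=0.5, lambda_=0.1)

    def test_null_model_predicts_half(self):
        m = self._model([0.0, 0.0])
        np.testing.assert_allclose(
            ms.predict_surrogate(m, np.random.default_rng(0)
                                 .normal(size=(5, 2))), 0.5)

    def test_single_coefficient_log3(self):
        m = self._model([1.0])
        assert ms.predict_surrogate(m, [[np.log(3)]])[0] \
            == pytest.approx(0.75)

    def test_monotone_in_linear_predictor(self):
        m = self._model([2.0, -1.0])
        X = np.random.default_rng(1).normal(size=(50, 2))
        eta = X @ m.coef
        order = np.argsort(eta)
        p = ms.predict_surrogate(m, X)
        assert (np.diff(p[order]) > 0).all()

    def test_dataframe_column_alignment(self):
        m = self._model([1.0, 0.0], names=["a", "b"])
        df = pd.DataFrame({"b": [0.0], "a": [np.log(3)]})
        assert ms.predict_surrogate(m, df)[0] == pytest.approx(0.75)

    def test_marker_mismatch_names_offenders(self):
        m = self._model([1.0, 1.0], names=["a", "b"])
        with pytest.raises(KeyError, match="b"):
            ms.predict_surrogate(m, pd.DataFrame({"a": [1.0], "c": [1.0]}))

    def test_scaling_applied_to_raw_input(self):
        m = self._model([1.0], names=["a"])
        m.scaling_mean = np.array([10.0])
        m.scaling_sd = np.array([2.0])
        assert ms.predict_surrogate(m, [[10.0]])[0] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((300, 12))
    eta = X[:, 0] - 0.8 * X[:, 1] + 0.5 * X[:, 2] - 1.0
    y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


class TestPenaltyPath:
    def test_lambda_max_zeroes_all_coefficients(self, xy):
        X, y = xy
        lams = lambda_grid(X, y, alpha=0.5, n_lambda=5, decades=2)
        _, coef = fit_enet_logistic(X, y, 0.5, lams[0] * 1.05)
        assert np.count_nonzero(coef) == 0

    def test_huge_penalty_shrinks_to_prevalence(self, xy):
        X, y = xy
        icept, coef = fit_enet_logistic(X, y, 0.5, lam=1e4)
        assert np.all(coef == 0)
        prev = y.mean()
        assert icept == pytest.approx(np.log(prev / (1 - prev)), abs=1e-2)

    def test_sparsity_monotone_along_grid(self, xy):
        X, y = xy
        lams = lambda_grid(X, y, alpha=0.5, n_lambda=25, decades=3)
        _, coefs = _fit_path(X, y, lams, 0.5, tol=1e-5, max_iter=1000)
        nnz = (np.abs(coefs) > 1e-10).sum(axis=1)
        assert (np.diff(nnz) >= 0).all()  # grid descends, support grows

    def test_training_rejects_single_class(self, fast_tc):
        X = np.random.default_rng(3).normal(size=(20, 3))
        with pytest.raises(ValueError, match="single class"):
            ms.train_surrogate(X, np.ones(20), fast_tc)


class TestTrainingAndEvaluation:
    def test_recovers_planted_signal(self, trained_model):
        kept, X, y, model = trained_model
        p = ms.predict_surrogate(model, X)
        assert ms.auc(p, y) > 0.9
        assert 0 < model.n_selected <= len(model.coef)

    def test_projection_consistency_bit_for_bit(self, trained_model):
        _, X, y, model = trained_model
        p1 = ms.predict_surrogate(model, X)
        p2 = ms.predict_surrogate(model, X)
        np.testing.assert_array_equal(p1, p2)

    def test_model_untouched_by_test_labels(self, trained_model, fast_tc):
        """No-leakage contract: the fitted model depends only on training
        data, never on held-out labels."""
        _, X, y, _ = trained_model
        tr = np.arange(0, len(y), 2)
        m1 = ms.train_surrogate(X[tr], y[tr], fast_tc)
        # perturb everything outside the training split, retrain
        y2 = y.copy()
        y2[1::2] = 1 - y2[1::2]
        m2 = ms.train_surrogate(X[tr], y2[tr], fast_tc)
        h1 = hashlib.sha256(m1.coef.tobytes()).hexdigest()
        h2 = hashlib.sha256(m2.coef.tobytes()).hexdigest()
        assert h1 == h2 and m1.intercept == m2.intercept

    def test_cv_report_deterministic_under_seed(self, qc_small, fast_tc):
        kept, _ = qc_small
        X = kept.metabolite_matrix()[:400]
        y = kept.df["planted_auc95"].to_numpy(int)[:400]
        r1 = ms.evaluate_cv(X, y, fast_tc, "p")
        r2 = ms.evaluate_cv(X, y, fast_tc, "p")
        assert r1.entries == r2.entries and r1.mean_auc == r2.mean_auc

    def test_lobov_weighted_mean_and_skip(self, qc_small, fast_tc):
        kept, _ = qc_small
        X = kept.metabolite_matrix()
        y = kept.df["planted_auc95"].to_numpy(int)
        cohorts = kept.df["cohort"].to_numpy().copy()
        # make one cohort single-class so it must be skipped
        first = cohorts == cohorts[0]
        y = y.copy()
        y[first] = 0
        rep = ms.evaluate_lobov(X, y, cohorts, fast_tc, "p")
        assert rep.skipped_cohorts == [str(cohorts[0])]
        w = np.array([e["n_test"] for e in rep.entries], dtype=float)
        a = np.array([e["auc"] for e in rep.entries])
        assert rep.weighted_mean_auc == pytest.approx((w * a).sum() / w.sum())
        assert min(a) <= rep.weighted_mean_auc <= max(a)

    def test_lobov_needs_two_cohorts(self, fast_tc):
        X = np.random.default_rng(4).normal(size=(40, 3))
        y = np.tile([0, 1], 20)
        with pytest.raises(ValueError, match="two cohorts"):
            ms.evaluate_lobov(X, y, ["c"] * 40, fast_tc)

    def test_model_json_roundtrip(self, trained_model, tmp_path):
        _, X, _, model = trained_model
        model.to_json(tmp_path / "m.json")
        back = SurrogateModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.coef, model.coef)
        assert back.lambda_ == model.lambda_
        np.testing.assert_array_equal(ms.predict_surrogate(back, X[:10]),
                                      ms.predict_surrogate(model, X[:10]))


class TestRelativeImportance:
    def _model(self, name, coef):
        return SurrogateModel(name=name, intercept=0.0,
                              coef=np.asarray(coef, float),
                              marker_names=["a", "b", "c"], alpha=0.5,
                              lambda_=0.1)

    def test_worked_example(self):
        imp = ms.relative_importance([self._model("m", [2.0, -1.0, 1.0])])
        np.testing.assert_allclose(imp.loc["m"], [0.5, -0.25, 0.25])
        assert np.abs(imp.loc["m"]).sum() == pytest.approx(1.0)

    def test_single_coefficient(self):
        imp = ms.relative_importance([self._model("m", [0, 3.0, 0])])
        np.testing.assert_allclose(imp.loc["m"], [0, 1.0, 0])

    def test_positive_scale_invariance(self):
        a = ms.relative_importance([self._model("m", [2.0, -1.0, 1.0])])
        b = ms.relative_importance([self._model("m", [6.0, -3.0, 3.0])])
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            ms.relative_importance([self._model("m", [0.0, 0.0, 0.0])])


class TestCorrelationsAndSeparation:
    def test_duplicate_surrogate_correlation_one(self):
        rng = np.random.default_rng(5)
        s = rng.random(100)
        surro = pd.DataFrame({"a": s, "b": s, "c": rng.random(100)})
        corr, _ = ms.surrogate_correlations_and_separation(surro)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_separation_means_and_sign(self):
        rng = np.random.default_rng(6)
        lab = rng.integers(0, 2, 400).astype(float)
        s = lab * 0.4 + rng.normal(0, 0.1, 400)
        lab[:40] = np.nan
        surro = pd.DataFrame({"a": s, "b": rng.random(400)})
        labels = pd.DataFrame({"a": pd.array(lab, dtype="Float64")})
        _, sep = ms.surrogate_correlations_and_separation(surro, labels)
        assert sep.loc["a", "mean_true"] > sep.loc["a", "mean_false"]
        assert sep.loc["a", "p"] < 1e-6
        assert np.isfinite(sep.loc["a", "mean_missing"])
        assert np.isnan(sep.loc["b", "t"])

    def test_constant_surrogate_rejected(self):
        surro = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            ms.surrogate_correlations_and_separation(surro)
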