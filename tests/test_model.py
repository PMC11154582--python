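"""OLS fitting, Table-3 statistics, VIF, PRESS and candidate ranking."""

import numpy as np
import pandas as pd
import pytest

from bbbqsar.model import (
    CollinearityError,
    LogBBModel,
    anova_f,
    compute_loo_press,
    compute_vif,
    enumerate_candidates,
    fit_ols,
)
from bbbqsar.simulate import GeneratorConfig, generate_panel


class TestFitOls:
    def test_exact_linear_response(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = fit_ols(2 * x + 1, x[:, None], ["x"])
        assert res.params["const"] == pytest.approx(1.0, abs=1e-12)
        assert res.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.sse == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self, toy_regression):
        X = toy_regression[["x1", "x2"]].to_numpy()
        y = toy_regression["y"].to_numpy()
        design = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        res = fit_ols(y, X, ["x1", "x2"])
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-12)

    def test_residuals_orthogonal_to_design(self, eq4_results):
        res = eq4_results
        assert abs(res.residuals.sum()) < 1e-10
        assert np.abs(res.model.design.T @ res.residuals).max() < 1e-8

    def test_sum_of_squares_decomposition(self, eq4_results):
        res = eq4_results
        assert res.ss_total == pytest.approx(res.sse + res.ssr, rel=1e-8)
        assert res.mse * (res.n - res.p - 1) == pytest.approx(res.sse, rel=1e-12)
        assert res.f_stat * res.p * res.mse == pytest.approx(res.ssr, rel=1e-10)

    def test_r2_adj_identity(self, eq4_results):
        res = eq4_results
        expected = 1 - (1 - res.r2) * (res.n - 1) / (res.n - res.p - 1)
        assert res.r2_adj == pytest.approx(expected, abs=1e-12)

    def test_collinear_design_rejected_with_names(self, fixture_frame):
        frame = fixture_frame.copy()
        frame["mw_copy"] = frame["mw"]
        with pytest.raises(CollinearityError, match="mw"):
            LogBBModel.from_dataframe(frame, ("log_kw_iam", "mw", "mw_copy"))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            fit_ols([1.0, 2.0], np.array([[1.0], [2.0]]))

    def test_missing_predictor_column_named(self, fixture_frame):
        with pytest.raises(KeyError, match="bogus"):
            LogBBModel.from_dataframe(fixture_frame, ("log_kw_iam", "bogus"))


class TestLooPress:
    def test_hat_shortcut_equals_explicit_refits(self, toy_regression):
        res = fit_ols(toy_regression["y"], toy_regression[["x1", "x2"]])
        press_hat, _ = compute_loo_press(res)
        # brute-force oracle: n refits each leaving one point out
        X = res.model.design
        y = res.model.endog
        press_refit = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            press_refit += (y[i] - X[i] @ beta) ** 2
        assert press_hat == pytest.approx(press_refit, abs=1e-10)

    def test_perfect_fit_gives_zero_press(self):
        x = np.linspace(0, 1, 8)
        res = fit_ols(3 * x - 2, x[:, None])
        press, r2_pred = compute_loo_press(res)
        assert press == pytest.approx(0.0, abs=1e-18)
        assert r2_pred == pytest.approx(1.0, abs=1e-12)

    def test_press_never_below_sse(self, eq4_results):
        assert eq4_results.press >= eq4_results.sse
        assert eq4_results.r2_pred <= eq4_results.r2

    def test_unit_leverage_rejected(self):
        # two isolated x-levels: the lone extreme point has h = 1 territory
        x = np.array([0.0, 0.0, 0.0, 1.0])
        res = fit_ols(np.array([0.1, -0.1, 0.0, 5.0]), x[:, None])
        assert res.hat_diagonal.max() > 1 - 1e-12
        with pytest.raises(ZeroDivisionError, match="leverage"):
            compute_loo_press(res)


class TestVif:
    def test_orthogonal_predictors_give_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]}, dtype=float)
        assert np.allclose(compute_vif(X), 1.0, atol=1e-12)

    def test_matches_auxiliary_regression_oracle(self, fixture_frame):
        X = fixture_frame[["log_kw_iam", "mw", "hb_total"]]
        vif = compute_vif(X)
        for col in X.columns:
            others = X.drop(columns=col)
            aux = fit_ols(X[col], others)
            assert vif[col] == pytest.approx(1 / (1 - aux.r2), rel=1e-10)

    def test_fixture_max_vif_below_published_bound(self, eq4_results):
        assert eq4_results.vif.max() < 2.8

    def test_perfect_collinearity_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        X["b"] = 2 * X["a"]
        with pytest.raises(CollinearityError, match="infinite VIF"):
            compute_vif(X)


class TestAnovaF:
    def test_internal_consistency(self, eq4_results):
        f, p_f = anova_f(eq4_results)
        assert f == pytest.approx(eq4_results.f_stat, rel=1e-10)
        assert p_f == pytest.approx(eq4_results.p_f, rel=1e-6, abs=1e-30)

    def test_type_one_error_rate_under_null(self):
        # pure-noise response: p < 0.05 should occur ~5% of the time
        rng = np.random.default_rng(11)
        n, hits, reps = 40, 0, 1000
        X = rng.standard_normal((n, 2))
        for _ in range(reps):
            y = rng.standard_normal(n)
            _, p_f = anova_f(fit_ols(y, X))
            hits += p_f < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_perfect_fit_gives_vanishing_p(self):
        x = np.linspace(0, 1, 6)
        f, p_f = anova_f(fit_ols(2 * x, x[:, None]))
        assert np.isinf(f) or f > 1e12
        assert p_f == 0.0


class TestEnumerateCandidates:
    def test_ranking_follows_adjusted_r2_with_parsimony(self, fixture_frame):
        # On this panel the alpha-based size block has the best adjusted R2;
        # among the MW-size candidates the published block leads.
        candidates = enumerate_candidates(fixture_frame)
        assert set(candidates[0].predictors) == {"log_kw_iam", "alpha", "hb_total"}
        mw_blocks = [c for c in candidates if "mw" in c.predictors]
        assert set(mw_blocks[0].predictors) == {"log_kw_iam", "mw", "hb_total"}

    def test_nrb_does_not_overcome_parsimony(self, fixture_frame):
        candidates = enumerate_candidates(fixture_frame)
        by_block = {frozenset(c.predictors): c for c in candidates}
        small = by_block[frozenset({"log_kw_iam", "mw", "hb_total"})]
        large = by_block[frozenset({"log_kw_iam", "mw", "hb_total", "nrb"})]
        assert large.r2_adj - small.r2_adj <= 0.005
        assert small.rank < large.rank

    def test_eight_blocks_always_include_lipophilicity(self, fixture_frame):
        candidates = enumerate_candidates(fixture_frame)
        assert len(candidates) == 8
        assert all("log_kw_iam" in c.predictors for c in candidates)
        for c in candidates:
            assert len({"mw", "alpha"} & set(c.predictors)) == 1
            assert len({"tpsa", "hb_total"} & set(c.predictors)) == 1

    def test_generating_block_recovered_on_synthetic_data(self):
        hits = 0
        reps = 60
        for seed in range(reps):
            panel = generate_panel(GeneratorConfig(seed=seed)).frame
            top = enumerate_candidates(panel)[0]
            hits += set(top.predictors) == {"log_kw_iam", "mw", "hb_total"}
        assert hits / reps >= 0.95


class TestResultsApi:
    def test_coefficient_table_regime(self, eq4_results):
        # standard errors of the published equation at printed precision
        se = eq4_results.se.round(4)
        assert se["const"] == pytest.approx(0.0967)
        assert se["log_kw_iam"] == pytest.approx(0.0194)
        assert se["mw"] == pytest.approx(0.0004)
        assert se["hb_total"] == pytest.approx(0.0066)

    def test_hat_diagonal_bounds_and_trace(self, eq4_results):
        h = eq4_results.hat_diagonal
        assert h.sum() == pytest.approx(eq4_results.p + 1, abs=1e-10)
        assert (h >= 1 / eq4_results.n - 1e-12).all()
        assert (h <= 1 + 1e-12).all()

    def test_to_dict_round_trips_through_json(self, eq4_results):
        import json

        payload = json.loads(eq4_results.to_json())
        assert payload["n"] == 126 and payload["p"] == 3
        assert payload["r2"] == pytest.approx(eq4_results.r2)

    def test_summary_mentions_key_statistics(self, eq4_results):
        text = eq4_results.summary()
        assert "R2=0.9342" in text
        assert "PRESS=1.76752" in text

    def test_predict_is_affine_in_descriptors(self, eq4_results):
        rng = np.random.default_rng(9)
        x1, x2 = rng.random((2, 3)) * [3.0, 400.0, 10.0]
        for a in (0.0, 0.3, 1.0):
            mix = a * x1 + (1 - a) * x2
            expected = (a * eq4_results.predict(x1[None])[0]
                        + (1 - a) * eq4_results.predict(x2[None])[0])
            assert eq4_results.predict(mix[None])[0] == pytest.approx(expected, rel=1e-10)
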