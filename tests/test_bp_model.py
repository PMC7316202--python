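"""Log-linear BP regression, feature selection, and agreement grading."""

import json

import numpy as np
import pandas as pd
import pytest

from pulsebp.bp_model import (
    LogLinearRegression,
    aami_check,
    bhs_grade,
    default_feature_sets,
    evaluate,
    fit_log_linear,
    predict,
    screen_features_r2,
    wrapper_select,
)


def _synthetic_table(n, rng, betas=(2.0, -1.5), beta0=4.8, noise=0.0):
    X = pd.DataFrame(
        {"x1": rng.uniform(0, 1, n), "x2": rng.uniform(0, 1, n)}
    )
    log_y = beta0 + betas[0] * X["x1"] + betas[1] * X["x2"]
    if noise:
        log_y = log_y + rng.normal(0, noise, n)
    return X, np.exp(log_y)


class TestFit:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        X, y = _synthetic_table(50, rng)
        model = fit_log_linear(X, y)
        assert model.intercept_ == pytest.approx(4.8, abs=1e-8)
        np.testing.assert_allclose(model.coef_, [2.0, -1.5], atol=1e-8)

    def test_constant_response_gives_zero_slopes(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x1": rng.uniform(0, 1, 30)})
        y = np.full(30, 120.0)
        model = fit_log_linear(X, y)
        assert model.coef_[0] == pytest.approx(0.0, abs=1e-10)
        assert model.intercept_ == pytest.approx(np.log(120.0))

    def test_larger_cohort_estimates_more_precisely(self):
        """Monte-Carlo consistency: coefficient RMSE shrinks with n."""
        errs = {50: [], 200: []}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            for n in errs:
                X, y = _synthetic_table(n, rng, noise=0.03)
                model = fit_log_linear(X, y)
                errs[n].append(np.sum((model.coef_ - [2.0, -1.5]) ** 2))
        rmse = {n: np.sqrt(np.mean(v)) for n, v in errs.items()}
        assert rmse[200] < rmse[50]

    def test_non_positive_y_rejected(self):
        X = pd.DataFrame({"x1": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="positive"):
            fit_log_linear(X, np.array([120.0, -3.0, 110.0]))

    def test_collinear_design_rejected_naming_columns(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 20)})
        X["b"] = 2.0 * X["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_log_linear(X, np.exp(4.8 + X["a"].to_numpy()))

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [0.1, 0.2], "b": [0.3, 0.4]})
        with pytest.raises(ValueError, match="rows"):
            fit_log_linear(X, np.array([120.0, 130.0]))

    def test_in_sample_roundtrip_mae_tiny(self):
        rng = np.random.default_rng(3)
        X, y = _synthetic_table(80, rng)
        model = fit_log_linear(X, y)
        mae = np.mean(np.abs(model.predict(X) - y))
        assert mae < 1e-6

    def test_sklearn_params_clone_contract(self):
        model = LogLinearRegression(target="dbp", features=["Trr"])
        params = model.get_params()
        assert params == {"target": "dbp", "features": ["Trr"]}
        other = LogLinearRegression(**params)
        assert other.get_params() == params


class TestPredict:
    def test_intercept_only_model(self):
        model = LogLinearRegression.from_dict(
            {"target": "sbp", "feature_names": [], "beta0": float(np.log(120.0)),
             "betas": []}
        )
        out = predict(model, pd.DataFrame(index=[0]))
        assert out == pytest.approx(120.0)

    def test_single_feature_linear_predictor(self):
        model = LogLinearRegression.from_dict(
            {"target": "sbp", "feature_names": ["T_RN2"], "beta0": 4.7875,
             "betas": [-0.8]}
        )
        out = predict(model, {"T_RN2": 0.25})
        assert out == pytest.approx(float(np.exp(4.7875 - 0.2)))
        assert out > 0

    def test_missing_feature_rejected_by_name(self):
        model = LogLinearRegression.from_dict(
            {"target": "sbp", "feature_names": ["T_RN2"], "beta0": 4.7,
             "betas": [-0.8]}
        )
        with pytest.raises(ValueError, match="T_RN2"):
            predict(model, {"Trr": 0.8})

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X, y = _synthetic_table(30, rng)
        model = fit_log_linear(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = LogLinearRegression.from_json(path)
        np.testing.assert_allclose(clone.predict(X), model.predict(X))


class TestEvaluate:
    def test_hand_computed_error_statistics(self):
        report = evaluate([120.0, 130.0], [118.0, 133.0])
        assert report.me == pytest.approx(-0.5)
        assert report.mae == pytest.approx(2.5)
        assert report.sd == pytest.approx(3.5355, abs=1e-4)

    def test_perfect_agreement(self):
        y = np.array([110.0, 120.0, 130.0, 140.0])
        report = evaluate(y, y)
        assert report.me == report.mae == report.sd == 0.0
        assert report.bhs["grade"] == "A"
        assert report.bhs["within5"] == 100.0
        assert report.aami_pass

    def test_constant_offset_fails_aami_on_mean_error(self):
        y = np.linspace(100, 140, 10)
        report = evaluate(y + 6.0, y)
        assert report.me == pytest.approx(6.0)
        assert report.mae == pytest.approx(6.0)
        assert report.sd == pytest.approx(0.0, abs=1e-12)
        assert not report.aami_pass

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(90, 180, 200)
        y = rng.uniform(90, 180, 200)
        report = evaluate(p, y)
        n = len(p)
        me = sum(p[i] - y[i] for i in range(n)) / n
        mae = sum(abs(p[i] - y[i]) for i in range(n)) / n
        sd = np.sqrt(sum(((p[i] - y[i]) - me) ** 2 for i in range(n)) / (n - 1))
        assert abs(report.me - me) < 1e-12
        assert abs(report.mae - mae) < 1e-12
        assert abs(report.sd - sd) < 1e-12

    def test_bhs_percentages_nondecreasing_and_monotone_in_offset(self):
        rng = np.random.default_rng(6)
        y = rng.uniform(100, 160, 100)
        prev_within = (100.0, 100.0, 100.0)
        for offset in (0.0, 4.0, 8.0, 12.0, 20.0):
            r = evaluate(y + offset, y)
            w = (r.bhs["within5"], r.bhs["within10"], r.bhs["within15"])
            assert w[0] <= w[1] <= w[2]
            assert all(a <= b for a, b in zip(w, prev_within))
            prev_within = w

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([120.0], [118.0, 119.0])


class TestGrades:
    @pytest.mark.parametrize(
        "w,expected",
        [
            ((60, 85, 95), "A"),
            ((59, 85, 95), "B"),
            ((50, 75, 90), "B"),
            ((40, 65, 85), "C"),
            ((30, 60, 80), "D"),
        ],
    )
    def test_bhs_grade_table(self, w, expected):
        assert bhs_grade(*w) == expected

    def test_aami_bounds(self):
        assert aami_check(5.0, 8.0)
        assert not aami_check(5.1, 8.0)
        assert not aami_check(0.0, 8.1)


class TestScreening:
    def test_perfect_predictor_kept(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 100)})
        y = np.exp(4.5 + 1.2 * X["a"])
        assert screen_features_r2(X, y) == ["a"]

    def test_independent_feature_dropped_under_null(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {"signal": rng.uniform(0, 1, 500), "noise": rng.uniform(0, 1, 500)}
        )
        y = np.exp(4.5 + 1.0 * X["signal"] + rng.normal(0, 0.05, 500))
        kept = screen_features_r2(X, y)
        assert "signal" in kept and "noise" not in kept

    def test_impossible_threshold_empties_selection(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 50)})
        y = np.exp(4.5 + X["a"])
        assert screen_features_r2(X, y, threshold=1.1) == []


class TestWrapperSelection:
    def _table(self, seed, n=120, noise=0.01):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {c: rng.uniform(0, 1, n) for c in ("a", "b", "c", "d")}
        )
        y = np.exp(4.6 + 1.5 * X["a"] - 1.0 * X["b"] + rng.normal(0, noise, n))
        return X, y

    def test_recovers_true_support_across_seeds(self):
        hits = 0
        for seed in range(50):
            X, y = self._table(seed)
            selected, _ = wrapper_select(X, y, ["a", "b", "c", "d"], seed=seed)
            if {"a", "b"} <= set(selected) and not {"c", "d"} & set(selected):
                hits += 1
        assert hits >= 45  # >= 90% of runs

    def test_single_candidate_kept_iff_it_beats_baseline(self):
        X, y = self._table(0)
        kept, _ = wrapper_select(X, y, ["a"], seed=0)
        assert kept == ["a"]
        rng = np.random.default_rng(11)
        X2 = pd.DataFrame({"junk": rng.uniform(0, 1, 120)})
        y2 = np.exp(np.log(120.0) + rng.normal(0, 0.02, 120))
        kept2, _ = wrapper_select(X2, y2, ["junk"], seed=0)
        assert kept2 == []

    def test_duplicated_feature_selected_once(self):
        X, y = self._table(1)
        X = X.assign(a2=X["a"])
        selected, _ = wrapper_select(X, y, ["a", "a2", "b"], seed=1)
        assert ("a" in selected) != ("a2" in selected) or "a2" not in selected
        assert selected.count("a") + selected.count("a2") == 1

    def test_random_mode_is_seed_deterministic(self):
        X, y = self._table(2)
        out1 = wrapper_select(X, y, ["a", "b", "c", "d"], seed=3, mode="random",
                              n_random=20)
        out2 = wrapper_select(X, y, ["a", "b", "c", "d"], seed=3, mode="random",
                              n_random=20)
        assert out1 == out2


class TestDefaultSets:
    def test_published_sizes_and_containment(self):
        sbp, dbp = default_feature_sets()
        assert len(sbp) == 9
        assert len(dbp) == 14
        assert set(sbp) < set(dbp)
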