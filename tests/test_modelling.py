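"""Endpoint binarization, selection pipeline, validation and stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from radpipe.modelling import (binarize, cross_validate, delong_ci,
                               fit_backward_aic, fit_pipeline, group_features,
                               horn_components, mann_whitney_auc,
                               prognostic_overlap, select_best, stratify_km,
                               univariable_screen, validate)
from radpipe.synthetic import simulate_feature_table


def outcome_table(times, events, outcome="efs"):
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(len(times))],
        f"{outcome}_months": times, f"{outcome}_event": events,
    })


class TestBinarize:
    def test_event_before_horizon_is_case(self):
        y = binarize(outcome_table([10.0], [1]), "efs", 12)
        assert y.tolist() == [1]

    def test_censored_before_horizon_is_excluded(self):
        y = binarize(outcome_table([8.0], [0]), "efs", 12)
        assert len(y) == 0

    def test_censored_after_horizon_is_control(self):
        y = binarize(outcome_table([30.0], [0]), "efs", 24)
        assert y.tolist() == [0]

    def test_censored_as_nonevent_option(self):
        y = binarize(outcome_table([8.0], [0]), "efs", 12, censored_as_nonevent=True)
        assert y.tolist() == [0]

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            binarize(outcome_table([-1.0], [1]), "efs", 12)


class TestAUC:
    def test_perfect_separation_is_one(self):
        x = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        assert mann_whitney_auc(x, y) == 1.0

    def test_printed_toy_set_matches_concordance_count(self):
        # 6-point set with one tie across classes
        x = np.array([0.1, 0.4, 0.4, 0.6, 0.8, 0.2])
        y = np.array([0, 0, 1, 1, 1, 0])
        pairs = [(a, b) for a in x[y == 1] for b in x[y == 0]]
        expected = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                            for a, b in pairs])
        assert mann_whitney_auc(x, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_pairs_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        x = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = np.zeros(n, int)
        y[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if y.all() or not y.any():
            y[0] = 1 - y[0]
        expected = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                            for a in x[y == 1] for b in x[y == 0]])
        assert mann_whitney_auc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_auc(np.ones(5), np.ones(5))


class TestHorn:
    def test_pure_noise_retains_at_most_one_component(self):
        rng = np.random.default_rng(55)
        X = rng.standard_normal((100, 20))
        assert horn_components(X, n_reps=300, seed=1) <= 1

    def test_three_planted_factors_are_recovered(self):
        rng = np.random.default_rng(7)
        f = rng.standard_normal((200, 3))
        blocks = [0.9 * f[:, k % 3] + 0.44 * rng.standard_normal(200)
                  for k in range(15)]
        noise = [rng.standard_normal(200) for _ in range(35)]
        X = np.column_stack(blocks + noise)
        assert horn_components(X, n_reps=300, seed=2) == 3

    def test_invalid_arguments_rejected(self):
        X = np.random.default_rng(0).random((20, 5))
        with pytest.raises(ValueError):
            horn_components(X, n_reps=0)
        with pytest.raises(ValueError):
            horn_components(X[:, :1])


class TestGrouping:
    def test_perfectly_correlated_features_share_a_group(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"f1": a, "f2": 2 * a + 1, "f3": rng.standard_normal(50)})
        g = group_features(X, 2)
        assert g["f1"] == g["f2"]

    def test_two_planted_blocks_are_recovered(self):
        rng = np.random.default_rng(3)
        u, v = rng.standard_normal((2, 120))
        X = pd.DataFrame({
            **{f"a{i}": 0.95 * u + 0.3 * rng.standard_normal(120) for i in range(4)},
            **{f"b{i}": 0.9 * v + 0.4 * rng.standard_normal(120) for i in range(3)},
        })
        g = group_features(X, 2)
        assert len({g[f"a{i}"] for i in range(4)}) == 1
        assert len({g[f"b{i}"] for i in range(3)}) == 1
        assert g["a0"] != g["b0"]

    def test_single_component_collapses_to_one_group(self):
        X = pd.DataFrame(np.random.default_rng(1).random((30, 5)))
        assert set(group_features(X, 1)) == {0}

    def test_zero_variance_feature_goes_to_sentinel_group(self):
        X = pd.DataFrame({"f1": np.arange(20.0), "f2": np.ones(20)})
        with pytest.warns(UserWarning, match="zero-variance"):
            g = group_features(X, 1)
        assert g["f2"] == -1


class TestScreen:
    def test_separating_feature_selected_with_auc_one(self):
        y = pd.Series([0] * 10 + [1] * 10)
        X = pd.DataFrame({"f": np.r_[np.zeros(10), np.ones(10)]})
        groups = pd.Series([0], index=["f"])
        cands, stats = univariable_screen(X, y, groups)
        assert cands == ["f"]
        assert stats.loc[0, "auc"] == 1.0

    def test_noise_feature_not_retained(self):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.integers(0, 2, 200))
        X = pd.DataFrame({"noise": rng.standard_normal(200)})
        groups = pd.Series([0], index=["noise"])
        cands, stats = univariable_screen(X, y, groups)
        assert cands == []
        assert abs(stats.loc[0, "auc"] - 0.5) < 0.1

    def test_single_class_labels_rejected(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        with pytest.raises(ValueError, match="single class"):
            univariable_screen(X, pd.Series(np.ones(10, int)),
                               pd.Series([0], index=["f"]))


class TestBackwardAIC:
    def test_pure_noise_candidate_is_dropped(self):
        rng = np.random.default_rng(21)
        n = 200
        signal = rng.standard_normal(n)
        y = pd.Series((rng.random(n) < special.expit(1.5 * signal)).astype(int))
        X = pd.DataFrame({"signal": signal, "noise": rng.standard_normal(n)})
        model = fit_backward_aic(X, y, ["signal", "noise"])
        assert model.features == ["signal"]

    def test_empty_candidates_yield_intercept_only_model(self):
        y = pd.Series([0, 1] * 10)
        X = pd.DataFrame({"f": np.arange(20.0)})
        model = fit_backward_aic(X, y, [])
        assert model.features == []
        probs = model.predict(X)
        assert probs.nunique() == 1
        assert mann_whitney_auc(probs.to_numpy(), y.to_numpy()) == 0.5

    def test_aic_matches_independent_loglik_summation(self):
        rng = np.random.default_rng(4)
        n = 150
        x = rng.standard_normal(n)
        y = pd.Series((rng.random(n) < special.expit(x)).astype(int))
        X = pd.DataFrame({"x": x})
        model = fit_backward_aic(X, y, ["x"])
        z = (x - x.mean()) / x.std()
        lp = model.intercept + model.coefficients[0] * z
        p = special.expit(lp)
        ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        k = len(model.features) + 1
        assert model.aic == pytest.approx(2 * k - 2 * ll, rel=1e-6)

    def test_final_aic_never_exceeds_start_aic(self):
        rng = np.random.default_rng(17)
        n = 120
        X = pd.DataFrame(rng.standard_normal((n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = pd.Series((rng.random(n) < special.expit(X["f0"])).astype(int))
        import statsmodels.api as sm
        Z = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        start = sm.Logit(y.to_numpy(), sm.add_constant(Z)).fit(disp=0)
        model = fit_backward_aic(X, y, list(X.columns))
        assert model.aic <= (2 * 6 - 2 * start.llf) + 1e-9


class TestCrossValidation:
    def test_same_seed_reproduces_folds_exactly(self):
        X, y, _ = simulate_feature_table(120, seed=2)
        a = cross_validate(X, y, k=4, seed=9, horn_reps=50)
        b = cross_validate(X, y, k=4, seed=9, horn_reps=50)
        assert a.fold_aucs == b.fold_aucs

    def test_permuted_labels_score_near_chance(self):
        X, y, _ = simulate_feature_table(200, seed=6)
        rng = np.random.default_rng(10)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = cross_validate(X, y_perm, k=5, seed=1, horn_reps=50)
        assert abs(res.mean_auc - 0.5) <= 0.10

    def test_designed_effect_recovered_in_cv(self):
        X, y, info = simulate_feature_table(300, seed=12)
        res = cross_validate(X, y, k=5, seed=3, horn_reps=100)
        assert abs(res.mean_auc - info["design_auc"]) <= 0.08

    def test_too_few_events_for_folds_rejected(self):
        X, y, _ = simulate_feature_table(40, seed=0)
        y[:] = 0
        y.iloc[:3] = 1
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(X, y, k=5)


class TestSelectBest:
    def test_tradeoff_arithmetic(self):
        choice = select_best({"a": (0.80, 0.10), "b": (0.78, 0.40)}, lam=0.5)
        assert choice == "a"  # 0.75 > 0.58

    def test_tie_broken_lexicographically(self):
        assert select_best({"b": (0.8, 0.2), "a": (0.8, 0.2)}) == "a"

    def test_single_model_returned(self):
        assert select_best({"only": (0.7, 0.1)}) == "only"

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_best({})


class TestValidate:
    def test_resubstitution_of_perfect_model_gives_auc_one(self):
        y = pd.Series([0] * 8 + [1] * 8, index=[f"P{i}" for i in range(16)])
        X = pd.DataFrame({"f": np.r_[np.zeros(8), np.ones(8)]}, index=y.index)
        model = fit_backward_aic(X, y, ["f"])
        auc, ci = validate(model, X, y)
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_single_class_validation_rejected(self):
        y = pd.Series([0] * 8 + [1] * 8, index=[f"P{i}" for i in range(16)])
        X = pd.DataFrame({"f": np.arange(16.0)}, index=y.index)
        model = fit_backward_aic(X, y, [])
        with pytest.raises(ValueError):
            validate(model, X, pd.Series(np.ones(16, int), index=y.index))

    def test_delong_interval_contains_auc(self):
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        p = np.clip(0.5 * y + rng.random(60) * 0.5, 0, 1)
        auc, (lo, hi) = delong_ci(y, p)
        assert 0 <= lo <= auc <= hi <= 1


class TestStratifyKM:
    def _probs(self, values):
        return pd.Series(values, index=[f"P{i}" for i in range(len(values))])

    def test_identical_groups_are_not_separated(self):
        times = [5, 10, 15, 20, 25] * 2
        events = [1, 1, 0, 1, 0] * 2
        probs = self._probs([0.2] * 5 + [0.8] * 5)
        res = stratify_km(probs, outcome_table(times, events))
        assert res.p_value > 0.5

    def test_km_without_censoring_matches_empirical_survival(self):
        times = [2.0, 4.0, 6.0, 8.0, 1.0, 3.0, 5.0, 7.0]
        probs = self._probs([0.1, 0.2, 0.3, 0.4, 0.9, 0.9, 0.9, 0.9])
        res = stratify_km(probs, outcome_table(times, [1] * 8))
        curve = res.km_curves["low"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[4.0] == pytest.approx(0.5)  # 2 of 4 low-risk still event-free
        assert res.median_survival["low"] == pytest.approx(4.0)

    def test_logrank_statistic_matches_observed_minus_expected_oracle(self):
        # 10 patients, no ties in group labels; hand-computable log-rank
        times = [1, 2, 3, 4, 5, 1.5, 2.5, 3.5, 4.5, 6]
        events = [1, 1, 0, 1, 1, 1, 1, 1, 0, 1]
        probs = self._probs([0.1] * 5 + [0.9] * 5)
        res = stratify_km(probs, outcome_table(times, events), rho=0.0)

        # oracle: sum over event times of (observed_high - expected_high)
        import numpy as np
        t = np.array(times)
        e = np.array(events)
        grp = np.array([0] * 5 + [1] * 5)
        o_minus_e, var = 0.0, 0.0
        for tt in sorted(t[e == 1]):
            at_risk = t >= tt
            d = ((t == tt) & (e == 1)).sum()
            d1 = ((t == tt) & (e == 1) & (grp == 1)).sum()
            n = at_risk.sum()
            n1 = (at_risk & (grp == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2 = o_minus_e**2 / var
        assert res.test_statistic == pytest.approx(chi2, rel=1e-6)

    def test_degenerate_cutoff_rejected(self):
        probs = self._probs([0.9] * 6)
        with pytest.raises(ValueError, match="one side"):
            stratify_km(probs, outcome_table([1] * 6, [1] * 6), cutoff=0.1)


class TestStratificationMonotonicity:
    def _separation(self, beta, seed=8, n=240):
        from radpipe.modelling import fit_pipeline
        X, y, info = simulate_feature_table(n, seed=seed, beta=beta)
        p = np.clip(special.expit(info["linear_predictor"]), 1e-6, 1 - 1e-6)
        rng = np.random.default_rng(seed + 500)
        t = rng.exponential(1.0 / (-np.log1p(-p) / 12.0))
        out = pd.DataFrame({"patient_id": X.index, "efs_months": t,
                            "efs_event": np.ones(n, int)})
        model = fit_pipeline(X, y, seed=seed)
        res = stratify_km(model.predict(X), out)
        return res.median_survival["low"] - res.median_survival["high"]

    def test_larger_designed_effect_never_reduces_group_separation(self):
        seps = [self._separation(b) for b in (0.2, 0.6125, 1.2)]
        assert seps[0] <= seps[1] <= seps[2]


class TestPrognosticOverlap:
    def _cohorts(self):
        rng = np.random.default_rng(31)
        n = 80
        sig = rng.standard_normal(n)
        y = pd.Series((rng.random(n) < special.expit(2 * sig)).astype(int),
                      index=[f"P{i}" for i in range(n)])
        X = pd.DataFrame({"good": sig, "junk": rng.standard_normal(n)},
                         index=y.index)
        return X, y

    def test_all_prognostic_and_stable_gives_100(self):
        X, y = self._cohorts()
        out = prognostic_overlap(X[["good"]], y, X[["good"]], y,
                                 {"motion": {"good"}, "delineation": {"good"},
                                  "attenuation": {"good"}})
        assert out["defined"]
        assert all(v == 100.0 for v in out["percent_stable"].values())

    def test_empty_prognostic_set_is_flagged(self):
        X, y = self._cohorts()
        out = prognostic_overlap(X[["junk"]], y, X[["junk"]], y,
                                 {"motion": set()})
        assert not out["defined"]
        assert out["percent_stable"]["motion"] == 0.0

    def test_percentages_match_set_arithmetic(self):
        X, y = self._cohorts()
        out = prognostic_overlap(X, y, X, y, {"motion": {"junk"},
                                              "delineation": {"good"}})
        assert out["prognostic_features"] == ["good"]
        assert out["percent_stable"] == {"motion": 0.0, "delineation": 100.0}
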