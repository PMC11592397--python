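import numpy as np
import pandas as pd
import pytest

from helpers_oracles import cindex_pairs_oracle, cox_newton_oracle
from petrad.survival import (
    ENCoxConfig,
    chi2_upper_p,
    concordance_index,
    evaluate_selection,
    fit_encox,
    kaplan_meier,
    logrank,
    mean_split_groups,
    nested_select,
    preprocess,
    risk_score,
    split_train_test,
)
from petrad.synthetic import CohortSpec, generate_cohort


def _cohort_frame(n=99, beta=None, seed=0, censoring=0.2):
    cs = CohortSpec(n_subjects=n, beta_true=beta or {}, seed=seed, censoring_rate=censoring)
    subs = generate_cohort(cs, make_volumes=False)
    df = pd.DataFrame(
        [
            {
                **s.lesion_params,
                "gender": s.clinical["gender"],
                "age": s.clinical["age"],
                "time_days": s.survival_time_days,
                "event": s.event,
                "one_year_dead": s.one_year_dead,
            }
            for s in subs
        ],
        index=[s.subject_id for s in subs],
    )
    return df


class TestChi2:
    def test_printed_p_values(self):
        # clinical / radiomics statistics reproduce the printed p-values
        assert float(f"{chi2_upper_p(6.55):.3g}") == 0.0105
        assert float(f"{chi2_upper_p(10.71):.3g}") == 1.07e-3

    def test_composite_statistic_consistency(self):
        # the printed p-value 5.77e-5 corresponds to the *unrounded* statistic:
        # sf(16.18) itself rounds to 5.76e-5, while a statistic within the
        # rounding interval of 16.18 (e.g. 16.177) reproduces 5.77e-5
        assert float(f"{chi2_upper_p(16.18):.3g}") == 5.76e-5
        assert float(f"{chi2_upper_p(16.177):.3g}") == 5.77e-5

    def test_zero_statistic(self):
        assert chi2_upper_p(0.0) == 1.0

    def test_erfc_identity(self, rng):
        from scipy.special import erfc

        for x in rng.uniform(0, 30, size=20):
            assert chi2_upper_p(x) == pytest.approx(erfc(np.sqrt(x / 2)), rel=1e-12)


class TestKaplanMeier:
    def test_hand_example(self):
        t, s = kaplan_meier([1, 2], [1, 1])
        np.testing.assert_array_equal(t, [1, 2])
        np.testing.assert_allclose(s, [0.5, 0.0])

    def test_all_censored(self):
        t, s = kaplan_meier([5, 6, 7], [0, 0, 0])
        assert t.size == 0  # S stays 1 everywhere

    def test_no_censoring_matches_ecdf(self, rng):
        times = rng.exponential(10, size=50)
        t, s = kaplan_meier(times, np.ones(50, int))
        for ti, si in zip(t, s):
            assert si == pytest.approx(1.0 - np.mean(times <= ti))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=80)
        events = (rng.random(80) < 0.7).astype(int)
        t, s = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for ti, si in zip(t, s):
            assert si == pytest.approx(kmf.predict(ti), abs=1e-10)


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_hypergeometric(self):
        chi2, p = logrank([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        ta = rng.exponential(10, 40)
        tb = rng.exponential(15, 35)
        ea = (rng.random(40) < 0.8).astype(int)
        eb = (rng.random(35) < 0.8).astype(int)
        chi2, p = logrank(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [0, 0], [3], [0])


class TestConcordance:
    def test_perfect_anti_ordering(self):
        times = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert concordance_index(times, np.ones(5, int), scores) == 1.0

    def test_random_scores_near_half(self, rng):
        times = rng.exponential(10, 400)
        scores = rng.random(400)
        assert concordance_index(times, np.ones(400, int), scores) == pytest.approx(0.5, abs=0.05)

    def test_matches_pairs_oracle_and_sksurv(self, rng):
        from sksurv.metrics import concordance_index_censored

        for _ in range(10):
            n = int(rng.integers(10, 31))
            times = np.round(rng.exponential(50, n))
            events = (rng.random(n) < 0.7).astype(int)
            if events.sum() == 0:
                events[0] = 1
            scores = rng.standard_normal(n)
            ours = concordance_index(times, events, scores)
            assert ours == pytest.approx(cindex_pairs_oracle(times, events, scores))
            ref = concordance_index_censored(events.astype(bool), times, scores)[0]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        times = rng.exponential(10, 50)
        events = (rng.random(50) < 0.8).astype(int)
        scores = rng.standard_normal(50)
        base = concordance_index(times, events, scores)
        assert concordance_index(times, events, np.exp(scores)) == pytest.approx(base)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError):
            concordance_index([5.0, 5.0], [0, 0], [1.0, 2.0])


class TestSplit:
    def test_79_20(self):
        df = _cohort_frame()
        train, test = split_train_test(df, seed=0)
        assert len(train) == 79 and len(test) == 20

    def test_event_balance(self):
        df = _cohort_frame(seed=3)
        train, test = split_train_test(df, seed=1)
        p_all = df["one_year_dead"].mean()
        assert abs(test["one_year_dead"].mean() - p_all) <= 1.5 / 20

    def test_determinism_and_disjointness(self):
        df = _cohort_frame()
        t1 = split_train_test(df, seed=5)
        t2 = split_train_test(df, seed=5)
        pd.testing.assert_frame_equal(t1[0], t2[0])
        assert set(t1[0].index).isdisjoint(t1[1].index)

    def test_joint_strata_fallback(self):
        df = _cohort_frame(n=12)
        # joint strata with a high-cardinality column are too small: must fall back
        train, test = split_train_test(df, seed=0, strat_cols=("gender", "age"))
        assert len(train) + len(test) == 12


class TestPreprocess:
    def test_minmax_definitional(self):
        train = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        test = pd.DataFrame({"x": [3.0, 8.0]})
        tr, te = preprocess(train, test, ["x"], [])
        np.testing.assert_allclose(tr["x"], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(te["x"], [0.25, 1.5])  # extrapolates, no clip

    def test_one_hot_sums_to_one(self):
        train = pd.DataFrame({"c": ["a", "b", "c", "a"]})
        test = pd.DataFrame({"c": ["b", "c"]})
        tr, te = preprocess(train, test, [], ["c"])
        assert tr.shape[1] == 3
        np.testing.assert_allclose(tr.sum(axis=1), 1.0)
        np.testing.assert_allclose(te.sum(axis=1), 1.0)

    def test_unseen_category_all_zero(self):
        train = pd.DataFrame({"c": ["a", "b"]})
        test = pd.DataFrame({"c": ["z"]})
        _, te = preprocess(train, test, [], ["c"])
        np.testing.assert_allclose(te.iloc[0], 0.0)

    def test_constant_column_zeroed(self):
        train = pd.DataFrame({"x": [3.0, 3.0]})
        test = pd.DataFrame({"x": [4.0]})
        tr, te = preprocess(train, test, ["x"], [])
        assert (tr["x"] == 0).all() and (te["x"] == 0).all()


class TestFitEncox:
    def _toy(self, rng, n=80):
        x = (rng.random(n) < 0.5).astype(float)
        # distinct times, effect via exponential scaling
        base = rng.exponential(100, n)
        times = np.sort(base * np.exp(-0.8 * x) + rng.random(n) * 1e-6)
        rng.shuffle(times)
        return x, times

    def test_large_alpha_all_zero(self, rng):
        X = rng.standard_normal((50, 4))
        times = rng.exponential(50, 50)
        events = np.ones(50, int)
        coefs = fit_encox(X, times, events, l1_ratio=0.9, alpha=50.0)
        np.testing.assert_array_equal(coefs, 0.0)

    def test_unpenalized_matches_newton_oracle(self, rng):
        x, times = self._toy(rng)
        events = np.ones(x.size, int)
        beta = fit_encox(x[:, None], times, events, l1_ratio=0.5, alpha=0.0)[0]
        oracle = cox_newton_oracle(x, times, events)
        assert beta == pytest.approx(oracle, abs=1e-4)

    def test_sign_equivariance(self, rng):
        X = rng.standard_normal((60, 3))
        times = rng.exponential(50, 60) * np.exp(-0.5 * X[:, 0])
        events = np.ones(60, int)
        c1 = fit_encox(X, times, events, 0.5, 0.01)
        X2 = X.copy()
        X2[:, 0] *= -1
        c2 = fit_encox(X2, times, events, 0.5, 0.01)
        assert c2[0] == pytest.approx(-c1[0], rel=1e-6)
        assert c2[1] == pytest.approx(c1[1], rel=1e-6, abs=1e-12)

    def test_path_monotone_sparsity(self, rng):
        X = rng.standard_normal((70, 8))
        times = rng.exponential(50, 70) * np.exp(-0.5 * X[:, 0] + 0.3 * X[:, 1])
        events = np.ones(70, int)
        alphas = np.geomspace(1e-3, 1.0, 12)
        nnz = [np.count_nonzero(fit_encox(X, times, events, 0.9, a)) for a in alphas]
        assert all(b <= a for a, b in zip(nnz, nnz[1:]))

    def test_too_few_events(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="events"):
            fit_encox(X, np.arange(1, 11), np.zeros(10, int), 0.5, 0.1)


def _fast_config(seed=0, n_select=7):
    return ENCoxConfig(
        l1_ratio_grid=(0.5, 0.9), n_alphas=10, inner_repeats=2, inner_folds=3,
        outer_folds=3, n_select=n_select, seed=seed,
    )


class TestNestedSelect:
    def test_forced_selection_with_exactly_seven(self, rng):
        df = _cohort_frame(beta={"heterogeneity_sd": 1.5}, seed=1)
        X = df[["heterogeneity_sd", "texture_scale_mm", "suv_max", "lesion_radius_mm"]].copy()
        for i in range(3):
            X[f"n{i}"] = rng.random(len(X))
        sel = nested_select(X, df["time_days"], df["event"], _fast_config())
        assert set(sel.selected) <= set(X.columns)
        assert len(sel.selected) <= 7

    def test_recovers_planted_signal(self):
        df = _cohort_frame(beta={"heterogeneity_sd": 1.5, "suv_max": -1.0}, seed=7)
        feats = ["heterogeneity_sd", "texture_scale_mm", "suv_max", "lesion_radius_mm"]
        rng = np.random.default_rng(0)
        X = df[feats].copy()
        for i in range(6):
            X[f"noise{i}"] = rng.random(len(X))
        sel = nested_select(X, df["time_days"], df["event"], _fast_config())
        assert "heterogeneity_sd" in sel.selected or "suv_max" in sel.selected

    def test_seeded_determinism(self):
        df = _cohort_frame(beta={"heterogeneity_sd": 1.2}, seed=2)
        X = df[["heterogeneity_sd", "texture_scale_mm", "suv_max", "lesion_radius_mm"]]
        a = nested_select(X, df["time_days"], df["event"], _fast_config(seed=11))
        b = nested_select(X, df["time_days"], df["event"], _fast_config(seed=11))
        assert a.selected == b.selected
        assert a.final_coefficients == b.final_coefficients
        assert a.outer_scores == b.outer_scores

    def test_outer_scores_structure(self):
        df = _cohort_frame(seed=4)
        X = df[["heterogeneity_sd", "texture_scale_mm", "suv_max", "lesion_radius_mm"]]
        sel = nested_select(X, df["time_days"], df["event"], _fast_config())
        assert len(sel.outer_scores) == 3
        assert sel.winner_fold == int(np.argmax(sel.outer_scores))
        assert all(0 <= s <= 1 for s in sel.outer_scores)

    def test_evaluation_on_held_out(self):
        df = _cohort_frame(beta={"heterogeneity_sd": 1.5}, seed=5)
        train, test = split_train_test(df, seed=0)
        feats = ["heterogeneity_sd", "texture_scale_mm", "suv_max", "lesion_radius_mm"]
        Xtr, Xte = preprocess(train, test, feats, [])
        sel = nested_select(Xtr, train["time_days"], train["event"], _fast_config())
        ci = evaluate_selection(sel, Xte, test["time_days"], test["event"])
        assert 0 <= ci <= 1
        assert sel.test_concordance == ci


class TestRiskScore:
    def test_zero_covariates(self):
        coefs = {"a": 0.5, "b": -1.0}
        X = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert risk_score(coefs, X)[0] == 0.0

    def test_linearity(self):
        coefs = {"a": 0.5}
        X1 = pd.DataFrame({"a": [2.0]})
        X2 = pd.DataFrame({"a": [4.0]})
        assert risk_score(coefs, X2)[0] - risk_score(coefs, X1)[0] == pytest.approx(1.0)

    def test_missing_feature_named(self):
        with pytest.raises(KeyError, match="b"):
            risk_score({"a": 1.0, "b": 2.0}, pd.DataFrame({"a": [1.0]}))

    def test_concordance_invariant_to_monotone_transform(self, rng):
        scores = rng.standard_normal(30)
        times = rng.exponential(10, 30)
        events = np.ones(30, int)
        assert concordance_index(times, events, scores) == pytest.approx(
            concordance_index(times, events, 3 * scores + 7)
        )


class TestMeanSplit:
    def test_two_scores(self):
        high = mean_split_groups(np.array([-1.0, 1.0]))
        np.testing.assert_array_equal(high, [False, True])

    def test_shift_invariance(self, rng):
        scores = rng.standard_normal(20)
        np.testing.assert_array_equal(
            mean_split_groups(scores), mean_split_groups(scores + 100.0)
        )

    def test_tie_at_mean_goes_low(self):
        high = mean_split_groups(np.array([1.0, 1.0, 4.0]))
        np.testing.assert_array_equal(high, [False, False, True])

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mean_split_groups(np.array([2.0, 2.0]))
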