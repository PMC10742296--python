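import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilscore.survival_models import (
    SurvivalData,
    SurvivalError,
    censor_at,
    cox_fit,
    cox_results_frame,
    feature_importance,
    find_cutoff,
    fit_rsf_cv,
    harrell_cindex,
    km_estimate,
    logrank_test,
    split_discovery_validation,
    stratify,
)

from .oracles import brute_force_cindex

SMALL_GRID = ({"n_estimators": 100, "min_samples_leaf": 10, "max_features": "sqrt"},)


def sdata(times, events, ids=None):
    ids = ids if ids is not None else [f"c{i}" for i in range(len(times))]
    return SurvivalData(np.asarray(ids), np.asarray(times, float), np.asarray(events))


class TestCensoring:
    @pytest.mark.parametrize(
        "t_in,e_in,t_out,e_out",
        [(79, 1, 60, 0), (36, 1, 36, 1), (60, 1, 60, 1), (60.5, 0, 60, 0)],
    )
    def test_horizon_clipping(self, t_in, e_in, t_out, e_out):
        out = censor_at(sdata([t_in], [e_in]), 60)
        assert out.times[0] == t_out and out.events[0] == e_out


class TestCindex:
    def test_perfect_concordance(self):
        assert harrell_cindex([3, 2, 1], sdata([1, 2, 3], [1, 1, 1])) == 1.0

    def test_constant_risk_half(self):
        assert harrell_cindex([5, 5, 5], sdata([1, 2, 3], [1, 1, 1])) == 0.5

    def test_partial_concordance_enumerated(self):
        # pairs (1,2) and (1,3) discordant, (2,3)... -> 1/3
        assert harrell_cindex([1, 2, 3], sdata([1, 3, 2], [1, 1, 1])) == pytest.approx(1 / 3)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(SurvivalError):
            harrell_cindex([1, 2], sdata([5, 5], [0, 0]))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 100))
        times = rng.integers(1, 20, n).astype(float)  # many ties
        events = rng.integers(0, 2, n)
        risk = rng.integers(0, 10, n).astype(float)  # risk ties too
        if events.sum() == 0:
            events[0] = 1
        data = sdata(times, events)
        assert harrell_cindex(risk, data) == pytest.approx(
            brute_force_cindex(risk, times, events), abs=1e-12
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 12),   # time
                st.integers(0, 1),    # event
                st.integers(0, 5),    # risk (integer grid forces ties)
            ),
            min_size=2,
            max_size=40,
        )
    )
    def test_property_matches_brute_force(self, rows):
        times = np.array([r[0] for r in rows], dtype=float)
        events = np.array([r[1] for r in rows])
        risk = np.array([r[2] for r in rows], dtype=float)
        data = sdata(times, events)
        try:
            ours = harrell_cindex(risk, data)
        except SurvivalError:
            with pytest.raises(ZeroDivisionError):
                brute_force_cindex(risk, times, events)
            return
        assert ours == pytest.approx(
            brute_force_cindex(risk, times, events), abs=1e-12
        )
        assert 0.0 <= ours <= 1.0

    def test_matches_sksurv(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 50
            times = rng.exponential(30, n) + 0.1
            events = rng.integers(0, 2, n)
            risk = rng.normal(size=n)
            if events.sum() == 0:
                events[0] = 1
            ours = harrell_cindex(risk, sdata(times, events))
            ref = concordance_index_censored(events.astype(bool), times, risk)[0]
            assert ours == pytest.approx(ref, abs=1e-12)


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        km = km_estimate(sdata([5, 10, 15], [0, 0, 0]))
        assert np.all(km.at([1, 10, 100]) == 1.0)

    def test_hand_product_limit(self):
        km = km_estimate(sdata([1, 2, 3], [1, 1, 0]))
        assert km.at(1)[0] == pytest.approx(2 / 3)
        assert km.at(2)[0] == pytest.approx(1 / 3)
        assert km.at(3)[0] == pytest.approx(1 / 3)
        assert km.at(0.5)[0] == 1.0

    def test_duplicating_subjects_leaves_curve_unchanged(self):
        a = km_estimate(sdata([1, 2, 5, 7], [1, 0, 1, 0]))
        b = km_estimate(sdata([1, 2, 5, 7] * 2, [1, 0, 1, 0] * 2))
        assert np.allclose(a.survival, b.survival)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(3, 60))
            times = rng.integers(1, 30, n).astype(float)
            events = rng.integers(0, 2, n)
            km = km_estimate(sdata(times, events))
            kmf = KaplanMeierFitter().fit(times, events)
            for t in np.unique(times):
                assert km.at(t)[0] == pytest.approx(
                    float(kmf.predict(t)), abs=1e-8
                )


class TestLogrank:
    def test_identical_groups_null(self):
        g = sdata([1, 2, 3, 4], [1, 0, 1, 0])
        stat, p = logrank_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_computed_risk_table(self):
        # A = [1,2,3], B = [4,5,6], all events: O1-E1 = 1.85, V = 0.6775
        stat, p = logrank_test(sdata([1, 2, 3], [1, 1, 1]), sdata([4, 5, 6], [1, 1, 1]))
        assert stat == pytest.approx(1.85**2 / 0.6775, rel=1e-9)

    def test_zero_events_degenerate(self):
        stat, p = logrank_test(sdata([1, 2], [0, 0]), sdata([3], [0]))
        assert (stat, p) == (0.0, 1.0)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        for _ in range(25):
            na, nb = int(rng.integers(3, 40)), int(rng.integers(3, 40))
            ta = rng.integers(1, 25, na).astype(float)
            tb = rng.integers(1, 25, nb).astype(float)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            stat, p = logrank_test(sdata(ta, ea), sdata(tb, eb))
            ref = ll_logrank(ta, tb, ea, eb)
            assert stat == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_power_under_strong_hazard_ratio(self):
        """Exponential groups with hazard ratio 3, n=200/arm: near-certain
        rejection at alpha = 0.05."""
        rng = np.random.default_rng(4)
        rejected = 0
        n_sim = 50
        for _ in range(n_sim):
            ta = rng.exponential(30, 200) + 1e-3
            tb = rng.exponential(10, 200) + 1e-3
            _, p = logrank_test(
                sdata(ta, np.ones(200, int)), sdata(tb, np.ones(200, int))
            )
            rejected += p < 0.05
        assert rejected / n_sim > 0.95


class TestRsfCv:
    def _planted(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
        # deterministic hazard: event time strictly decreasing in f0
        times = 100.0 * np.exp(-X["f0"].to_numpy())
        times = times / times.max() * 59 + 0.5
        return X, sdata(times, np.ones(n, int))

    def test_planted_signal_recovered(self):
        X, data = self._planted()
        grid = ({"n_estimators": 200, "min_samples_leaf": 5, "max_features": None},)
        model = fit_rsf_cv(X, data, grid=grid, seed=0)
        assert model.mean_validation_cindex > 0.9

    def test_null_cindex_near_half(self):
        rng = np.random.default_rng(5)
        cs = []
        for seed in range(4):
            X, data = self._planted(seed=seed)
            perm = rng.permutation(len(data))
            data_perm = sdata(data.times[perm], data.events[perm])
            model = fit_rsf_cv(X, data_perm, grid=SMALL_GRID, seed=seed)
            cs.append(model.mean_validation_cindex)
        assert 0.4 < np.mean(cs) < 0.6

    def test_deterministic_under_seed(self):
        X, data = self._planted(n=120)
        m1 = fit_rsf_cv(X, data, grid=SMALL_GRID, seed=7)
        m2 = fit_rsf_cv(X, data, grid=SMALL_GRID, seed=7)
        assert np.array_equal(m1.oof_scores, m2.oof_scores)
        assert np.array_equal(m1.fold_assignment, m2.fold_assignment)

    def test_out_of_fold_scores_cover_every_case(self):
        X, data = self._planted(n=90)
        model = fit_rsf_cv(X, data, grid=SMALL_GRID, seed=1)
        assert len(model.oof_scores) == 90
        assert np.isfinite(model.oof_scores).all()
        assert sorted(np.unique(model.fold_assignment)) == [0, 1, 2]

    def test_missing_values_rejected(self):
        X, data = self._planted(n=60)
        X.iloc[0, 0] = np.nan
        with pytest.raises(SurvivalError):
            fit_rsf_cv(X, data, grid=SMALL_GRID)

    def test_too_few_events_for_folds(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        events = np.zeros(30, int)
        events[0] = 1
        with pytest.raises(SurvivalError):
            fit_rsf_cv(X, sdata(rng.uniform(1, 50, 30), events), grid=SMALL_GRID)


class TestFeatureImportance:
    def test_informative_feature_ranks_first_and_constant_zero(self):
        rng = np.random.default_rng(7)
        n = 250
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"f{i}" for i in range(6)])
        X["const"] = 1.0
        times = 80.0 * np.exp(-1.5 * X["f2"].to_numpy()) + rng.exponential(2, n)
        times = np.clip(times, 0.5, 400)
        data = sdata(times, np.ones(n, int))
        model = fit_rsf_cv(X, data, grid=SMALL_GRID, seed=0)
        imp = feature_importance(model, X, data, n_repeats=5, seed=0)
        assert imp.iloc[0]["feature"] == "f2"
        const_imp = float(imp.set_index("feature").loc["const", "importance"])
        assert abs(const_imp) < 1e-12  # permuting a constant changes nothing

    def test_ranking_deterministic(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        data = sdata(rng.uniform(1, 60, 100), rng.integers(0, 2, 100))
        model = fit_rsf_cv(X, data, grid=SMALL_GRID, seed=2)
        i1 = feature_importance(model, X, data, n_repeats=3, seed=5)
        i2 = feature_importance(model, X, data, n_repeats=3, seed=5)
        pd.testing.assert_frame_equal(i1, i2)


class TestCutoff:
    def test_exhaustive_scan_oracle(self):
        # events only for the two highest scores, with the shortest times
        risk = np.array([1.0, 2.0, 3.0, 4.0])
        data = sdata([50, 40, 1, 1], [0, 0, 1, 1])
        res = find_cutoff(risk, data, min_group_frac=0.0)
        assert 2 < res.cutoff < 3
        # independent exhaustive scan over all midpoints with lifelines
        from lifelines.statistics import logrank_test as ll_logrank

        ps = {}
        for c in (1.5, 2.5, 3.5):
            low = risk <= c
            ps[c] = ll_logrank(
                data.times[low], data.times[~low], data.events[low], data.events[~low]
            ).p_value
        assert min(ps, key=ps.get) == pytest.approx(res.cutoff)
        assert res.p_value == pytest.approx(ps[2.5], abs=1e-8)

    def test_two_scores_single_midpoint(self):
        res = find_cutoff(
            np.array([1.0, 3.0]), sdata([10, 2], [1, 1]), min_group_frac=0.0
        )
        assert res.cutoff == pytest.approx(2.0)

    def test_identical_scores_error(self):
        with pytest.raises(SurvivalError):
            find_cutoff(np.ones(5), sdata([1, 2, 3, 4, 5], [1, 1, 1, 1, 1]))

    def test_group_size_floor_respected(self):
        rng = np.random.default_rng(9)
        risk = rng.normal(size=50)
        data = sdata(rng.uniform(1, 60, 50), rng.integers(0, 2, 50))
        res = find_cutoff(risk, data, min_group_frac=0.2)
        assert res.n_low >= 10 and res.n_high >= 10

    def test_stratify_low_is_leq_cutoff(self):
        risk = np.array([1.0, 2.0, 3.0, 4.0])
        data = sdata([10, 20, 5, 2], [1, 0, 1, 1])
        strat = stratify(risk, data, cutoff=2.0)
        assert strat.low_mask.tolist() == [True, True, False, False]


class TestCox:
    def _binary_ph(self, n=500, hr=2.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        lam = 0.02 * hr**x
        times = rng.exponential(1 / lam) + 1e-3
        cens = rng.exponential(80, n)
        obs = np.minimum(times, cens)
        events = (times <= cens).astype(int)
        return pd.DataFrame({"x": x.astype(float)}), sdata(obs, events)

    def test_hr_recovery_single_fit(self):
        cov, data = self._binary_ph()
        results, cindex = cox_fit(cov, data, "multivariate")
        assert 1.6 < results[0].hr < 2.5
        assert results[0].ci_lower < 2.0 < results[0].ci_upper
        assert 0.5 < cindex < 1.0

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"noise": rng.normal(size=400)})
        data = sdata(rng.exponential(30, 400) + 1e-3, rng.integers(0, 2, 400))
        results, _ = cox_fit(cov, data, "univariate")
        assert 0.8 < results[0].hr < 1.25

    def test_duplication_keeps_hr_shrinks_ci(self):
        cov, data = self._binary_ph(n=200, seed=3)
        r1, _ = cox_fit(cov, data, "multivariate")
        cov2 = pd.concat([cov, cov], ignore_index=True)
        data2 = sdata(np.r_[data.times, data.times], np.r_[data.events, data.events])
        r2, _ = cox_fit(cov2, data2, "multivariate")
        # duplication creates tied event times, which Efron's tie correction
        # treats slightly differently from the untied data: near-equality only
        assert r2[0].hr == pytest.approx(r1[0].hr, rel=0.02)
        assert (r2[0].ci_upper - r2[0].ci_lower) < (r1[0].ci_upper - r1[0].ci_lower)

    def test_categorical_reference_levels(self):
        rng = np.random.default_rng(4)
        n = 200
        cov = pd.DataFrame(
            {
                "sex": rng.choice(["male", "female"], n),
                "ebv_group": rng.choice(["low", "high"], n),
            }
        )
        data = sdata(rng.exponential(30, n) + 1e-3, rng.integers(0, 2, n))
        results, _ = cox_fit(cov, data, "univariate")
        frame = cox_results_frame(results)
        assert set(frame["covariate"]) == {"sex", "ebv_group"}
        assert frame.loc[frame["covariate"] == "sex", "level"].tolist() == ["male"]
        assert frame.loc[frame["covariate"] == "sex", "reference"].tolist() == ["female"]

    def test_model_cindex_equals_linear_predictor_cindex(self):
        cov, data = self._binary_ph(n=300, seed=5)
        results, cindex = cox_fit(cov, data, "multivariate")
        beta = np.log(results[0].hr)
        assert harrell_cindex(beta * cov["x"].to_numpy(), data) == pytest.approx(cindex)

    def test_sign_agrees_with_logrank_direction(self):
        cov, data = self._binary_ph(n=300, seed=6)
        results, _ = cox_fit(cov, data, "multivariate")
        mask = cov["x"] == 1
        km_hi = km_estimate(data.subset(mask.to_numpy()))
        km_lo = km_estimate(data.subset(~mask.to_numpy()))
        # HR > 1 (x=1 riskier) must match lower survival for x=1
        assert (results[0].hr > 1) == (km_hi.median() < km_lo.median())

    def test_separation_flagged_not_crashed(self):
        # complete separation: events only when x = 1, times split
        cov = pd.DataFrame({"x": [0.0, 0, 0, 1, 1, 1]})
        data = sdata([50, 55, 60, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        results, _ = cox_fit(cov, data, "multivariate")
        assert len(results) == 1  # flagged or huge-HR result, never an exception


class TestSplit:
    def test_proportional_event_stratification(self):
        events = np.r_[np.ones(10, int), np.zeros(90, int)]
        data = sdata(np.arange(1, 101, dtype=float), events)
        disc, val = split_discovery_validation(data, 0.3, seed=0)
        assert len(val) == 30
        assert events[val].sum() == 3
        assert len(np.intersect1d(disc, val)) == 0

    def test_zero_fraction_rejected(self):
        data = sdata([1, 2, 3, 4], [1, 0, 1, 0])
        with pytest.raises(SurvivalError):
            split_discovery_validation(data, 0.0)

    def test_same_seed_same_split(self):
        rng = np.random.default_rng(10)
        data = sdata(rng.uniform(1, 60, 80), rng.integers(0, 2, 80))
        s1 = split_discovery_validation(data, 0.3, seed=3)
        s2 = split_discovery_validation(data, 0.3, seed=3)
        assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])
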