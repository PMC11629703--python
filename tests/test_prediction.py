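"""Ridge benchmark: feature assembly, stratified folds, nested CV,
corrected model comparison and learning curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wmhlnm as w
from wmhlnm.prediction import (
    _ridge_path,
    _standardize_train_test,
    naive_paired_ttest,
    pairwise_comparisons,
)


@pytest.fixture(scope="module")
def cohort_features(small_cohort):
    return dict(
        patients=small_cohort.patients.table,
        flnm=small_cohort.flnm,
        slnm=small_cohort.slnm,
        volumetrics=w.volumetric_features(
            small_cohort.patients.masks, small_cohort.parcellation.tract_masks
        ),
    )


class TestAssembleFeatures:
    @pytest.mark.parametrize(
        "set_id,n_cols",
        [
            ("demo", 3),
            ("demo+totalWMH", 4),
            ("demo+tractWMH", 3 + 8),
            ("demo+fLNM", 3 + 52),
            ("demo+sLNM", 3 + 52),
            ("demo+fLNM+sLNM", 3 + 104),
        ],
    )
    def test_column_counts_toy_scale(self, cohort_features, set_id, n_cols):
        fs = w.assemble_features(set_id, cohort_features["patients"],
                                 "attention_executive",
                                 cohort_features["flnm"], cohort_features["slnm"],
                                 cohort_features["volumetrics"])
        assert fs.n_features == n_cols
        assert list(fs.X.columns[:3]) == ["age", "sex", "education"]
        assert not fs.X.isna().any().any()

    def test_published_atlas_scale_column_count(self):
        """At the published atlas size (400+16+64 ROIs, 64 tracts), the
        combined LNM set has 3 + 2*480 = 963 columns."""
        n = 12
        rng = np.random.default_rng(0)
        patients = pd.DataFrame(
            dict(id=range(n), age=rng.normal(70, 8, n), sex=rng.integers(0, 2, n),
                 education=rng.normal(12, 4, n), memory=rng.normal(size=n))
        )
        roi_ids = list(range(1, 481))
        mk = lambda: w.LNMScoreMatrix(
            "fLNM", "positive", 1.0,
            pd.DataFrame(rng.random((n, 480)), columns=roi_ids),
            pd.DataFrame(0, index=range(n), columns=roi_ids),
            pd.DataFrame(False, index=range(n), columns=roi_ids),
        )
        fs = w.assemble_features("demo+fLNM+sLNM", patients, "memory", mk(), mk())
        assert fs.n_features == 963

    def test_missing_targets_dropped(self, cohort_features):
        patients = cohort_features["patients"].copy()
        patients.loc[patients.index[:7], "verbal_memory"] = np.nan
        fs = w.assemble_features("demo", patients, "verbal_memory")
        assert len(fs.y) == len(patients) - 7

    def test_unknown_set_and_missing_source(self, cohort_features):
        with pytest.raises(ValueError):
            w.assemble_features("demo+pet", cohort_features["patients"], "language")
        with pytest.raises(ValueError):
            w.assemble_features("demo+fLNM", cohort_features["patients"], "language")


class TestContinuousStratifiedFolds:
    def test_even_fold_sizes(self):
        y = np.random.default_rng(1).normal(size=100)
        folds = w.continuous_stratified_folds(y, 10, seed=0)
        assert all(len(te) == 10 for _, te in folds)

    def test_partition_properties(self):
        y = np.random.default_rng(2).normal(size=83)
        folds = w.continuous_stratified_folds(y, 7, seed=3)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(83))
        for tr, te in folds:
            assert set(tr) & set(te) == set()

    def test_stratification_beats_random_splits_on_skewed_target(self):
        """Max fold-vs-overall KS distance is below the 95th percentile of
        unstratified splits."""
        rng = np.random.default_rng(4)
        y = rng.lognormal(0, 1, size=200)
        folds = w.continuous_stratified_folds(y, 10, seed=5)
        ks_strat = max(stats.ks_2samp(y[te], y).statistic for _, te in folds)
        null = []
        for _ in range(1000):
            perm = rng.permutation(200)
            null.append(stats.ks_2samp(y[perm[:20]], y).statistic)
        assert ks_strat < np.quantile(null, 0.95)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            w.continuous_stratified_folds(np.arange(5.0), 6)


class TestScorePredictions:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        sc = w.score_predictions(y, y)
        assert sc == {"pearson_r": pytest.approx(1.0), "r2_ss": pytest.approx(1.0),
                      "neg_mse": pytest.approx(0.0)}

    def test_constant_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        sc = w.score_predictions(y, np.full(4, y.mean()))
        assert sc["r2_ss"] == pytest.approx(0.0)
        assert np.isnan(sc["pearson_r"])

    def test_anticorrelated_prediction(self):
        y = np.array([-2.0, -1.0, 1.0, 2.0])  # centred
        sc = w.score_predictions(y, -y)
        assert sc["pearson_r"] == pytest.approx(-1.0)
        assert sc["r2_ss"] == pytest.approx(-3.0)

    def test_r2_matches_sklearn_formulation(self):
        from sklearn.metrics import r2_score

        rng = np.random.default_rng(5)
        y, yp = rng.normal(size=50), rng.normal(size=50)
        assert w.score_predictions(y, yp)["r2_ss"] == pytest.approx(r2_score(y, yp))


class TestNestedRidgeCV:
    def test_strong_signal_recovered(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 5))
        y = 3 * X[:, 0] + rng.normal(scale=0.1, size=300)
        res = w.nested_ridge_cv(X, y, repeats=2, seed=0)
        assert res.mean_pearson_r > 0.95
        assert set(res.records["alpha"]).issubset(set(w.ALPHA_GRID))

    def test_null_signal_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)  # independent of X
        res = w.nested_ridge_cv(X, y, repeats=10, seed=1)
        assert len(res.records) == 100
        assert abs(res.mean_pearson_r) < 0.1

    def test_bookkeeping_100_scores(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, 0.5, -0.5] + rng.normal(size=60)
        res = w.nested_ridge_cv(X, y, repeats=10, seed=2)
        assert len(res.records) == 100
        assert res.records.groupby("repeat").size().eq(10).all()

    def test_leakage_guard_training_stats_unaffected_by_test_outlier(self):
        """Injecting an outlier into a test fold must not move training-fold
        standardization statistics, hence must not change train predictions."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 4))
        y = X[:, 0] + rng.normal(size=50)
        tr = np.arange(40)
        te = np.arange(40, 50)
        Xt1, Xe1 = _standardize_train_test(X[tr], X[te], np.ones(4, bool))
        X_out = X.copy()
        X_out[45] += 100.0  # outlier in the test fold only
        Xt2, Xe2 = _standardize_train_test(X_out[tr], X_out[te], np.ones(4, bool))
        np.testing.assert_array_equal(Xt1, Xt2)

    def test_ridge_path_matches_sklearn(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        Xs, Xe = _standardize_train_test(X[:30], X[30:], np.ones(6, bool))
        preds = _ridge_path(Xs, y[:30], Xe, [0.1, 10.0])
        for alpha, pred in zip([0.1, 10.0], preds):
            sk = Ridge(alpha=alpha).fit(Xs, y[:30]).predict(Xe)
            np.testing.assert_allclose(pred, sk, atol=1e-8)


class TestCorrectedTTest:
    def test_identical_scores(self):
        s = np.random.default_rng(11).normal(size=100)
        cmp = w.corrected_ttest(s, s, 90, 10)
        assert cmp.t == 0.0 and cmp.p == 1.0

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.3, 0.05, 100)
        b = rng.normal(0.28, 0.05, 100)
        cmp = w.corrected_ttest(a, b, 90, 10)
        d = a - b
        t_direct = d.mean() / np.sqrt((1 / 100 + 10 / 90) * d.var(ddof=1))
        assert cmp.t == pytest.approx(t_direct, abs=1e-12)
        assert cmp.p == pytest.approx(2 * stats.t.sf(abs(t_direct), 99), abs=1e-12)

    def test_corrected_never_exceeds_naive(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            corr = w.corrected_ttest(a, b, 90, 10)
            naive_t, _ = naive_paired_ttest(a, b)
            assert abs(corr.t) <= abs(naive_t) + 1e-12

    def test_antisymmetry_and_degenerate(self):
        a = np.full(20, 0.5)
        b = np.full(20, 0.4)
        cmp = w.corrected_ttest(a, b, 90, 10)
        assert cmp.degenerate and cmp.p == pytest.approx(1 / 20)
        ab = w.corrected_ttest(b + 0.01 * np.arange(20), b, 90, 10)
        ba = w.corrected_ttest(b, b + 0.01 * np.arange(20), 90, 10)
        assert ab.t == pytest.approx(-ba.t)


@pytest.fixture(scope="module")
def strong_data():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(200, 4))
    y = X[:, 0] + rng.normal(scale=0.8, size=200)
    return X, y


class TestLearningCurve:

    def test_full_fraction_reproduces_full_cv(self, strong_data):
        X, y = strong_data
        lc = w.learning_curve(X, y, fractions=[1.0], seed=3, repeats=2)
        full = w.nested_ridge_cv(X, y, seed=3, repeats=2)
        assert lc.loc[0, "mean_pearson_r"] == pytest.approx(full.mean_pearson_r)

    def test_all_fractions_reported(self, strong_data):
        X, y = strong_data
        lc = w.learning_curve(X, y, fractions=[0.4, 0.7, 1.0], seed=4, repeats=1)
        assert list(lc["fraction"]) == [0.4, 0.7, 1.0]
        assert lc["mean_pearson_r"].notna().all()

    def test_more_data_helps_on_strong_signal(self):
        """On a many-feature problem where fitting is sample-hungry, the
        full sample outperforms a 20% subsample in >= 18/20 replicates."""
        rng = np.random.default_rng(15)
        X = rng.normal(size=(500, 60))
        y = X @ rng.normal(scale=0.12, size=60) + rng.normal(size=500)
        wins = 0
        for s in range(20):
            lc = w.learning_curve(X, y, fractions=[0.2, 1.0], seed=s, repeats=2)
            if lc.loc[1, "mean_pearson_r"] >= lc.loc[0, "mean_pearson_r"]:
                wins += 1
        assert wins >= 18

    def test_tiny_fraction_rejected(self, strong_data):
        X, y = strong_data
        with pytest.raises(ValueError):
            w.learning_curve(X, y, fractions=[0.05], seed=0)


class TestHeadlinePatternDirection:
    def test_volume_mediated_effects_favour_volumetric_features(self):
        """When cognition is driven by total lesion volume rather than
        network connectivity, the LNM feature set must not significantly
        beat the total-volume set — the main contrast reverses."""
        eff = w.EffectSpec({"attention_executive": w.DomainEffect(
            target_network="dorsal_attention", modality="volume", effect_size=-0.4)})
        vol_better = 0
        for rep in range(3):
            c = w.simulate_cohort(n_patients=300, effects=eff, seed=500 + rep)
            vol = w.volumetric_features(c.patients.masks, c.parcellation.tract_masks)
            res = {}
            for sid in ("demo+totalWMH", "demo+fLNM+sLNM"):
                fs = w.assemble_features(sid, c.patients.table, "attention_executive",
                                         c.flnm, c.slnm, vol)
                res[sid] = w.nested_ridge_cv(fs.X.to_numpy(), fs.y.to_numpy(),
                                             repeats=5, seed=rep,
                                             continuous=fs.continuous)
            a, b = res["demo+fLNM+sLNM"], res["demo+totalWMH"]
            cmp = w.corrected_ttest(a.scores, b.scores,
                                    float(a.records["n_train"].mean()),
                                    float(a.records["n_test"].mean()))
            assert not (cmp.t > 0 and cmp.p < 0.05)
            vol_better += b.mean_pearson_r > a.mean_pearson_r
        assert vol_better >= 2


class TestAddedPerformanceRatio:
    def test_equal_gain_is_one_and_zero_denominator(self):
        assert w.added_performance_ratio(0.3, 0.35, 0.35) == pytest.approx(1.0)
        with pytest.raises(ZeroDivisionError):
            w.added_performance_ratio(0.3, 0.3, 0.4)
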