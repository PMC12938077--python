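import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import recall_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from coaxstack import (
    FEATURE_NAMES,
    ModelHyperparameters,
    bayes_optimize,
    estimate_threshold,
    feature_importances,
    load_model,
    predict_pairs,
    save_model,
    train_forest,
)
from coaxstack.classifier import _kde_density, ablation_run

FAST_HP = ModelHyperparameters(n_trees=120, max_depth=12, seed=2)


def planted_table(n=400, seed=0, informative="L0"):
    """Random feature table whose label depends on a single feature."""
    rng = np.random.default_rng(seed)
    data = {name: rng.normal(size=n) for name in FEATURE_NAMES}
    df = pd.DataFrame(data)
    df["label"] = (df[informative] > 0).astype(int)
    return df


class TestTrainForest:
    def test_defaults_are_the_reference_optimum(self):
        hp = ModelHyperparameters()
        assert (hp.n_trees, hp.max_depth, hp.min_split, hp.min_leaf) == (703, 43, 5, 1)
        assert (hp.feature_fraction, hp.positive_class_weight) == (0.23, 4.8)

    def test_separable_rule_recovered(self):
        df = planted_table(400, seed=1)
        cv = StratifiedKFold(10, shuffle=True, random_state=0)
        scores = cross_val_score(
            FAST_HP.make_forest(), df[list(FEATURE_NAMES)], df["label"], cv=cv,
            scoring="accuracy",
        )
        assert scores.mean() > 0.9

    def test_missing_feature_column_rejected(self):
        df = planted_table(50).drop(columns=["L2"])
        with pytest.raises(ValueError, match="missing columns"):
            train_forest(df, FAST_HP)

    def test_single_class_rejected(self):
        df = planted_table(50)
        df["label"] = 1
        with pytest.raises(ValueError, match="2 samples per class"):
            train_forest(df, FAST_HP)

    def test_determinism_with_fixed_seed(self):
        df = planted_table(200, seed=3)
        m1 = train_forest(df, FAST_HP, threshold=0.42)
        m2 = train_forest(df, FAST_HP, threshold=0.42)
        p1 = [p.probability for p in predict_pairs(m1, df)]
        p2 = [p.probability for p in predict_pairs(m2, df)]
        assert p1 == p2

    def test_pinned_threshold_recorded(self):
        df = planted_table(100, seed=4)
        m = train_forest(df, FAST_HP, threshold=0.42)
        assert m.threshold == 0.42
        assert m.training_metadata["threshold_source"] == "pinned"

    def test_model_roundtrip(self, tmp_path):
        df = planted_table(100, seed=5)
        m = train_forest(df, FAST_HP, threshold=0.42)
        save_model(m, tmp_path / "m.joblib")
        m2 = load_model(tmp_path / "m.joblib")
        assert m2.threshold == m.threshold
        assert [p.probability for p in predict_pairs(m2, df)] == [
            p.probability for p in predict_pairs(m, df)
        ]


class TestPredictPairs:
    def test_empty_input(self):
        m = train_forest(planted_table(100, seed=6), FAST_HP, threshold=0.42)
        assert predict_pairs(m, []) == []

    def test_label_threshold_consistency(self):
        df = planted_table(200, seed=7)
        m = train_forest(df, FAST_HP)
        for p in predict_pairs(m, df):
            assert p.label == int(p.probability > m.threshold)

    def test_repeat_calls_identical(self):
        df = planted_table(100, seed=8)
        m = train_forest(df, FAST_HP, threshold=0.42)
        assert predict_pairs(m, df) == predict_pairs(m, df)


class TestThreshold:
    def test_well_separated_constant_samples(self):
        t = estimate_threshold([0.9] * 30, [0.1] * 30)
        assert 0.1 < t < 0.9

    def test_identical_distributions_fall_back(self):
        with pytest.warns(UserWarning, match="do not cross"):
            t = estimate_threshold([0.5] * 20, [0.5] * 20)
        assert t == 0.5

    def test_crossing_between_separated_gaussians(self):
        rng = np.random.default_rng(0)
        pos = np.clip(rng.normal(0.8, 0.05, 300), 0, 1)
        neg = np.clip(rng.normal(0.3, 0.05, 300), 0, 1)
        t = estimate_threshold(pos, neg)
        assert 0.4 < t < 0.7

    def test_kde_matches_scipy_at_equal_bandwidth(self):
        # scipy's "silverman" factor omits the IQR term of the classic
        # 0.9*min(sd, iqr/1.34) rule, so compare at a pinned bandwidth
        from scipy.stats import gaussian_kde

        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.1, 200)
        grid = np.linspace(0, 1, 64)
        sd, iqr = x.std(ddof=1), np.subtract(*np.percentile(x, [75, 25]))
        bw = 0.9 * min(sd, iqr / 1.34) * len(x) ** (-1 / 5)
        ours = _kde_density(x, grid)
        ref = gaussian_kde(x, bw_method=bw / sd)(grid)
        assert np.allclose(ours, ref, rtol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_threshold([], [0.1])


class TestImportances:
    def test_sum_to_one_and_rule_feature_leads(self):
        df = planted_table(500, seed=9, informative="dG_coax")
        m = train_forest(df, FAST_HP, threshold=0.42)
        for criterion in ("gini", "information_gain"):
            imp = feature_importances(m, criterion)
            assert sum(v for _, v in imp) == pytest.approx(1.0, abs=1e-9)
            assert imp[0][0] == "dG_coax"

    def test_constant_feature_gets_zero(self):
        df = planted_table(300, seed=10)
        df["A_L2"] = 0.0
        m = train_forest(df, FAST_HP, threshold=0.42)
        assert dict(feature_importances(m))["A_L2"] == 0.0

    def test_unknown_criterion(self):
        m = train_forest(planted_table(100, seed=11), FAST_HP, threshold=0.42)
        with pytest.raises(ValueError):
            feature_importances(m, "chi2")


class TestAblation:
    def test_dropping_nothing_equals_baseline(self):
        df = planted_table(250, seed=12)
        base = ablation_run(df, [], FAST_HP, folds=5, seed=3)
        again = ablation_run(df, [], FAST_HP, folds=5, seed=3)
        assert base == again

    def test_dropping_sole_informative_feature_collapses_accuracy(self):
        df = planted_table(400, seed=13)
        full, _ = ablation_run(df, [], FAST_HP, folds=5, seed=3)
        ablated, _ = ablation_run(df, ["L0"], FAST_HP, folds=5, seed=3)
        prior = max(df["label"].mean(), 1 - df["label"].mean())
        assert full > 0.9
        assert ablated < prior + 0.1

    def test_dropping_noise_feature_changes_little(self):
        df = planted_table(400, seed=14)
        full, _ = ablation_run(df, [], FAST_HP, folds=5, seed=3)
        ablated, _ = ablation_run(df, ["A_L1"], FAST_HP, folds=5, seed=3)
        assert abs(full - ablated) < 0.05

    def test_dropping_everything_rejected(self):
        df = planted_table(100, seed=15)
        with pytest.raises(ValueError):
            ablation_run(df, list(FEATURE_NAMES), FAST_HP, folds=3, seed=0)


class TestBayesOptimize:
    def test_collapsed_space_returns_the_point(self):
        df = planted_table(120, seed=16)
        space = {"n_trees": ("choice", [25]), "max_depth": ("choice", [6])}
        hp = bayes_optimize(df, space, folds=3, seed=0)
        assert (hp.n_trees, hp.max_depth) == (25, 6)

    def test_two_point_space_picks_the_better_config(self):
        df = planted_table(250, seed=17)
        space = {"n_trees": ("choice", [1, 60])}
        hp = bayes_optimize(df, space, folds=4, seed=0)
        # oracle: exhaustive evaluation of both candidates
        cv = StratifiedKFold(4, shuffle=True, random_state=0)
        scores = {
            n: cross_val_score(
                ModelHyperparameters(n_trees=n, seed=0).make_forest(),
                df[list(FEATURE_NAMES)], df["label"], cv=cv, scoring="roc_auc",
            ).mean()
            for n in (1, 60)
        }
        assert hp.n_trees == max(scores, key=scores.get)

    def test_seeded_search_is_deterministic(self):
        df = planted_table(150, seed=18)
        space = {
            "n_trees": ("int", 10, 60),
            "feature_fraction": ("float", 0.2, 1.0),
        }
        a = bayes_optimize(df, space, n_init=3, n_iter=3, folds=3, seed=7)
        b = bayes_optimize(df, space, n_init=3, n_iter=3, folds=3, seed=7)
        assert a == b

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            bayes_optimize(planted_table(60, seed=19), {"n_trees": ("int", 50, 10)},
                           folds=3)


class TestSyntheticRecoveryProperties:
    def test_higher_l0_does_not_raise_stacking_probability(self, small_dataset, params):
        m = train_forest(small_dataset.table, FAST_HP, threshold=0.42)
        from coaxstack.thermodynamics import coaxial_stack_energy  # noqa: F401

        rows = []
        for L0 in range(0, 11):
            if L0 == 0:
                dg = -2.0
            elif L0 == 1:
                dg = 0.0
            elif L0 <= 6:
                dg = 8.1
            else:
                dg = 8.1 + 1.1 * np.log(L0 / 6)
            rows.append(dict(zip(FEATURE_NAMES,
                                 [L0, 2, 2, 0, 0, 0, 4, 4, 0, -3.0, -3.0, dg])))
        probs = [p.probability for p in predict_pairs(m, pd.DataFrame(rows))]
        assert probs[0] > probs[-1]
        assert np.mean(probs[:3]) > np.mean(probs[-3:])

    def test_class_weight_never_hurts_recall(self, small_dataset):
        df = small_dataset.table
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(df))
        cut = int(0.7 * len(df))
        tr, te = df.iloc[idx[:cut]], df.iloc[idx[cut:]]
        recalls = []
        for w in (0.5, 2.0, 4.8, 8.0):
            hp = ModelHyperparameters(n_trees=120, max_depth=12,
                                      positive_class_weight=w, seed=2)
            m = train_forest(tr, hp, threshold=0.5)
            pred = [p.label for p in predict_pairs(m, te)]
            recalls.append(recall_score(te["label"], pred))
        # monotone trend up to a small bootstrap-noise tolerance
        for a, b in zip(recalls, recalls[1:]):
            assert b >= a - 0.01
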