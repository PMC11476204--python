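"""Model training, SMOTE, evaluation metrics and their oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiosplice import (
    FEATURE_SETS,
    ModelConfig,
    bias_variance_decomposition,
    cross_validate,
    evaluate,
    feature_importance,
    haldane_anscombe_or,
    make_training_set,
    smote_oversample,
    train_model,
)
from cardiosplice.rf_model import decompose_scores


def labeled_frame(n_pos=30, n_neg=300, seed=0, separation=2.0) -> pd.DataFrame:
    """Labeled variants where max_delta (and weakly median_tpm) carry the
    signal."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    df = pd.DataFrame({
        "max_delta": np.clip(0.4 + separation * 0.1 * y + rng.normal(0, 0.12, n), 0, 1),
        "dist_junction": rng.integers(0, 300, n).astype(float),
        "is_snv": (rng.random(n) < 0.85).astype(float),
        "in_branchpoint": (rng.random(n) < 0.05).astype(float),
        "in_low_complexity": (rng.random(n) < 0.1).astype(float),
        "in_repeat": (rng.random(n) < 0.3).astype(float),
        "median_tpm": np.exp(rng.normal(1 + 0.3 * y, 1.0)),
        "label": np.where(y == 1, "confirmed", "unconfirmed"),
    })
    return df


class TestTrainingSet:
    def test_feature_set_columns(self):
        df = labeled_frame()
        X1, _ = make_training_set(df, 1)
        assert list(X1.columns) == ["max_delta"]
        X2, _ = make_training_set(df, 2)
        assert "max_delta" not in X2.columns and "median_tpm" not in X2.columns
        X4, _ = make_training_set(df, 4)
        assert set(X4.columns) == set(FEATURE_SETS[4])

    def test_missing_rows_omitted_per_feature_set(self):
        df = labeled_frame(n_pos=5, n_neg=20)
        df.loc[3, "median_tpm"] = np.nan
        X3, _ = make_training_set(df, 3)
        X2, _ = make_training_set(df, 2)
        assert 3 not in X3.index and 3 in X2.index
        assert X3.attrs["n_dropped_missing"] == 1

    def test_indeterminate_excluded(self):
        df = labeled_frame(n_pos=5, n_neg=20)
        df.loc[0, "label"] = "indeterminate"
        X, y = make_training_set(df, 4)
        assert 0 not in X.index

    def test_single_class_error(self):
        df = labeled_frame(n_pos=5, n_neg=5)
        df["label"] = "confirmed"
        with pytest.raises(ValueError):
            make_training_set(df, 1)


class TestSmote:
    def test_two_point_segment(self):
        synth = smote_oversample(np.array([[0.0, 0.0], [1.0, 1.0]]), k=1, n_new=50, seed=0)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert (synth >= 0).all() and (synth <= 1).all()

    def test_zero_new_points(self):
        out = smote_oversample(np.array([[0.0], [1.0]]), k=1, n_new=0)
        assert out.shape == (0, 1)

    def test_bounding_box_property(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        synth = smote_oversample(X, k=3, n_new=100, seed=2)
        assert (synth >= X.min(axis=0) - 1e-12).all()
        assert (synth <= X.max(axis=0) + 1e-12).all()

    def test_binary_columns_stay_binary(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=20), (rng.random(20) < 0.5).astype(float)])
        synth = smote_oversample(X, k=4, n_new=200, seed=4)
        assert set(np.unique(synth[:, 1])) <= {0.0, 1.0}

    def test_singleton_minority_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            smote_oversample(np.array([[1.0, 2.0]]), k=1, n_new=5)
        with pytest.raises(ValueError, match="smote_k"):
            smote_oversample(np.eye(3), k=3, n_new=5)


class TestTrainModel:
    def test_separable_training_auc(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"max_delta": np.r_[rng.normal(0.9, 0.01, 20), rng.normal(0.1, 0.01, 20)]})
        y = np.r_[np.ones(20), np.zeros(20)]
        fitted = train_model(X, y, ModelConfig(feature_set=1, imbalance="none", seed=1))
        m = evaluate(fitted.score(X), y, ModelConfig(seed=1))
        assert m.auc == 1.0

    def test_deterministic_given_seed(self):
        df = labeled_frame()
        X, y = make_training_set(df, 4)
        cfg = ModelConfig(seed=11, n_trees=50)
        s1 = train_model(X, y, cfg).score(X)
        s2 = train_model(X, y, cfg).score(X)
        assert np.array_equal(s1, s2)

    def test_constant_label_error(self):
        X = pd.DataFrame({"max_delta": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            train_model(X, np.ones(3), ModelConfig())

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        aucs = []
        for seed in range(10):
            df = labeled_frame(n_pos=40, n_neg=40, seed=seed)
            df["label"] = rng.permutation(df["label"].to_numpy())
            try:
                res = cross_validate(df, ModelConfig(feature_set=4, imbalance="none",
                                                     n_trees=100, seed=seed))
            except ValueError:
                continue
            aucs.append(res.pooled.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestEvaluate:
    def test_perfect_ranking(self):
        m = evaluate(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0]), ModelConfig())
        assert m.auc == 1.0

    def test_or_ha_closed_form(self):
        assert haldane_anscombe_or(9, 1, 1, 9) == pytest.approx((9.5 * 9.5) / (1.5 * 1.5))
        m = evaluate(np.array([0.9] * 9 + [0.9] + [0.1] + [0.1] * 9),
                     np.array([1] * 9 + [0] + [1] + [0] * 9), ModelConfig())
        assert (m.tp, m.fp, m.fn, m.tn) == (9, 1, 1, 9)
        assert m.or_ha == pytest.approx(40.11, abs=0.01)

    def test_zero_cells_finite(self):
        scores = np.zeros(20)
        y = np.array([1] * 10 + [0] * 10)
        m = evaluate(scores, y, ModelConfig(vote_threshold=1.1))
        assert (m.tp, m.fp) == (0, 0)
        assert np.isfinite(m.or_ha) and m.or_ha > 0

    def test_single_class_auc_undefined(self):
        m = evaluate(np.array([0.2, 0.6]), np.array([1, 1]), ModelConfig())
        assert np.isnan(m.auc)

    def test_auc_equals_normalized_mwu(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n1, n0 = rng.integers(3, 30, 2)
            y = np.r_[np.ones(n1), np.zeros(n0)]
            s = rng.choice(np.linspace(0, 1, 11), size=n1 + n0)  # force ties
            auc = evaluate(s, y, ModelConfig()).auc
            u = stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert auc == pytest.approx(u / (n1 * n0))


class TestCrossValidate:
    def test_separable_pooled_auc(self):
        df = labeled_frame(n_pos=30, n_neg=300, separation=6.0, seed=1)
        res = cross_validate(df, ModelConfig(feature_set=1, imbalance="weighted",
                                             n_trees=100, seed=2))
        assert res.pooled.auc >= 0.95

    def test_smote_outside_folds_leaks(self):
        # applying SMOTE before the split (deliberate bug) inflates the
        # apparent AUC relative to leak-free CV
        df = labeled_frame(n_pos=12, n_neg=240, separation=1.0, seed=3)
        cfg = ModelConfig(feature_set=4, imbalance="smote", n_trees=100, seed=4)
        honest = cross_validate(df, cfg).pooled.auc

        X, y = make_training_set(df, 4)
        Xm = X[y == 1].to_numpy(float)
        synth = smote_oversample(Xm, k=5, n_new=int((y == 0).sum() - (y == 1).sum()), seed=5)
        leaky_df = pd.concat(
            [df, pd.DataFrame(synth, columns=X.columns).assign(label="confirmed")],
            ignore_index=True,
        )
        leaky = cross_validate(leaky_df, ModelConfig(feature_set=4, imbalance="none",
                                                     n_trees=100, seed=4)).pooled.auc
        assert honest <= leaky

    def test_reproducible_folds(self):
        df = labeled_frame(seed=7)
        cfg = ModelConfig(feature_set=4, n_trees=50, seed=9)
        r1 = cross_validate(df, cfg)
        r2 = cross_validate(df, cfg)
        pd.testing.assert_series_equal(r1.oof_scores, r2.oof_scores)

    def test_too_few_positives_error(self):
        df = labeled_frame(n_pos=3, n_neg=100)
        with pytest.raises(ValueError, match="cv_folds"):
            cross_validate(df, ModelConfig(cv_folds=5))


class TestImportanceAndBiasVariance:
    def test_single_feature_importance_one(self):
        df = labeled_frame()
        X, y = make_training_set(df, 1)
        fitted = train_model(X, y, ModelConfig(feature_set=1, n_trees=50, seed=0))
        imp = feature_importance(fitted)
        assert imp["max_delta"] == pytest.approx(1.0)

    def test_informative_feature_ranks_first(self):
        wins = 0
        for seed in range(10):
            df = labeled_frame(n_pos=60, n_neg=60, separation=5.0, seed=seed)
            # keep only max_delta informative
            rng = np.random.default_rng(seed)
            df["median_tpm"] = np.exp(rng.normal(1, 1, len(df)))
            X, y = make_training_set(df, 4)
            fitted = train_model(X, y, ModelConfig(feature_set=4, n_trees=100, seed=seed))
            wins += feature_importance(fitted).index[0] == "max_delta"
        assert wins >= 9

    def test_importances_sum_to_one(self):
        df = labeled_frame()
        X, y = make_training_set(df, 4)
        fitted = train_model(X, y, ModelConfig(feature_set=4, n_trees=50, seed=1))
        assert feature_importance(fitted).sum() == pytest.approx(1.0)

    def test_decompose_constant_correct_predictor(self):
        S = np.ones((4, 6))
        y = np.ones(6)
        b2, var, mse = decompose_scores(S, y)
        assert b2 == var == mse == 0.0

    def test_decompose_constant_half_predictor(self):
        S = np.full((5, 10), 0.5)
        y = np.array([0, 1] * 5)
        b2, var, mse = decompose_scores(S, y)
        assert b2 == pytest.approx(0.25)
        assert var == pytest.approx(0.0)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(8)
        S = rng.random((6, 40))
        S[rng.random(S.shape) < 0.3] = np.nan
        y = rng.integers(0, 2, 40)
        b2, var, mse = decompose_scores(S, y)
        assert mse == pytest.approx(b2 + var, abs=1e-9)

    def test_bootstrap_decomposition_runs(self):
        df = labeled_frame(n_pos=20, n_neg=60, seed=9)
        b2, var, mse = bias_variance_decomposition(
            df, ModelConfig(feature_set=4, n_trees=30, seed=3), n_reps=5
        )
        assert mse == pytest.approx(b2 + var, abs=1e-9)
        assert b2 >= 0 and var >= 0
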