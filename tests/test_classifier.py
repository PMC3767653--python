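"""Scaling, SVM training, cross-validation, prediction, persistence."""

import numpy as np
import pytest

from vhsecleave import classifier, corpus, metrics
from vhsecleave.classifier import (
    FeatureMatrix,
    apply_scaler,
    cross_validate,
    featurize,
    fit_scaler,
    predict_windows,
    train,
)


def _toy_features(n=40, seed=0):
    """Separable toy: positives clustered at +1, negatives at 0 on feature 0."""
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=0.05, size=(n, 3))
    y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    X[:, 0] += (y == 1).astype(float)
    return FeatureMatrix(X, y, [("P1", 1), ("P1", 3), ("P1", 5)])


class TestScaler:
    def test_affine_map_endpoints_and_interior(self):
        col = np.array([[-1.17], [0.15], [1.36]])
        p = fit_scaler(col)
        assert p.mins[0] == -1.17 and p.maxs[0] == 1.36
        scaled = apply_scaler(p, col).ravel()
        assert scaled[0] == 0.0 and scaled[2] == 1.0
        assert scaled[1] == pytest.approx((0.15 + 1.17) / 2.53)

    def test_constant_column_maps_to_zero(self):
        p = fit_scaler(np.full((5, 2), 3.0))
        assert (apply_scaler(p, np.full((4, 2), 3.0)) == 0.0).all()

    def test_unseen_values_clip(self):
        p = fit_scaler(np.array([[0.0], [1.0]]))
        assert apply_scaler(p, np.array([[2.0]]))[0, 0] == 1.0
        assert apply_scaler(p, np.array([[-1.0]]))[0, 0] == 0.0

    def test_dimension_mismatch_rejected(self):
        p = fit_scaler(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            apply_scaler(p, np.zeros((3, 5)))

    def test_training_is_affine_invariant(self):
        # shifting/stretching a raw column is absorbed by the [0,1] scaler
        feats = _toy_features()
        shifted = FeatureMatrix(feats.X * 7.0 - 3.0, feats.y, feats.index_map)
        m1 = train(feats, C=1.0)
        m2 = train(shifted, C=1.0)
        d1 = m1.decision_function(feats.X)
        d2 = m2.decision_function(shifted.X)
        assert d1 == pytest.approx(d2, abs=1e-6)


class TestTrain:
    def test_separable_toy_is_perfectly_classified(self):
        feats = _toy_features()
        model = train(feats, kernel="linear", C=10.0)
        pred = np.where(model.decision_function(feats.X) > 0, 1, -1)
        assert (pred == feats.y).all()

    def test_primal_weights_equal_dual_expansion(self):
        # w = sum_i alpha_i y_i x_i over the support vectors
        model = train(_toy_features(), kernel="linear", C=1.0)
        assert model.weights == pytest.approx(
            model.dual_coef @ model.support_vectors, abs=1e-10
        )

    def test_explicit_weights_match_support_expansion(self, small_features, small_linear_model):
        d_w = small_linear_model.decision_function(small_features.X[:50])
        d_sv = small_linear_model.decision_from_support(small_features.X[:50])
        assert d_w == pytest.approx(d_sv, abs=1e-8)

    def test_rbf_model_scores_finite_and_sane(self, small_features):
        model = train(small_features, kernel="rbf", C=1.0, gamma=0.125)
        d = model.decision_function(small_features.X)
        assert np.isfinite(d).all()
        rep = metrics.report(small_features.y, np.where(d > 0, 1, -1), d)
        assert rep.auc > 0.8

    def test_invalid_arguments_rejected(self):
        feats = _toy_features()
        with pytest.raises(ValueError):
            train(feats, kernel="poly")
        with pytest.raises(ValueError):
            train(feats, C=-1.0)
        with pytest.raises(ValueError):
            train(feats, kernel="rbf", gamma=None)
        single = FeatureMatrix(feats.X, np.ones_like(feats.y), feats.index_map)
        with pytest.raises(ValueError):
            train(single)
        bad = FeatureMatrix(feats.X.copy(), feats.y, feats.index_map)
        bad.X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train(bad)


class TestCrossValidate:
    def test_fold_sizes_and_stratification(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = np.array([1] * 60 + [-1] * 40)
        X[:, 0] += 0.5 * y
        feats = FeatureMatrix(X, y, [("P1", 1), ("P1", 3)])
        from sklearn.model_selection import StratifiedKFold

        folds = list(
            StratifiedKFold(n_splits=10, shuffle=True, random_state=5).split(X, y)
        )
        for _, test_idx in folds:
            assert len(test_idx) == 10
            n_pos = int(np.sum(y[test_idx] == 1))
            assert 5 <= n_pos <= 7  # within one sample of the 6:4 ratio
        table, best = cross_validate(feats, c_grid=[1.0], folds=10, seed=5)
        assert len(table) == 1

    def test_same_seed_reproduces_table_and_selection(self, small_features):
        t1, b1 = cross_validate(small_features, c_grid=[0.5, 1.0], folds=5, seed=11)
        t2, b2 = cross_validate(small_features, c_grid=[0.5, 1.0], folds=5, seed=11)
        assert t1.equals(t2)
        assert b1 == b2

    def test_selection_prefers_mcc_then_smaller_c(self, small_features):
        table, best = cross_validate(small_features, c_grid=[0.25, 1.0, 4.0], folds=5, seed=2)
        assert best["MCC"] == table["MCC"].max()

    def test_too_few_samples_per_class(self):
        feats = _toy_features(n=10)
        with pytest.raises(ValueError):
            cross_validate(feats, folds=10)

    def test_longer_windows_do_not_hurt_when_rule_spans_them(self, small_samples):
        """Planted rule spans +/-10: widening 6 -> 10 should not degrade CV MCC."""
        mccs = {}
        for h in (6, 10):
            ss = corpus.trim_samples(small_samples, h)
            feats = featurize(ss)
            _, best = cross_validate(feats, c_grid=[1.0], folds=5, seed=3)
            mccs[h] = best["MCC"]
        assert mccs[10] >= mccs[6] - 0.02


class TestPredictAndPersist:
    def test_malformed_windows_flagged_not_scored(self, small_linear_model):
        h = small_linear_model.half_width
        good = "LVAMFKWYIC" * (2 * h // 10)
        preds = predict_windows(small_linear_model, [good, "SHORT", "X" * 2 * h])
        assert preds[0].decision is not None and preds[0].flag is None
        assert preds[1].flag == "wrong_length"
        assert preds[2].flag == "noncanonical_residue"

    def test_prediction_is_deterministic(self, small_linear_model):
        h = small_linear_model.half_width
        w = "ACDEFGHIKLMNPQRSTVWY"[: 2 * h]
        p1 = predict_windows(small_linear_model, [w])[0]
        p2 = predict_windows(small_linear_model, [w])[0]
        assert p1 == p2

    def test_json_round_trip_preserves_decisions(self, tmp_path, small_features, small_linear_model):
        path = tmp_path / "model.json"
        small_linear_model.save(path)
        back = classifier.TrainedModel.load(path)
        assert back.kernel == "linear"
        assert back.decision_function(small_features.X[:20]) == pytest.approx(
            small_linear_model.decision_function(small_features.X[:20]), abs=1e-12
        )

    def test_evaluate_dimension_mismatch(self, small_linear_model):
        feats = _toy_features()
        with pytest.raises(ValueError):
            classifier.evaluate(small_linear_model, feats)


class TestFeatureCsv:
    def test_csv_round_trip(self, tmp_path, small_features):
        path = tmp_path / "features.csv"
        classifier.write_features_csv(path, small_features)
        back = classifier.read_features_csv(path)
        assert back.index_map == small_features.index_map
        assert back.X == pytest.approx(small_features.X)
        assert (back.y == small_features.y).all()

    def test_header_names_encode_position_and_component(self, small_features):
        names = small_features.feature_names
        assert names[0] == "P10_VHSE1"
        assert names[-1] == "P10'_VHSE5"
        assert len(names) == 60
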