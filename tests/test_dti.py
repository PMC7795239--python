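"""DTI classifier: preprocessing, network training, metrics, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import gwgenkit as gk
from gwgenkit.dti import (
    DTIModel,
    DTIModelConfig,
    DenseNetwork,
    evaluate,
    fit_preprocessor,
    train_dnn,
)

SMALL = dict(
    n_components=16, hidden_sizes=(32, 16), epochs=80, batch_size=32,
    learning_rate=3e-3,
)


def _small_data(n=400, dim=30, seed=0, noise=0.0):
    spec = gk.DTIDatasetSpec(
        n_drugs=30, n_targets=30, drug_dim=dim // 2, target_dim=dim - dim // 2,
        n_pairs=n, label_noise=noise, seed=seed,
    )
    d = gk.generate_dti_dataset(spec)
    return d.features, d.labels


class TestPreprocessor:
    def test_training_columns_centered_before_pca(self):
        X, _ = _small_data()
        pre = fit_preprocessor(X, 10)
        Z = pre.standardize(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-8

    def test_full_component_pca_is_an_isometry(self):
        X, _ = _small_data(n=100, dim=20)
        pre = fit_preprocessor(X, 20)
        Z = pre.transform(X)
        S = pre.standardize(X)
        d_before = np.linalg.norm(S[:20, None] - S[None, :20], axis=2)
        d_after = np.linalg.norm(Z[:20, None] - Z[None, :20], axis=2)
        np.testing.assert_allclose(d_before, d_after, atol=1e-8)

    def test_explained_variance_nonincreasing(self):
        X, _ = _small_data()
        pre = fit_preprocessor(X, 12)
        assert (np.diff(pre.pca.explained_variance_) <= 1e-10).all()

    def test_components_clipped_to_rank_and_sigma_floored(self):
        X = np.hstack([np.random.default_rng(0).random((5, 4)), np.ones((5, 1))])
        pre = fit_preprocessor(X, 50)
        assert pre.n_components <= 5
        assert pre.sigma[-1] > 0  # constant feature floored, not zero


class TestTraining:
    def test_epoch_one_loss_near_log_two_for_balanced_classes(self):
        X, y = _small_data(n=600)
        config = DTIModelConfig(
            **{**SMALL, "epochs": 1, "learning_rate": 1e-6}, seed=0
        )
        pre = fit_preprocessor(X, config.n_components)
        Z = pre.transform(X)
        _, hist = train_dnn(Z[:400], y[:400], Z[400:], y[400:], config)
        # with a near-zero learning rate this is the untrained predictor
        assert hist.train_loss[0] == pytest.approx(np.log(2), abs=0.1)

    def test_fixed_seed_reproduces_history_bit_for_bit(self):
        X, y = _small_data()
        config = DTIModelConfig(**SMALL, seed=7)
        pre = fit_preprocessor(X, config.n_components)
        Z = pre.transform(X)
        _, h1 = train_dnn(Z[:300], y[:300], Z[300:], y[300:], config)
        _, h2 = train_dnn(Z[:300], y[:300], Z[300:], y[300:], config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_separable_data_reaches_high_validation_accuracy(self):
        X, y = _small_data(n=800, seed=3)
        config = DTIModelConfig(**SMALL, seed=3)
        pre = fit_preprocessor(X, config.n_components)
        Z = pre.transform(X)
        _, hist = train_dnn(Z[:600], y[:600], Z[600:], y[600:], config)
        assert max(hist.val_accuracy) >= 0.95

    def test_early_stopping_restores_best_validation_weights(self):
        # noisy labels make validation loss rebound, triggering the patience
        X, y = _small_data(n=500, seed=5, noise=0.3)
        config = DTIModelConfig(
            **{**SMALL, "epochs": 200, "learning_rate": 5e-3},
            early_stopping_patience=5, seed=5,
        )
        pre = fit_preprocessor(X, config.n_components)
        Z = pre.transform(X)
        net, hist = train_dnn(Z[:350], y[:350], Z[350:], y[350:], config)
        assert hist.stopped_epoch is not None
        assert hist.best_epoch < hist.stopped_epoch
        p_val = net.predict_proba(Z[350:])
        from gwgenkit.dti.nn import binary_cross_entropy

        restored = binary_cross_entropy(p_val, y[350:])
        assert restored == pytest.approx(min(hist.val_loss), abs=1e-6)

    def test_single_class_training_set_rejected(self):
        X, y = _small_data()
        config = DTIModelConfig(**SMALL)
        with pytest.raises(ValueError, match="both classes"):
            train_dnn(X[:10], np.zeros(10, dtype=int), X[10:20], y[10:20], config)

    def test_inference_is_deterministic_with_dropout_disabled(self):
        rng = np.random.default_rng(0)
        net = DenseNetwork((8, 6, 1), dropout=0.4, rng=rng)
        X = rng.standard_normal((20, 8)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_proba(X), net.predict_proba(X))

    def test_sigmoid_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        net = DenseNetwork((4, 3, 1), dropout=0.0, rng=rng)
        X = rng.standard_normal((50, 4)).astype(np.float32) * 10
        p = net.predict_proba(X)
        assert (p > 0).all() and (p < 1).all()
        from gwgenkit.dti.nn import binary_cross_entropy

        # extreme logits stay finite in the loss via probability clipping
        extreme = net.predict_proba(X * 1e6)
        assert np.isfinite(
            binary_cross_entropy(extreme, np.zeros(50, dtype=int))
        )


class TestEvaluate:
    def test_perfect_scores(self):
        labels = np.array([0, 0, 1, 1, 1])
        scores = labels.astype(float)
        m = evaluate(scores, labels)
        assert m.auc == pytest.approx(1.0)
        assert m.tpr == 1.0 and m.fpr == 0.0 and m.accuracy == 1.0

    def test_label_independent_scores_have_half_auc(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 10_000)
        scores = rng.random(10_000)
        m = evaluate(scores, labels)
        assert m.auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_normalized_mann_whitney_u(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            labels = rng.integers(0, 2, 60)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.random(60) + 0.3 * labels
            m = evaluate(scores, labels)
            u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            assert m.auc == pytest.approx(
                u / (labels.sum() * (len(labels) - labels.sum())), abs=1e-10
            )

    def test_confusion_identities(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 200)
        scores = rng.random(200)
        m = evaluate(scores, labels)
        assert m.tpr == pytest.approx(m.tp / (m.tp + m.fn))
        assert m.fpr == pytest.approx(1 - m.specificity)
        assert m.roc_fpr[0] == 0 and m.roc_tpr[0] == 0
        assert m.roc_fpr[-1] == 1 and m.roc_tpr[-1] == 1
        assert (np.diff(m.roc_tpr) >= 0).all()

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            evaluate(np.array([0.2, 0.8]), np.array([1, 1]))


@pytest.fixture(scope="module")
def fitted():
    X, y = _small_data(n=600, seed=9)
    config = DTIModelConfig(**SMALL, cv_folds=10, seed=9)
    return DTIModel(X, y, config).fit()


class TestCrossValidationAndPrediction:

    def test_report_layout_matches_fold_table(self, fitted):
        table = fitted.cv_report.table
        assert list(table.index) == [str(i) for i in range(1, 11)] + [
            "Average", "Standard deviation",
        ]

    def test_average_row_recomputes_from_folds(self, fitted):
        table = fitted.cv_report.table
        folds = table.iloc[:10]
        assert table.loc["Average", "testing_accuracy_pct"] == pytest.approx(
            folds["testing_accuracy_pct"].mean(), abs=1e-12
        )

    def test_separable_data_cross_validates_accurately(self, fitted):
        assert fitted.cv_report.mean_testing_accuracy >= 95.0

    def test_predict_bindings_threshold_extremes(self, fitted):
        rng = np.random.default_rng(3)
        drugs = pd.DataFrame(rng.standard_normal((3, 15)),
                             index=["d1", "d2", "d3"])
        targets = pd.DataFrame(rng.standard_normal((4, 15)),
                               index=["t1", "t2", "t3", "t4"])
        all_pairs, _ = fitted.predict_bindings(drugs, targets, threshold=0.0)
        assert all(len(v) == 4 for v in all_pairs.values())
        none, matrix = fitted.predict_bindings(drugs, targets, threshold=1.01)
        assert all(len(v) == 0 for v in none.values())
        assert matrix.shape == (3, 4)

    def test_dimension_mismatch_rejected(self, fitted):
        drugs = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"])
        targets = pd.DataFrame(np.zeros((2, 3)), index=["x", "y"])
        with pytest.raises(ValueError, match="dimension"):
            fitted.predict_bindings(drugs, targets)

    def test_saved_model_round_trips_predictions(self, fitted, tmp_path):
        from gwgenkit.dti.model import load_model

        path = tmp_path / "model.npz"
        fitted.save(path)
        net, preproc = load_model(path)
        X, _ = _small_data(n=50, seed=21)
        reloaded = net.predict_proba(preproc.transform(X))
        np.testing.assert_array_equal(reloaded, fitted.predict_proba(X))

    def test_predictions_recover_planted_rule_out_of_sample(self):
        spec = gk.DTIDatasetSpec(
            n_drugs=40, n_targets=40, drug_dim=15, target_dim=15,
            n_pairs=1200, label_noise=0.0, seed=13,
        )
        data = gk.generate_dti_dataset(spec)
        config = DTIModelConfig(**SMALL, seed=13)
        results = DTIModel(data.features[:900], data.labels[:900], config).fit()
        held = results.predict_proba(data.features[900:])
        accuracy = np.mean((held >= 0.5) == data.labels[900:])
        assert accuracy >= 0.95
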