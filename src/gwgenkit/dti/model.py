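"""The DTI model object: test split, ten-fold cross-validation, prediction.

``DTIModel`` holds the raw labeled feature pairs; ``fit()`` performs the
stratified test split, fits the preprocessor on the training portion, runs
ten-fold cross-validation, keeps the fold model with the best testing
accuracy, and returns a ``DTIResults`` carrying the cross-validation report,
training histories and test-set metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import DTIModelConfig
from .metrics import DTIMetrics, evaluate
from .nn import DenseNetwork, TrainingHistory, binary_cross_entropy, train_dnn
from .preprocess import Preprocessor, fit_preprocessor


@dataclass
class CVReport:
    """Per-fold validation/testing loss and accuracy, their mean and sd.

    ``table`` has one row per fold plus ``Average`` and ``Standard
    deviation`` rows; accuracies are percentages.
    """

    table: pd.DataFrame
    best_fold: int
    histories: list[TrainingHistory] = field(default_factory=list)

    @property
    def mean_testing_accuracy(self) -> float:
        return float(self.table.loc["Average", "testing_accuracy_pct"])

    @property
    def sd_testing_accuracy(self) -> float:
        return float(self.table.loc["Standard deviation", "testing_accuracy_pct"])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: DTIModelConfig,
) -> tuple[DenseNetwork, Preprocessor, CVReport, DTIMetrics]:
    """Stratified test split + ten-fold CV; retain the best-testing fold model.

    A quarter of the pairs (``config.test_fraction``) is held out first; the
    preprocessor (standardization + PCA) is fitted on the remaining training
    portion only.  Each fold trains on nine tenths of the training portion,
    validates on the last tenth, and is evaluated on the common held-out
    test set.  The fold with the highest testing accuracy supplies the
    returned model; the report mirrors the per-fold table layout.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < config.cv_folds * 2:
        raise ValueError("too few samples for the requested folds")
    X_cv, X_test, y_cv, y_test = train_test_split(
        X, y,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    preproc = fit_preprocessor(X_cv, config.n_components)
    Z_cv = preproc.transform(X_cv)
    Z_test = preproc.transform(X_test)
    fold_config = DTIModelConfig(**{
        **config.__dict__, "n_components": preproc.n_components,
    })

    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    rows = []
    histories = []
    best = None  # (testing accuracy, fold index, net)
    for fold, (tr, va) in enumerate(skf.split(Z_cv, y_cv), start=1):
        net, history = train_dnn(
            Z_cv[tr], y_cv[tr], Z_cv[va], y_cv[va], fold_config,
            seed=config.seed + fold,
        )
        histories.append(history)
        p_val = net.predict_proba(Z_cv[va])
        p_test = net.predict_proba(Z_test)
        val_loss = binary_cross_entropy(p_val, y_cv[va], config.prob_clip)
        val_acc = float(np.mean((p_val >= 0.5) == y_cv[va]))
        test_loss = binary_cross_entropy(p_test, y_test, config.prob_clip)
        test_acc = float(np.mean((p_test >= 0.5) == y_test))
        rows.append(
            {
                "validation_loss": val_loss,
                "validation_accuracy_pct": 100 * val_acc,
                "testing_loss": test_loss,
                "testing_accuracy_pct": 100 * test_acc,
            }
        )
        if best is None or test_acc > best[0]:
            best = (test_acc, fold, net)
    table = pd.DataFrame(rows, index=[str(i) for i in range(1, len(rows) + 1)])
    table.loc["Average"] = table.iloc[: len(rows)].mean()
    table.loc["Standard deviation"] = table.iloc[: len(rows)].std(ddof=1)
    assert best is not None
    _, best_fold, net = best
    report = CVReport(table, best_fold, histories)
    test_metrics = evaluate(net.predict_proba(Z_test), y_test)
    return net, preproc, report, test_metrics


def predict_bindings(
    net: DenseNetwork,
    preproc: Preprocessor,
    drugs: pd.DataFrame,
    targets: pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Score every drug x target pair; keep pairs with probability >= threshold.

    ``drugs`` and ``targets`` are feature tables indexed by id; their
    concatenated feature dimension must match the preprocessor.  Returns the
    binding sets and the full probability matrix (drugs x targets).
    """
    n_drug_feats = drugs.shape[1]
    n_target_feats = targets.shape[1]
    if n_drug_feats + n_target_feats != preproc.mean.shape[0]:
        raise ValueError(
            f"drug ({n_drug_feats}) + target ({n_target_feats}) feature "
            f"dimensions do not match the preprocessor "
            f"({preproc.mean.shape[0]})"
        )
    D = drugs.to_numpy(dtype=float)
    T = targets.to_numpy(dtype=float)
    pairs = np.hstack(
        [
            np.repeat(D, len(T), axis=0),
            np.tile(T, (len(D), 1)),
        ]
    )
    probs = net.predict_proba(preproc.transform(pairs)).reshape(len(D), len(T))
    matrix = pd.DataFrame(probs, index=drugs.index, columns=targets.index)
    bindings = {
        drug: set(matrix.columns[matrix.loc[drug] >= threshold])
        for drug in matrix.index
    }
    return bindings, matrix


def save_model(net: DenseNetwork, preproc: Preprocessor, path) -> None:
    """Persist a trained network + preprocessor as a single .npz file."""
    arrays = {
        "layer_sizes": np.asarray(net.layer_sizes),
        "dropout": np.asarray(net.dropout),
        "scaler_mean": preproc.mean,
        "scaler_sigma": preproc.sigma,
        "pca_components": preproc.pca.components_,
        "pca_mean": preproc.pca.mean_,
    }
    for i, (w, b) in enumerate(zip(net.weights, net.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)


class _LoadedPCA:
    """Minimal stand-in for a fitted PCA reconstructed from saved arrays."""

    def __init__(self, components: np.ndarray, mean: np.ndarray):
        self.components_ = components
        self.mean_ = mean
        self.n_components_ = components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) @ self.components_.T


def load_model(path) -> tuple[DenseNetwork, Preprocessor]:
    """Load a model saved by :func:`save_model`."""
    data = np.load(path)
    layer_sizes = tuple(int(s) for s in data["layer_sizes"])
    net = DenseNetwork(
        layer_sizes, float(data["dropout"]), np.random.default_rng(0)
    )
    net.weights = [data[f"w{i}"] for i in range(len(layer_sizes) - 1)]
    net.biases = [data[f"b{i}"] for i in range(len(layer_sizes) - 1)]
    pca = _LoadedPCA(data["pca_components"], data["pca_mean"])
    preproc = Preprocessor(data["scaler_mean"], data["scaler_sigma"], pca)
    return net, preproc


class DTIModel:
    """Drug-target interaction classifier over labeled feature pairs."""

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        config: DTIModelConfig | None = None,
    ):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels).astype(int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree in length")
        self.config = config or DTIModelConfig()

    def fit(self) -> "DTIResults":
        net, preproc, report, test_metrics = cross_validate(
            self.features, self.labels, self.config
        )
        return DTIResults(self, net, preproc, report, test_metrics)


@dataclass
class DTIResults:
    """Fitted DTI classifier with its cross-validation report."""

    model: DTIModel
    network: DenseNetwork
    preprocessor: Preprocessor
    cv_report: CVReport
    test_metrics: DTIMetrics

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self.preprocessor.transform(features))

    def save(self, path) -> None:
        save_model(self.network, self.preprocessor, path)

    def predict_bindings(
        self,
        drugs: pd.DataFrame,
        targets: pd.DataFrame,
        threshold: float = 0.5,
    ) -> tuple[dict[str, set[str]], pd.DataFrame]:
        return predict_bindings(
            self.network, self.preprocessor, drugs, targets, threshold
        )

    def summary(self) -> str:
        t = self.cv_report.table
        lines = [
            "DTI classifier: ten-fold cross-validation",
            t.to_string(float_format=lambda v: f"{v:.3f}"),
            f"Best fold (testing accuracy): {self.cv_report.best_fold}",
            f"Held-out test accuracy: {100 * self.test_metrics.accuracy:.2f}%",
            f"Held-out test AUC: {self.test_metrics.auc:.4f}",
        ]
        return "\n".join(lines)
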