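"""Feature standardization and PCA reduction for DTI descriptor vectors.

Descriptors arrive on wildly different scales, so each feature is
standardized to zero mean and unit variance using statistics fitted on the
training split only, then projected onto the leading principal components
(618 by default, matching the classifier's input layer; clipped to the
available rank for small datasets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: floor for a zero-variance feature's standard deviation
SIGMA_FLOOR = 1e-8


@dataclass
class Preprocessor:
    """Fitted standardization statistics and PCA basis."""

    mean: np.ndarray
    sigma: np.ndarray
    pca: PCA

    @property
    def n_components(self) -> int:
        return int(self.pca.n_components_)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sigma

    def transform(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the fitted "
                f"preprocessor ({self.mean.shape[0]})"
            )
        return self.pca.transform(self.standardize(X))


def fit_preprocessor(X_train: np.ndarray, n_components: int) -> Preprocessor:
    """Fit standardization + PCA on training features only.

    ``n_components`` is clipped (with a warning) to min(#train, #features),
    the maximal attainable rank.
    """
    if X_train.shape[0] == 0:
        raise ValueError("training set is empty")
    mean = X_train.mean(axis=0)
    sigma = X_train.std(axis=0)
    zero_var = sigma < SIGMA_FLOOR
    if zero_var.any():
        logger.warning(
            "%d zero-variance feature(s); sigma floored at %g",
            int(zero_var.sum()), SIGMA_FLOOR,
        )
        sigma = np.where(zero_var, SIGMA_FLOOR, sigma)
    limit = min(X_train.shape[0], X_train.shape[1])
    if n_components > limit:
        logger.warning(
            "n_components=%d exceeds attainable rank %d; clipped",
            n_components, limit,
        )
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit((X_train - mean) / sigma)
    return Preprocessor(mean, sigma, pca)
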