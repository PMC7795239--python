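"""Hyperparameters of the DTI classifier."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class DTIModelConfig:
    """Architecture and training settings.

    The input layer is 618-dimensional (the PCA-reduced descriptor space);
    four hidden layers of 512, 256, 128 and 64 ReLU units each followed by
    dropout, and a single sigmoid output unit.  Training uses Adam at
    learning rate 1e-4 on binary cross-entropy, batches of 100, up to 100
    epochs, with early stopping on validation loss (patience 10, best
    weights restored).  A quarter of the data is held out as the test set;
    ten-fold cross-validation runs on the remainder.
    """

    n_components: int = 618
    hidden_sizes: tuple[int, ...] = (512, 256, 128, 64)
    dropout: float = 0.4
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 100
    test_fraction: float = 0.25
    cv_folds: int = 10
    early_stopping_patience: int = 10
    prob_clip: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes) or self.n_components < 1:
            raise ValueError("layer sizes must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_components, *self.hidden_sizes, 1)
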