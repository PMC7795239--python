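"""Expression data and gene-set containers.

The expression matrix carries entity x sample nonnegative expression for
every node of a GWGEN (protein, gene, TF, lncRNA, miRNA rows alike — a TF
row is the expression of its gene/protein) together with per-sample
control/disease group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
DISEASE = "disease"
GROUPS = (CONTROL, DISEASE)


class ExpressionError(ValueError):
    """Raised for invalid expression matrices or group labels."""


@dataclass
class ExpressionMatrix:
    """Entity x sample nonnegative expression with binary group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are entities (node ids), columns are sample ids.
    group : pandas.Series
        Maps each sample id to ``"control"`` or ``"disease"``.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ExpressionError("need at least two samples")
        if self.values.isna().any().any():
            raise ExpressionError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("expression values must be nonnegative")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ExpressionError(f"duplicate entity row {dup!r}")
        missing = set(self.values.columns) - set(self.group.index)
        if missing:
            raise ExpressionError(
                f"samples without group label: {sorted(missing)}"
            )
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise ExpressionError(f"unknown group labels: {sorted(bad)}")
        # align label order with the matrix columns
        self.group = self.group.loc[list(self.values.columns)]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    def __contains__(self, entity: str) -> bool:
        return entity in self.values.index

    def row(self, entity: str) -> np.ndarray:
        return self.values.loc[entity].to_numpy(dtype=float)

    def samples_in(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])

    def subset(self, group: str) -> "ExpressionMatrix":
        """Restrict to the samples of one group (keeps both-label schema)."""
        cols = self.samples_in(group)
        if len(cols) < 2:
            raise ExpressionError(f"group {group!r} has fewer than 2 samples")
        return ExpressionMatrix(self.values[cols].copy(), self.group.loc[cols])

    def group_means(self) -> pd.DataFrame:
        """Per-entity mean expression in each group (columns control, disease)."""
        out = {}
        for g in GROUPS:
            cols = self.samples_in(g)
            if not cols:
                raise ExpressionError(f"group {g!r} has zero samples")
            out[g] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. pathway memberships read from a GMT file."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: list[str], description: str = "") -> None:
        deduped = list(dict.fromkeys(members))  # keep first occurrence order
        if not deduped:
            raise ExpressionError(f"gene set {name!r} is empty")
        self.sets[name] = deduped
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
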