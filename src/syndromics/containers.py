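"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OutcomeMatrix:
    """Subjects-by-outcomes table with per-subject metadata.

    Attributes
    ----------
    outcomes : pandas.DataFrame
        Numeric outcome variables, one row per subject (index = subject
        id). NaN marks missing observations.
    metadata : pandas.DataFrame
        Per-subject metadata aligned on the same index; conventionally
        holds ``arm``, ``dose`` and ``severity`` columns.
    """

    outcomes: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if not self.outcomes.index.equals(self.metadata.index):
            raise ValueError("outcomes and metadata must share a subject index")
        if self.outcomes.index.has_duplicates:
            raise ValueError("duplicate subject ids")

    @property
    def subject_ids(self) -> list:
        return list(self.outcomes.index)

    @property
    def n_subjects(self) -> int:
        return self.outcomes.shape[0]


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression matrix with sample group labels.

    ``values`` holds log-scale expression after preprocessing (no
    missing entries); ``groups`` maps each sample id to its ordered
    group label (reference / lesioned-vehicle / lesioned-treated).
    """

    values: pd.DataFrame
    groups: pd.Series
    batch: pd.Series | None = None

    def __post_init__(self):
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group labels: {missing}")
        if self.values.shape[1] < 3:
            raise ValueError("need >= 3 samples")
        if np.isnan(self.values.to_numpy()).any():
            raise ValueError("missing values in expression matrix")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.groups.copy(),
                                None if self.batch is None else self.batch.copy())
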