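"""Labeled feature matrices exchanged between encoder, balancer and classifier."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LabeledFeatureMatrix:
    """An n x d feature matrix with binary labels and sample identifiers.

    Labels are exactly {0, 1}; by the pipeline's convention 1 marks the
    positive (sucrose transporter) class. Synthetic oversampled rows get
    generated ids tagged with a ``synthetic|`` prefix so that leak
    checks can recognise them.
    """

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    schema: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, d = self.X.shape
        if len(self.y) != n or len(self.ids) != n:
            raise ValueError("X, y and ids must agree on sample count")
        if len(self.schema) != d:
            raise ValueError(f"schema has {len(self.schema)} names for {d} columns")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(negative count, positive count)."""
        pos = int(self.y.sum())
        return len(self.y) - pos, pos

    def subset(self, idx: np.ndarray) -> "LabeledFeatureMatrix":
        idx = np.asarray(idx)
        return LabeledFeatureMatrix(
            self.X[idx], self.y[idx], [self.ids[i] for i in idx], list(self.schema)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.schema)
        df.insert(0, "label", self.y)
        df.insert(0, "id", self.ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledFeatureMatrix":
        if list(df.columns[:2]) != ["id", "label"]:
            raise ValueError("first two columns must be 'id' and 'label'")
        schema = list(df.columns[2:])
        return cls(
            df[schema].to_numpy(dtype=float),
            df["label"].to_numpy(dtype=int),
            df["id"].astype(str).tolist(),
            schema,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledFeatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
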