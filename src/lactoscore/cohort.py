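"""Bulk cohort container: expression with a binary label and survival outcome."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortTable"]


@dataclass
class CohortTable:
    """Samples x genes expression plus per-sample label, time and event flag.

    ``expression`` is a DataFrame indexed by sample id with gene columns.
    ``label`` is 0/1 (e.g. normal vs tumor), ``time`` a positive follow-up
    time and ``event`` the usual 1=event-observed / 0=censored flag.
    """

    expression: pd.DataFrame
    label: pd.Series
    time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        idx = self.expression.index
        for name in ("label", "time", "event"):
            s = getattr(self, name)
            if not s.index.equals(idx):
                raise ValueError(f"{name} index does not match expression samples")
            if s.isna().any():
                raise ValueError(f"{name} contains missing values")
        if not set(np.unique(self.label)) <= {0, 1}:
            raise ValueError("label must be binary 0/1")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event must be binary 0/1")
        if (self.time <= 0).any():
            raise ValueError("time must be positive")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.expression.index.to_numpy()

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    def restrict(self, genes: list[str]) -> "CohortTable":
        """Keep only the candidate genes present in the table."""
        keep = [g for g in genes if g in self.expression.columns]
        if not keep:
            raise ValueError("no candidate genes found in cohort expression")
        return CohortTable(self.expression[keep], self.label, self.time, self.event)

    def to_tsv(self, path: str | Path) -> None:
        df = self.expression.copy()
        df.insert(0, "event", self.event)
        df.insert(0, "time", self.time)
        df.insert(0, "label", self.label)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            expression=df.drop(columns=["label", "time", "event"]),
            label=df["label"].astype(int),
            time=df["time"].astype(float),
            event=df["event"].astype(int),
        )
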