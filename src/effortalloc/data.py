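"""Shared data containers for condition-level summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Condition, design_conditions

__all__ = ["ConditionSummary"]


@dataclass
class ConditionSummary:
    """Per-condition mean effort/rest durations for one subject-visit.

    This is the fitting target: one mean effort duration (``te``) and one
    mean rest duration (``tr``) per cell of the 3x3 design, plus the number
    of epochs each mean is based on.
    """

    conditions: list[Condition]
    te: np.ndarray  # mean effort duration per condition, s
    tr: np.ndarray  # mean rest duration per condition, s
    n_effort: np.ndarray = None
    n_rest: np.ndarray = None

    def __post_init__(self):
        self.te = np.asarray(self.te, dtype=float)
        self.tr = np.asarray(self.tr, dtype=float)
        n = len(self.conditions)
        if self.te.shape != (n,) or self.tr.shape != (n,):
            raise ValueError("te/tr must have one entry per condition")
        if self.n_effort is None:
            self.n_effort = np.full(n, -1)
        if self.n_rest is None:
            self.n_rest = np.full(n, -1)
        self.n_effort = np.asarray(self.n_effort)
        self.n_rest = np.asarray(self.n_rest)

    @property
    def I(self) -> np.ndarray:
        return np.array([c.I for c in self.conditions])

    @property
    def D(self) -> np.ndarray:
        return np.array([c.D for c in self.conditions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "incentive_pence": [c.incentive_pence for c in self.conditions],
                "difficulty_frac": [c.difficulty_frac for c in self.conditions],
                "I": self.I,
                "D": self.D,
                "te": self.te,
                "tr": self.tr,
                "n_effort": self.n_effort,
                "n_rest": self.n_rest,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConditionSummary":
        conds = [
            Condition(int(r.incentive_pence), float(r.difficulty_frac))
            for r in df.itertuples()
        ]
        return cls(
            conditions=conds,
            te=df["te"].to_numpy(),
            tr=df["tr"].to_numpy(),
            n_effort=df["n_effort"].to_numpy() if "n_effort" in df else None,
            n_rest=df["n_rest"].to_numpy() if "n_rest" in df else None,
        )
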