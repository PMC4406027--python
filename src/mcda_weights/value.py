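"""Additive value model: V = sum_i w_i * v_i, normalized to % of maximum.

Weights come from :mod:`mcda_weights.derive`; performance scores ``v_i``
live on a declared scale ``[0, s_max]`` (default 3).  Because the weights
sum to one, the maximum attainable V equals ``s_max``, so the percentage
of maximum is ``100 * V / s_max``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .derive import WeightVector
from .hierarchy import CriteriaHierarchy

__all__ = ["ScoreVector", "ValueEstimate", "overall_value", "percent_of_max"]

DEFAULT_S_MAX = 3.0


@dataclass(frozen=True)
class ScoreVector:
    """Performance scores of one intervention on every criterion."""

    codes: tuple[str, ...]
    values: np.ndarray
    s_max: float = DEFAULT_S_MAX

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")
        if v.shape != (len(self.codes),):
            raise ValueError("scores and codes differ in length")
        if (v < 0).any() or (v > self.s_max).any():
            raise ValueError(f"scores must lie in [0, {self.s_max}]")

    def __getitem__(self, code: str) -> float:
        return float(self.values[self.codes.index(code)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.codes), name="score")

    @classmethod
    def from_mapping(
        cls,
        scores: Mapping[str, float],
        h: CriteriaHierarchy,
        s_max: float = DEFAULT_S_MAX,
    ) -> "ScoreVector":
        missing = [c for c in h.codes if c not in scores]
        if missing:
            raise ValueError(f"missing scores for {missing}")
        return cls(h.codes, np.array([scores[c] for c in h.codes]), s_max)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame({"criterion": self.codes, "score": self.values})
        frame["s_max"] = self.s_max
        frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ScoreVector":
        frame = pd.read_csv(path)
        return cls(
            tuple(frame["criterion"]),
            frame["score"].to_numpy(float),
            float(frame["s_max"].iloc[0]),
        )


@dataclass(frozen=True)
class ValueEstimate:
    """Overall value of an intervention under one weight vector."""

    V: float
    pct_of_max: float
    technique: str = ""
    respondent_id: str = ""


def percent_of_max(V: float, s_max: float) -> float:
    """Normalize a value estimate to a score out of 100."""
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    if not (0.0 <= V <= s_max + 1e-12):
        raise ValueError(f"V={V} outside [0, {s_max}]")
    return 100.0 * V / s_max


def overall_value(w: WeightVector, v: ScoreVector) -> ValueEstimate:
    """Weighted-sum value V = sum_i w_i * v_i and its percent of maximum.

    Weights and scores must cover the same criteria; scores are aligned
    to the weight vector's code order before the dot product.
    """
    if set(w.codes) != set(v.codes):
        raise ValueError("weight and score vectors cover different criteria")
    scores = v.as_series().reindex(list(w.codes)).to_numpy()
    V = float(np.dot(w.values, scores))
    return ValueEstimate(
        V=V,
        pct_of_max=percent_of_max(V, v.s_max),
        technique=w.technique,
        respondent_id=w.respondent_id,
    )
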