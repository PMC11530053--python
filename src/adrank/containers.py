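"""Shared containers for the multi-criteria decision stages.

A :class:`DecisionMatrix` is an m-alternatives x n-criteria table of
strictly positive performance values; entropy weighting, TOPSIS and SAW all
consume it.  A :class:`WeightVector` carries per-criterion non-negative
weights summing to one, and a :class:`CriterionDirection` records whether
each criterion is a benefit (larger is better) or a cost (smaller is
better).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DecisionMatrix", "WeightVector", "CriterionDirection"]

BENEFIT = "benefit"
COST = "cost"


def _check_unique(labels: Sequence[str], what: str) -> List[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    return labels


@dataclass(frozen=True)
class DecisionMatrix:
    """m x n grid of strictly positive reals with row/column labels.

    Raises
    ------
    ValueError
        If m < 2, n < 1, labels are duplicated or mismatched, or any entry
        is non-positive or non-finite.
    """

    alternatives: List[str]
    criteria: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        alts = _check_unique(self.alternatives, "alternative")
        crit = _check_unique(self.criteria, "criterion")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(alts), len(crit)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(alts)} alternatives x {len(crit)} criteria"
            )
        if len(alts) < 2:
            raise ValueError("need at least 2 alternatives")
        if len(crit) < 1:
            raise ValueError("need at least 1 criterion")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite entries in decision matrix")
        if np.any(vals <= 0):
            i, j = np.argwhere(vals <= 0)[0]
            raise ValueError(
                f"non-positive entry {vals[i, j]} at "
                f"({alts[i]!r}, {crit[j]!r}); all entries must be > 0"
            )
        object.__setattr__(self, "alternatives", alts)
        object.__setattr__(self, "criteria", crit)
        object.__setattr__(self, "values", vals)

    @property
    def m(self) -> int:
        return len(self.alternatives)

    @property
    def n(self) -> int:
        return len(self.criteria)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DecisionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path) -> "DecisionMatrix":
        """First column = alternative id, header row = criterion names."""
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls.from_dataframe(df)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.alternatives, name="alternative"),
                            columns=self.criteria)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass(frozen=True)
class WeightVector:
    """Per-criterion non-negative weights summing to 1 (within 1e-9)."""

    criteria: List[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        crit = _check_unique(self.criteria, "criterion")
        w = np.asarray(self.w, dtype=float)
        if w.shape != (len(crit),):
            raise ValueError("weight vector length does not match criteria")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum()}, expected 1")
        object.__setattr__(self, "criteria", crit)
        object.__setattr__(self, "w", np.clip(w, 0.0, 1.0))

    @classmethod
    def equal(cls, criteria: Sequence[str]) -> "WeightVector":
        n = len(criteria)
        return cls(list(criteria), np.full(n, 1.0 / n))

    @classmethod
    def from_csv(cls, path) -> "WeightVector":
        df = pd.read_csv(path, comment="#")
        if "criterion" not in df.columns or "weight" not in df.columns:
            raise ValueError("weights CSV needs 'criterion' and 'weight' columns")
        w = df["weight"].to_numpy(dtype=float)
        # tolerate rounding from fixed-precision CSV output, reject real errors
        if abs(w.sum() - 1.0) > 1e-4:
            raise ValueError(f"weights in {path} sum to {w.sum()}, expected 1")
        return cls(list(df["criterion"].astype(str)), w / w.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.w, index=self.criteria, name="weight")

    def aligned_to(self, criteria: Sequence[str]) -> np.ndarray:
        """Weights re-ordered to a criterion list (raises on mismatch)."""
        lookup = dict(zip(self.criteria, self.w))
        missing = [c for c in criteria if c not in lookup]
        if missing:
            raise ValueError(f"weights missing for criteria {missing}")
        return np.array([lookup[c] for c in criteria], dtype=float)


@dataclass(frozen=True)
class CriterionDirection:
    """Benefit/cost flag per criterion.

    ``is_benefit`` exposes the flags as a boolean array aligned to
    ``criteria`` (True = benefit = larger is better).
    """

    criteria: List[str]
    direction: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        crit = _check_unique(self.criteria, "criterion")
        dirs = [str(d).lower() for d in self.direction]
        if len(dirs) != len(crit):
            raise ValueError("one direction flag required per criterion")
        bad = sorted(set(dirs) - {BENEFIT, COST})
        if bad:
            raise ValueError(f"unknown direction flags {bad}; use 'benefit' or 'cost'")
        object.__setattr__(self, "criteria", crit)
        object.__setattr__(self, "direction", dirs)

    @classmethod
    def all_benefit(cls, criteria: Sequence[str]) -> "CriterionDirection":
        return cls(list(criteria), [BENEFIT] * len(criteria))

    @classmethod
    def from_mapping(cls, criteria: Sequence[str],
                     mapping: Mapping[str, str]) -> "CriterionDirection":
        """Directions from a {criterion: flag} mapping; missing -> benefit with a warning."""
        dirs = []
        for c in criteria:
            if c in mapping:
                dirs.append(mapping[c])
            else:
                warnings.warn(f"no direction given for criterion {c!r}; defaulting to benefit")
                dirs.append(BENEFIT)
        return cls(list(criteria), dirs)

    @classmethod
    def from_json(cls, criteria: Sequence[str], path) -> "CriterionDirection":
        return cls.from_mapping(criteria, json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dict(zip(self.criteria, self.direction)), indent=2) + "\n")

    @property
    def is_benefit(self) -> np.ndarray:
        return np.array([d == BENEFIT for d in self.direction], dtype=bool)

    def aligned_to(self, criteria: Sequence[str]) -> "CriterionDirection":
        lookup = dict(zip(self.criteria, self.direction))
        missing = [c for c in criteria if c not in lookup]
        if missing:
            raise ValueError(f"directions missing for criteria {missing}")
        return CriterionDirection(list(criteria), [lookup[c] for c in criteria])
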