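"""Simple Additive Weighting: ranking by weighted sums of normalized scores.

Benefit criteria are max-normalized (n_ij = x_ij / max_i x_ij) and cost
criteria min/x-normalized (n_ij = min_i x_ij / x_ij), so every normalized
entry lies in (0, 1] and each column attains 1.  The total score of an
alternative is TS_i = sum_j w_j * n_ij; with weights summing to 1 it lies in
(0, 1], reaching 1 only for an alternative best on every criterion.  Rank 1
is the highest total score.

A ``vector`` normalization variant (x / column Euclidean norm for benefit,
inverted for cost) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .containers import CriterionDirection, DecisionMatrix, WeightVector
from .topsis import TIE_TOL, rank_descending

__all__ = ["SawResult", "saw_normalize", "saw_total_scores", "saw_rank"]


def saw_normalize(D: DecisionMatrix, direction: CriterionDirection | None = None,
                  scheme: str = "linear") -> np.ndarray:
    """Direction-adjusted normalization of a decision matrix.

    ``linear`` (default): x/max per benefit column, min/x per cost column.
    ``vector``: x / ||column|| for benefit, (min/x scaled to max 1) for cost.
    """
    if direction is None:
        direction = CriterionDirection.all_benefit(D.criteria)
    direction = direction.aligned_to(D.criteria)
    x = D.values
    if scheme == "linear":
        benefit = x / x.max(axis=0, keepdims=True)
        cost = x.min(axis=0, keepdims=True) / x
    elif scheme == "vector":
        norms = np.sqrt((x ** 2).sum(axis=0, keepdims=True))
        benefit = x / norms
        inv = x.min(axis=0, keepdims=True) / x
        cost = inv / np.sqrt((inv ** 2).sum(axis=0, keepdims=True))
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    return np.where(direction.is_benefit[None, :], benefit, cost)


def saw_total_scores(N: np.ndarray, W: WeightVector, criteria=None) -> np.ndarray:
    """TS_i = sum_j w_j * n_ij."""
    N = np.asarray(N, dtype=float)
    w = W.aligned_to(criteria) if criteria is not None else np.asarray(W.w)
    if N.shape[1] != w.size:
        raise ValueError(f"grid has {N.shape[1]} columns but {w.size} weights")
    return N @ w


@dataclass(frozen=True)
class SawResult:
    """Audit trail of one SAW run."""

    alternatives: List[str]
    criteria: List[str]
    normalized: np.ndarray
    weighted: np.ndarray
    total_scores: np.ndarray
    ranks: np.ndarray
    ties: List[List[int]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"total_score": self.total_scores, "rank": self.ranks},
            index=pd.Index(self.alternatives, name="alternative"),
        )


def saw_rank(D: DecisionMatrix, W: WeightVector,
             direction: CriterionDirection | None = None,
             scheme: str = "linear", tie_tol: float = TIE_TOL) -> SawResult:
    """Normalize, weight, sum and rank (rank 1 = highest total score)."""
    N = saw_normalize(D, direction, scheme)
    w = W.aligned_to(D.criteria)
    S = N * w[None, :]
    ts = S.sum(axis=1)
    ranks, ties = rank_descending(ts, tie_tol)
    return SawResult(D.alternatives, D.criteria, N, S, ts, ranks, ties)
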