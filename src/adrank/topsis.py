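"""TOPSIS: ranking by relative closeness to the ideal solution.

The decision matrix is vector-normalized column-wise
(r_ij = x_ij / sqrt(sum_i x_ij^2)), scaled by the criterion weights
(v_ij = w_j r_ij), and each alternative's Euclidean distances to the ideal
point (per-criterion best weighted value) and anti-ideal point (per-criterion
worst) are combined into the closeness coefficient

    C_i = P-_i / (P+_i + P-_i)  in [0, 1],

where P+ and P- are the distances to the ideal and anti-ideal points.  Rank 1
goes to the largest closeness.  For a benefit criterion the ideal is the
column maximum; for a cost criterion the column minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .containers import CriterionDirection, DecisionMatrix, WeightVector

__all__ = [
    "DegenerateInstanceError",
    "TopsisResult",
    "vector_normalize",
    "weight_matrix",
    "ideal_points",
    "separation_measures",
    "closeness_coefficient",
    "rank_descending",
    "topsis_rank",
]

TIE_TOL = 1e-12


class DegenerateInstanceError(ValueError):
    """An alternative is simultaneously ideal and anti-ideal (all columns
    constant), so the closeness coefficient is 0/0."""


def vector_normalize(D: DecisionMatrix) -> np.ndarray:
    """Column-wise Euclidean normalization; every column gets norm 1."""
    x = D.values
    return x / np.sqrt((x ** 2).sum(axis=0, keepdims=True))


def weight_matrix(R: np.ndarray, W: WeightVector,
                  criteria=None) -> np.ndarray:
    """v_ij = w_j * r_ij; weights aligned by criterion name when given."""
    R = np.asarray(R, dtype=float)
    w = W.aligned_to(criteria) if criteria is not None else np.asarray(W.w)
    if R.shape[1] != w.size:
        raise ValueError(f"grid has {R.shape[1]} columns but {w.size} weights")
    return R * w[None, :]


def ideal_points(V: np.ndarray, direction: CriterionDirection) -> Tuple[np.ndarray, np.ndarray]:
    """(ideal, anti-ideal): per-column max/min for benefit, min/max for cost."""
    V = np.asarray(V, dtype=float)
    is_benefit = direction.is_benefit
    if V.shape[1] != is_benefit.size:
        raise ValueError("direction flags do not match grid columns")
    hi, lo = V.max(axis=0), V.min(axis=0)
    ideal = np.where(is_benefit, hi, lo)
    anti = np.where(is_benefit, lo, hi)
    return ideal, anti


def separation_measures(V: np.ndarray, ideal: np.ndarray,
                        anti_ideal: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Euclidean distances of each row to the ideal and anti-ideal points."""
    V = np.asarray(V, dtype=float)
    p_plus = np.sqrt(((V - ideal[None, :]) ** 2).sum(axis=1))
    p_minus = np.sqrt(((V - anti_ideal[None, :]) ** 2).sum(axis=1))
    return p_plus, p_minus


def closeness_coefficient(p_plus: np.ndarray, p_minus: np.ndarray) -> np.ndarray:
    """C = P- / (P+ + P-); errors if any alternative has P+ = P- = 0."""
    p_plus = np.asarray(p_plus, dtype=float)
    p_minus = np.asarray(p_minus, dtype=float)
    if np.any(p_plus < 0) or np.any(p_minus < 0):
        raise ValueError("separation measures must be non-negative")
    denom = p_plus + p_minus
    if np.any(denom == 0):
        raise DegenerateInstanceError(
            "alternative at zero distance from both ideal and anti-ideal "
            "(all criterion columns constant)"
        )
    return p_minus / denom


def rank_descending(scores: np.ndarray, tie_tol: float = TIE_TOL
                    ) -> Tuple[np.ndarray, List[List[int]]]:
    """Competition ranks (1 = best) for scores where larger is better.

    Scores within ``tie_tol`` of each other share the minimum rank and
    subsequent ranks are skipped.  Returns (ranks, tie groups) where each
    tie group lists the row indices sharing a rank.
    """
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(scores.size, dtype=int)
    groups: List[List[int]] = []
    pos = 0
    while pos < order.size:
        group = [order[pos]]
        while (pos + len(group) < order.size
               and abs(scores[order[pos + len(group)]] - scores[group[0]]) <= tie_tol):
            group.append(order[pos + len(group)])
        for idx in group:
            ranks[idx] = pos + 1
        if len(group) > 1:
            groups.append(sorted(int(i) for i in group))
        pos += len(group)
    return ranks, groups


@dataclass(frozen=True)
class TopsisResult:
    """Full audit trail of one TOPSIS run."""

    alternatives: List[str]
    criteria: List[str]
    normalized: np.ndarray
    weighted: np.ndarray
    ideal: np.ndarray
    anti_ideal: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray
    closeness: np.ndarray
    ranks: np.ndarray
    ties: List[List[int]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"P_plus": self.p_plus, "P_minus": self.p_minus,
             "closeness": self.closeness, "rank": self.ranks},
            index=pd.Index(self.alternatives, name="alternative"),
        )


def topsis_rank(D: DecisionMatrix, W: WeightVector,
                direction: CriterionDirection | None = None,
                tie_tol: float = TIE_TOL) -> TopsisResult:
    """Run the full TOPSIS chain on a decision matrix.

    Directions default to all-benefit.  Deterministic: rank 1 is the largest
    closeness, ties resolved by competition ranking at ``tie_tol``.
    """
    if direction is None:
        direction = CriterionDirection.all_benefit(D.criteria)
    direction = direction.aligned_to(D.criteria)
    R = vector_normalize(D)
    V = weight_matrix(R, W, D.criteria)
    ideal, anti = ideal_points(V, direction)
    p_plus, p_minus = separation_measures(V, ideal, anti)
    closeness = closeness_coefficient(p_plus, p_minus)
    ranks, ties = rank_descending(closeness, tie_tol)
    return TopsisResult(D.alternatives, D.criteria, R, V, ideal, anti,
                        p_plus, p_minus, closeness, ranks, ties)
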