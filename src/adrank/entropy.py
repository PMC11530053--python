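"""Objective criterion weighting by the entropy method.

Each criterion column of the decision matrix is normalized to a discrete
probability distribution over the m alternatives,

    r_ij = x_ij / sum_i x_ij,

its Shannon entropy is scaled to [0, 1] by 1/ln(m),

    E_j = -(1/ln m) * sum_i r_ij * ln(r_ij)        (0*ln 0 := 0),

and the weight of criterion j is its normalized information content,

    w_j = (1 - E_j) / sum_k (1 - E_k).

A uniform column carries no information (E = 1) and receives zero weight; a
more dispersed column receives more.  Weights are invariant to positive
rescaling of any column, since the normalization cancels the scale.
"""

from __future__ import annotations

import numpy as np

from .containers import DecisionMatrix, WeightVector

__all__ = [
    "DegenerateWeightsError",
    "column_normalize",
    "criterion_entropy",
    "entropy_weights",
    "entropy_weight_vector",
]


class DegenerateWeightsError(ValueError):
    """All criterion columns are uniform: every entropy is 1 and Eq-10 weights
    are 0/0.  Pass ``equal_weights_fallback=True`` to assign 1/n each."""


def column_normalize(D: DecisionMatrix) -> np.ndarray:
    """Proportion grid r_ij = x_ij / column sum; every column sums to 1."""
    x = D.values
    return x / x.sum(axis=0, keepdims=True)


def criterion_entropy(R: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy of each column of a proportion grid.

    Columns must sum to 1 with entries in [0, 1]; needs at least two rows
    (the 1/ln m scale is undefined for m < 2).  Zero entries contribute 0
    via the 0*ln 0 := 0 convention, so the one-hot limit gives E = 0.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    m = R.shape[0]
    if m < 2:
        raise ValueError("entropy undefined for fewer than 2 alternatives (ln m = 0)")
    if np.any(R < 0) or np.any(R > 1 + 1e-12):
        raise ValueError("proportions must lie in [0, 1]")
    if not np.allclose(R.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("each column must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(R > 0, R * np.log(np.where(R > 0, R, 1.0)), 0.0)
    E = -plogp.sum(axis=0) / np.log(m)
    return np.clip(E, 0.0, 1.0)


def entropy_weights(E: np.ndarray, criteria=None, *,
                    equal_weights_fallback: bool = False) -> WeightVector:
    """Weights w_j = (1 - E_j) / sum(1 - E_k) from per-criterion entropies."""
    E = np.asarray(E, dtype=float)
    if np.any(E < -1e-12) or np.any(E > 1 + 1e-12):
        raise ValueError("entropies must lie in [0, 1]")
    d = 1.0 - np.clip(E, 0.0, 1.0)
    total = d.sum()
    names = list(criteria) if criteria is not None else [f"C{j+1}" for j in range(E.size)]
    if total <= 1e-12:
        if equal_weights_fallback:
            return WeightVector.equal(names)
        raise DegenerateWeightsError(
            "all criteria have maximum entropy (uniform columns); "
            "no objective weights exist — use the equal-weights fallback"
        )
    return WeightVector(names, d / total)


def entropy_weight_vector(D: DecisionMatrix, *,
                          equal_weights_fallback: bool = False) -> WeightVector:
    """Full pipeline: decision matrix -> proportions -> entropies -> weights."""
    E = criterion_entropy(column_normalize(D))
    return entropy_weights(E, D.criteria, equal_weights_fallback=equal_weights_fallback)
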