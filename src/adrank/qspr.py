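"""QSPR: relating topological indices to physicochemical properties.

Pearson correlations are computed between every (index, property) pair over
the alternatives both tables share (pairwise deletion of missing property
values), simple ordinary-least-squares regressions property = slope*index +
intercept quantify the planted relations, each index criterion is allocated
the property it correlates with most strongly in absolute value, and that
property's pharmacological preference fixes the criterion's benefit/cost
direction:

=================  ========  ===============================================
property           direction  rationale
=================  ========  ===============================================
melting_point      cost      lower melting point, higher absorption
boiling_point      benefit   higher boiling point, less volatile
molecular_weight   benefit   higher weight, higher absorption degree
density            cost      lower density preferred for absorption
flash_point        benefit   higher flash point, less flammable
complexity         cost      complexity is a risk factor for dosing errors
=================  ========  ===============================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CriterionDirection
from .indices import INDEX_NAMES, IndexVector

__all__ = [
    "PROPERTY_VOCABULARY",
    "PROPERTY_DIRECTIONS",
    "PropertyTable",
    "QsprFit",
    "correlate",
    "fit_simple_regression",
    "qspr_fit_table",
    "allocate_property_to_index",
    "criterion_directions_from_properties",
]

#: canonical property order — also the tie-break order in allocation
PROPERTY_VOCABULARY = (
    "melting_point",    # degC
    "boiling_point",    # degC
    "molecular_weight", # g/mol
    "density",          # g/cm^3
    "flash_point",      # degC
    "complexity",       # dimensionless score
)

PROPERTY_DIRECTIONS: Dict[str, str] = {
    "melting_point": "cost",
    "boiling_point": "benefit",
    "molecular_weight": "benefit",
    "density": "cost",
    "flash_point": "benefit",
    "complexity": "cost",
}


@dataclass(frozen=True)
class PropertyTable:
    """Alternatives x physicochemical-properties table; NaN marks missing."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = [c for c in self.df.columns if c not in PROPERTY_VOCABULARY]
        if unknown:
            raise ValueError(
                f"unknown properties {unknown}; allowed: {list(PROPERTY_VOCABULARY)}")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate alternative labels")
        object.__setattr__(self, "df", self.df.astype(float))

    @classmethod
    def from_csv(cls, path) -> "PropertyTable":
        return cls(pd.read_csv(path, index_col=0, comment="#"))

    @property
    def alternatives(self) -> List[str]:
        return list(self.df.index.astype(str))

    @property
    def properties(self) -> List[str]:
        return list(self.df.columns)

    def missingness(self) -> pd.Series:
        """Per-property count of missing entries."""
        return self.df.isna().sum()


@dataclass(frozen=True)
class QsprFit:
    """One simple linear fit property = slope*index + intercept."""

    index_name: str
    property_name: str
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    stderr_slope: float
    n_used: int


def _indices_frame(indices: Iterable[IndexVector] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(indices, pd.DataFrame):
        return indices
    rows = {iv.graph_id: iv.as_dict() for iv in indices}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_NAMES))


def correlate(indices: Iterable[IndexVector] | pd.DataFrame, props: PropertyTable,
              method: str = "pearson") -> pd.DataFrame:
    """Correlation grid (indices x properties) over shared alternatives.

    Pairwise-complete: each cell uses the alternatives where both the index
    and that property are observed.  A property constant across alternatives
    (or with fewer than 3 complete pairs) gives NaN, flagged as missing
    rather than reported as 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    idx_df = _indices_frame(indices)
    shared = [a for a in idx_df.index.astype(str) if a in set(props.alternatives)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared alternatives, have {len(shared)}")
    idx_df = idx_df.loc[shared]
    prop_df = props.df.loc[shared]

    out = pd.DataFrame(index=idx_df.columns, columns=prop_df.columns, dtype=float)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for ic in idx_df.columns:
        for pc in prop_df.columns:
            pair = pd.concat([idx_df[ic], prop_df[pc]], axis=1).dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                out.loc[ic, pc] = np.nan
                continue
            out.loc[ic, pc] = float(corr(x, y)[0])
    return out


def fit_simple_regression(x, y, index_name: str = "x",
                          property_name: str = "y") -> QsprFit:
    """OLS fit y = slope*x + intercept (closed form, deterministic).

    Requires n >= 3 complete pairs and non-constant x.  A constant y gives
    slope 0 and r^2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 points, have {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("singular fit: x is constant")
    if np.ptp(y) == 0:
        return QsprFit(index_name, property_name, 0.0, float(y[0]), 0.0, 0.0, 0.0, x.size)
    res = stats.linregress(x, y)
    return QsprFit(index_name, property_name, float(res.slope), float(res.intercept),
                   float(res.rvalue), float(res.rvalue ** 2), float(res.stderr), x.size)


def qspr_fit_table(indices: Iterable[IndexVector] | pd.DataFrame,
                   props: PropertyTable) -> pd.DataFrame:
    """OLS fit of every (index, property) pair, one row per pair."""
    idx_df = _indices_frame(indices)
    shared = [a for a in idx_df.index.astype(str) if a in set(props.alternatives)]
    rows = []
    for ic in idx_df.columns:
        for pc in props.properties:
            pair = pd.concat([idx_df.loc[shared, ic], props.df.loc[shared, pc]],
                             axis=1).dropna()
            if len(pair) < 3 or np.ptp(pair.iloc[:, 0].to_numpy()) == 0:
                continue
            f = fit_simple_regression(pair.iloc[:, 0], pair.iloc[:, 1], ic, pc)
            rows.append({"index": f.index_name, "property": f.property_name,
                         "slope": f.slope, "intercept": f.intercept,
                         "pearson_r": f.pearson_r, "r_squared": f.r_squared,
                         "stderr_slope": f.stderr_slope, "n_used": f.n_used})
    return pd.DataFrame(rows)


def allocate_property_to_index(corr: pd.DataFrame) -> Dict[str, Optional[str]]:
    """Assign each index the property with largest \\|r\\|.

    Ties break toward the earlier property in :data:`PROPERTY_VOCABULARY`;
    an index with no finite correlation is left unallocated (None) with a
    warning.
    """
    order = {p: k for k, p in enumerate(PROPERTY_VOCABULARY)}
    alloc: Dict[str, Optional[str]] = {}
    for ic in corr.index:
        row = corr.loc[ic]
        finite = row[np.isfinite(row.astype(float))]
        if finite.empty:
            warnings.warn(f"index {ic!r}: all correlations missing; left unallocated")
            alloc[ic] = None
            continue
        best = sorted(finite.items(), key=lambda kv: (-abs(kv[1]), order.get(kv[0], 99)))[0][0]
        alloc[ic] = best
    return alloc


def criterion_directions_from_properties(alloc: Dict[str, Optional[str]]) -> CriterionDirection:
    """Each index criterion inherits benefit/cost from its allocated property.

    Unallocated indices default to benefit with a warning.
    """
    criteria, dirs = [], []
    for ic, prop in alloc.items():
        criteria.append(ic)
        if prop is None:
            warnings.warn(f"index {ic!r} unallocated; direction defaults to benefit")
            dirs.append("benefit")
        else:
            dirs.append(PROPERTY_DIRECTIONS[prop])
    return CriterionDirection(criteria, dirs)
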