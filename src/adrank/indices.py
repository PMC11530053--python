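"""Degree-based topological indices.

Each index is a sum over the edges ``uv`` of a molecular graph of a kernel
``k(d(u), d(v))`` of the two endpoint degrees, so it is computed most
naturally from the degree-pair edge partition::

    index(G) = sum over degree pairs (a, b) of  count(a, b) * k(a, b)

The six built-ins:

===============  ======================  =========================
name             symbol                  kernel k(a, b)
===============  ======================  =========================
first Zagreb     M1                      a + b
second Zagreb    M2                      a * b
hyper Zagreb     HZ                      (a + b)**2
harmonic         H                       2 / (a + b)
forgotten        F                       a**2 + b**2
sum connectivity SCI                     (a + b)**(-1/2)
===============  ======================  =========================

The algebraic identity ``HZ = F + 2*M2`` holds exactly for integer degrees
and is used as a built-in cross-check.  Additional indices can be registered
via :func:`register_index` without touching downstream code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List

import pandas as pd

from .molgraph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "IndexVector",
    "INDEX_REGISTRY",
    "INDEX_NAMES",
    "register_index",
    "evaluate_index",
    "first_zagreb",
    "second_zagreb",
    "hyper_zagreb",
    "harmonic_index",
    "forgotten_index",
    "sum_connectivity",
    "compute_all",
    "indices_table",
]

Kernel = Callable[[int, int], float]

#: name -> per-degree-pair kernel; insertion order fixes column order downstream
INDEX_REGISTRY: Dict[str, Kernel] = {}


def register_index(name: str, kernel: Kernel) -> None:
    """Register a degree-pair kernel under ``name`` (overwrites silently)."""
    INDEX_REGISTRY[name] = kernel


register_index("M1", lambda a, b: a + b)
register_index("M2", lambda a, b: a * b)
register_index("HZ", lambda a, b: (a + b) ** 2)
register_index("H", lambda a, b: 2.0 / (a + b))
register_index("F", lambda a, b: a * a + b * b)
register_index("SCI", lambda a, b: (a + b) ** -0.5)

INDEX_NAMES = ("M1", "M2", "HZ", "H", "F", "SCI")


def evaluate_index(p: EdgePartition, name: str) -> float:
    """Evaluate a registered index on an edge partition (0 for empty)."""
    kernel = INDEX_REGISTRY[name]
    return float(sum(c * kernel(a, b) for (a, b), c in p.counts.items()))


def first_zagreb(p: EdgePartition) -> float:
    """M1: sum of endpoint-degree sums; equals the sum of squared vertex degrees."""
    return evaluate_index(p, "M1")


def second_zagreb(p: EdgePartition) -> float:
    """M2: sum of endpoint-degree products."""
    return evaluate_index(p, "M2")


def hyper_zagreb(p: EdgePartition) -> float:
    """HZ: sum of squared endpoint-degree sums; equals F + 2*M2."""
    return evaluate_index(p, "HZ")


def harmonic_index(p: EdgePartition) -> float:
    """H: sum of 2/(d(u)+d(v)) over edges."""
    return evaluate_index(p, "H")


def forgotten_index(p: EdgePartition) -> float:
    """F: sum of d(u)^2 + d(v)^2 over edges."""
    return evaluate_index(p, "F")


def sum_connectivity(p: EdgePartition) -> float:
    """SCI: sum of (d(u)+d(v))^(-1/2) over edges."""
    return evaluate_index(p, "SCI")


@dataclass(frozen=True)
class IndexVector:
    """The six built-in indices of one graph."""

    graph_id: str
    m1: float
    m2: float
    hyper_zagreb: float
    harmonic: float
    forgotten: float
    sum_connectivity: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "M1": self.m1,
            "M2": self.m2,
            "HZ": self.hyper_zagreb,
            "H": self.harmonic,
            "F": self.forgotten,
            "SCI": self.sum_connectivity,
        }

    @classmethod
    def from_partition(cls, graph_id: str, p: EdgePartition) -> "IndexVector":
        vals = {name: evaluate_index(p, name) for name in INDEX_NAMES}
        return cls(graph_id, vals["M1"], vals["M2"], vals["HZ"],
                   vals["H"], vals["F"], vals["SCI"])


def compute_all(g: MolecularGraph) -> IndexVector:
    """All six indices of a graph via its edge partition (all zero if edgeless)."""
    iv = IndexVector.from_partition(g.id, edge_partition(g))
    hz, f, m2 = iv.hyper_zagreb, iv.forgotten, iv.m2
    if not math.isclose(hz, f + 2 * m2, rel_tol=0, abs_tol=1e-9):
        raise AssertionError(f"{g.id}: identity HZ = F + 2*M2 violated ({hz} vs {f + 2 * m2})")
    return iv


def indices_table(graphs: Iterable[MolecularGraph]) -> pd.DataFrame:
    """Indices for many graphs as a DataFrame (index: graph_id; columns M1..SCI).

    The CSV written from this frame is a valid decision-matrix input for the
    entropy/TOPSIS/SAW stages.
    """
    rows: List[Dict[str, float]] = []
    ids: List[str] = []
    for g in graphs:
        iv = compute_all(g)
        ids.append(iv.graph_id)
        rows.append(iv.as_dict())
    df = pd.DataFrame(rows, index=pd.Index(ids, name="graph_id"), columns=list(INDEX_NAMES))
    return df
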