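"""Seeded generators for every input the pipeline consumes.

Three artifact kinds, each with its own RNG stream spawned from one master
seed (so adding molecules never perturbs the property-noise draws):

* connected simple graphs with a chemically plausible degree cap, built as a
  degree-capped random spanning tree plus a few ring-closing extra edges —
  the shape of hydrogen-suppressed small-molecule skeletons;
* strictly positive decision matrices (log-normal entries);
* physicochemical property tables planted as linear functions of a
  designated topological index plus Gaussian noise, with the ground truth
  recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .containers import DecisionMatrix
from .indices import indices_table
from .molgraph import MolecularGraph
from .qspr import PROPERTY_VOCABULARY, PropertyTable

__all__ = [
    "SyntheticPanelSpec",
    "random_molecular_graph",
    "random_decision_matrix",
    "synthetic_qspr_panel",
]

#: default planted relation per property: (designated index, slope, intercept, noise sd)
DEFAULT_PLANT: Dict[str, Tuple[str, float, float, float]] = {
    "melting_point": ("H", 8.0, 40.0, 4.0),
    "boiling_point": ("M1", 2.0, 150.0, 8.0),
    "molecular_weight": ("M2", 1.2, 30.0, 6.0),
    "density": ("SCI", 0.05, 0.5, 0.02),
    "flash_point": ("F", 0.5, 80.0, 6.0),
    "complexity": ("HZ", 0.6, 50.0, 12.0),
}


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Configuration of one synthetic drug panel.

    Defaults mirror the study conditions: 12 molecules, 10-30 heavy atoms
    (the span of the fixture drugs), valence-like degree cap 4, and one
    distinct planted property-index relation per property.
    """

    n_molecules: int = 12
    vertex_range: Tuple[int, int] = (10, 30)
    max_degree: int = 4
    ring_density: float = 0.15
    plant: Dict[str, Tuple[str, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLANT))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 2:
            raise ValueError("need at least 2 molecules")
        if self.vertex_range[0] < 2 or self.vertex_range[1] < self.vertex_range[0]:
            raise ValueError("invalid vertex range")
        if self.max_degree < 2:
            raise ValueError("max_degree must be >= 2")
        bad = [p for p in self.plant if p not in PROPERTY_VOCABULARY]
        if bad:
            raise ValueError(f"unknown properties in plant: {bad}")
        for p, (_, _, _, sd) in self.plant.items():
            if sd < 0:
                raise ValueError(f"negative noise sd for {p!r}")


def random_molecular_graph(n_vertices: int, max_degree: int = 4,
                           seed: int | np.random.Generator = 0,
                           ring_density: float = 0.15,
                           id: str = "synthetic") -> MolecularGraph:
    """Connected simple graph with every degree <= ``max_degree``.

    A random spanning tree is grown by attaching each new vertex to a
    uniformly chosen existing vertex with spare degree capacity; then extra
    ring-closing edges (expected count ``ring_density * n_vertices``) are
    added between non-adjacent capacity-bearing pairs.  Same seed, same
    graph.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if max_degree < 2:
        raise ValueError("max_degree must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    deg = np.zeros(n_vertices, dtype=int)
    edges: set = set()
    for v in range(1, n_vertices):
        candidates = [u for u in range(v) if deg[u] < max_degree]
        u = int(rng.choice(candidates))
        edges.add((u, v))
        deg[u] += 1
        deg[v] += 1

    n_extra = int(rng.poisson(ring_density * n_vertices))
    for _ in range(n_extra):
        spare = [v for v in range(n_vertices) if deg[v] < max_degree]
        pairs = [(a, b) for i, a in enumerate(spare) for b in spare[i + 1:]
                 if (a, b) not in edges]
        if not pairs:
            break
        a, b = pairs[int(rng.integers(len(pairs)))]
        edges.add((a, b))
        deg[a] += 1
        deg[b] += 1

    return MolecularGraph.from_edges(id, ((f"v{u}", f"v{v}") for u, v in edges))


def random_decision_matrix(m: int, n: int, seed: int | np.random.Generator = 0,
                           mu: float = 0.0, sigma: float = 1.0) -> DecisionMatrix:
    """m x n strictly positive matrix with log-normal(mu, sigma) entries,
    labelled A1..Am / C1..Cn; seed-reproducible."""
    if m < 2 or n < 1:
        raise ValueError("need m >= 2 alternatives and n >= 1 criteria")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = rng.lognormal(mean=mu, sigma=sigma, size=(m, n))
    return DecisionMatrix([f"A{i+1}" for i in range(m)],
                          [f"C{j+1}" for j in range(n)], vals)


def synthetic_qspr_panel(spec: SyntheticPanelSpec
                         ) -> Tuple[List[MolecularGraph], pd.DataFrame,
                                    PropertyTable, Dict[str, dict]]:
    """Generate (graphs, index table, property table, ground truth).

    Properties obey ``prop = slope * index + intercept + N(0, sd)`` with the
    designation recorded in the returned ground-truth mapping
    ``{property: {"index", "slope", "intercept", "noise_sd"}}``.
    """
    master = np.random.SeedSequence(spec.seed)
    graph_seq, noise_seq = master.spawn(2)
    graph_rng = np.random.default_rng(graph_seq)
    # one substream per property so panel growth never shifts another
    # property's noise draws
    noise_rngs = {p: np.random.default_rng(s)
                  for p, s in zip(PROPERTY_VOCABULARY,
                                  noise_seq.spawn(len(PROPERTY_VOCABULARY)))}

    lo, hi = spec.vertex_range
    graphs = [
        random_molecular_graph(int(graph_rng.integers(lo, hi + 1)), spec.max_degree,
                               graph_rng, spec.ring_density, id=f"mol{i+1:03d}")
        for i in range(spec.n_molecules)
    ]
    idx = indices_table(graphs)

    props = {}
    truth: Dict[str, dict] = {}
    for prop in PROPERTY_VOCABULARY:
        if prop not in spec.plant:
            continue
        index_name, slope, intercept, sd = spec.plant[prop]
        noise = (noise_rngs[prop].normal(0.0, sd, size=spec.n_molecules)
                 if sd > 0 else 0.0)
        props[prop] = slope * idx[index_name].to_numpy() + intercept + noise
        truth[prop] = {"index": index_name, "slope": slope,
                       "intercept": intercept, "noise_sd": sd}
    table = PropertyTable(pd.DataFrame(props, index=idx.index.copy()))
    return graphs, idx, table, truth


def write_panel(spec: SyntheticPanelSpec, out_dir) -> Dict[str, str]:
    """Materialize a panel as edge-list TSV, indices CSV, properties CSV and
    a ground-truth JSON; returns the written paths."""
    from .molgraph import write_edge_list

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graphs, idx, table, truth = synthetic_qspr_panel(spec)
    paths = {
        "edge_list": str(out / "graphs.tsv"),
        "indices": str(out / "indices.csv"),
        "properties": str(out / "properties.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_edge_list(graphs, paths["edge_list"])
    idx.to_csv(paths["indices"])
    table.df.to_csv(paths["properties"])
    Path(paths["ground_truth"]).write_text(json.dumps(truth, indent=2) + "\n")
    return paths
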