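"""Hydrogen-suppressed molecular graphs and degree-pair edge partitions.

A molecule is modelled as a simple, finite, connected, undirected graph:
heavy (non-hydrogen) atoms are vertices and bonds are edges.  Bond order,
aromaticity, charge and isotope labels are deliberately ignored — every
bonded heavy-atom pair contributes exactly one edge.  All degree-based
topological indices downstream are sums over edges of a kernel of the two
endpoint degrees, so the only summary a graph needs to expose is its
*edge partition*: the tally of edges keyed by the unordered pair of
endpoint degrees ``(a, b)`` with ``a <= b``.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "SmilesParseError",
    "DisconnectedInputError",
    "EdgeListFormatError",
    "graph_from_smiles",
    "graph_from_edge_list",
    "read_smiles_file",
    "edge_partition",
]

DegreePair = Tuple[int, int]


class SmilesParseError(ValueError):
    """SMILES string could not be parsed into a molecule."""


class DisconnectedInputError(ValueError):
    """Input molecule has more than one fragment and largest-fragment mode is off."""


class EdgeListFormatError(ValueError):
    """Malformed, duplicated or self-looping row in an edge-list file."""


@dataclass(frozen=True)
class MolecularGraph:
    """Simple connected undirected graph of heavy atoms.

    Parameters
    ----------
    id : str
        Label for the molecule (e.g. a drug name).
    vertices : frozenset of str
        Vertex identifiers.
    edges : frozenset of 2-tuples
        Unordered vertex pairs, each stored sorted.
    """

    id: str
    vertices: frozenset = field(default_factory=frozenset)
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"{self.id!r}: self-loop on vertex {u!r}")
            if u not in self.vertices or v not in self.vertices:
                raise ValueError(f"{self.id!r}: edge ({u!r}, {v!r}) has undeclared endpoint")
        if self.n_vertices > 1 and not nx.is_connected(self.to_networkx()):
            raise ValueError(f"{self.id!r}: graph is not connected")

    @classmethod
    def from_edges(cls, id: str, edges: Iterable[Tuple[str, str]],
                   isolated: Iterable[str] = ()) -> "MolecularGraph":
        """Build a graph from an edge iterable, inferring the vertex set."""
        norm = frozenset(tuple(sorted((str(u), str(v)))) for u, v in edges)
        verts = frozenset(itertools.chain(*norm)) | frozenset(str(v) for v in isolated)
        return cls(id=id, vertices=verts, edges=norm)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> Dict[str, int]:
        """Degree of every vertex (0 for isolated vertices)."""
        d = {v: 0 for v in self.vertices}
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class EdgePartition:
    """Edge counts keyed by unordered endpoint-degree pair ``(a, b)``, ``a <= b``.

    Absent pairs are omitted rather than stored as zero; every stored count
    is strictly positive and every key satisfies ``1 <= a <= b``.
    """

    counts: Mapping[DegreePair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[DegreePair, int] = {}
        for key, c in dict(self.counts).items():
            a, b = int(key[0]), int(key[1])
            if not 1 <= a <= b:
                raise ValueError(f"invalid degree pair {key!r}: need 1 <= a <= b")
            c = int(c)
            if c < 0:
                raise ValueError(f"negative count for pair {key!r}")
            if c > 0:
                clean[(a, b)] = c
        object.__setattr__(self, "counts", clean)

    @property
    def n_edges(self) -> int:
        return sum(self.counts.values())

    def items(self):
        return sorted(self.counts.items())

    def __getitem__(self, pair: DegreePair) -> int:
        a, b = pair
        return self.counts.get((min(a, b), max(a, b)), 0)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, EdgePartition):
            return dict(self.counts) == dict(other.counts)
        if isinstance(other, dict):
            return dict(self.counts) == {tuple(sorted(k)): v for k, v in other.items()}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def merge(self, other: "EdgePartition") -> "EdgePartition":
        """Key-wise sum — the partition of a disjoint union of graphs."""
        merged = Counter(self.counts)
        merged.update(other.counts)
        return EdgePartition(dict(merged))


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Tally the edges of ``g`` by sorted endpoint-degree pair.

    The counts sum to ``g.n_edges``; an edgeless graph yields an empty
    partition.
    """
    deg = g.degrees()
    tally: Counter = Counter()
    for u, v in g.edges:
        a, b = sorted((deg[u], deg[v]))
        tally[(a, b)] += 1
    return EdgePartition(dict(tally))


def graph_from_smiles(smiles: str, id: str = "", *,
                      largest_fragment: bool = False) -> MolecularGraph:
    """Parse a SMILES string into its hydrogen-suppressed skeleton.

    Heavy atoms become vertices (labelled by rdkit atom index) and every
    bonded heavy-atom pair becomes one edge regardless of bond order or
    aromaticity; explicit hydrogens are dropped.  Multi-fragment input
    (e.g. salts) raises :class:`DisconnectedInputError` unless
    ``largest_fragment`` selects the component with the most heavy atoms
    (ties broken by smallest vertex label).
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"{id or 'input'}: unparsable SMILES {smiles!r}")
    try:
        Chem.SanitizeMol(
            mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
        )
    except Exception as exc:  # rdkit raises several exception types
        raise SmilesParseError(f"{id or 'input'}: invalid SMILES {smiles!r}: {exc}") from exc
    mol = Chem.RemoveHs(mol, sanitize=False)

    edges = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((f"a{u}", f"a{v}"))
    verts = [f"a{a.GetIdx()}" for a in mol.GetAtoms()]

    g = nx.Graph()
    g.add_nodes_from(verts)
    g.add_edges_from(edges)
    if g.number_of_nodes() == 0:
        raise SmilesParseError(f"{id or 'input'}: SMILES {smiles!r} has no heavy atoms")
    components = list(nx.connected_components(g))
    if len(components) > 1:
        if not largest_fragment:
            raise DisconnectedInputError(
                f"{id or 'input'}: {len(components)} fragments; "
                "pass largest_fragment=True to keep the biggest one"
            )
        keep = max(components, key=lambda c: (len(c), min(c)))
        g = g.subgraph(keep)
    return MolecularGraph.from_edges(id or smiles, g.edges(), isolated=g.nodes())


def read_smiles_file(path) -> List[Tuple[str, str]]:
    """Read ``<id><TAB><smiles>`` records; '#' comment and blank lines skipped."""
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise EdgeListFormatError(
                f"{path}:{lineno}: expected '<id>\\t<smiles>', got {raw!r}"
            )
        records.append((parts[0].strip(), parts[1].strip()))
    return records


def graphs_from_smiles_file(path, *, largest_fragment: bool = False) -> List[MolecularGraph]:
    return [graph_from_smiles(smi, id, largest_fragment=largest_fragment)
            for id, smi in read_smiles_file(path)]


def graph_from_edge_list(path) -> List[MolecularGraph]:
    """Read a ``graph_id\\tu\\tv`` TSV into validated graphs, one per graph id.

    Row order is irrelevant.  Duplicate edges, self-loops and malformed rows
    raise :class:`EdgeListFormatError` with the offending line number.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise EdgeListFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    start = 1 if [h.strip().lower() for h in header] == ["graph_id", "u", "v"] else 0

    per_graph: Dict[str, set] = {}
    order: List[str] = []
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 3 or not all(p.strip() for p in parts):
            raise EdgeListFormatError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {raw!r}"
            )
        gid, u, v = (p.strip() for p in parts)
        if u == v:
            raise EdgeListFormatError(f"{path}:{lineno}: self-loop on vertex {u!r}")
        edge = tuple(sorted((u, v)))
        bucket = per_graph.setdefault(gid, set())
        if gid not in order:
            order.append(gid)
        if edge in bucket:
            raise EdgeListFormatError(f"{path}:{lineno}: duplicate edge {edge!r} in graph {gid!r}")
        bucket.add(edge)
    return [MolecularGraph.from_edges(gid, per_graph[gid]) for gid in order]


def write_edge_list(graphs: Iterable[MolecularGraph], path) -> None:
    """Write graphs as the ``graph_id\\tu\\tv`` TSV that ``graph_from_edge_list`` reads."""
    out = ["graph_id\tu\tv"]
    for g in graphs:
        for u, v in sorted(g.edges):
            out.append(f"{g.id}\t{u}\t{v}")
    Path(path).write_text("\n".join(out) + "\n")
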