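"""End-to-end orchestration: graphs -> indices -> entropy weights -> TOPSIS + SAW.

Every assumption triggered on the way (defaulted criterion directions,
equal-weight fallback, tie events) is emitted at warning level so the run's
audit trail is visible.  Re-running with the same configuration reproduces
all output files byte-for-byte (fixed float formatting, fixed row order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CriterionDirection, DecisionMatrix, WeightVector
from .entropy import entropy_weight_vector
from .indices import indices_table
from .molgraph import graph_from_edge_list, graphs_from_smiles_file
from .qspr import (PropertyTable, allocate_property_to_index, correlate,
                   criterion_directions_from_properties)
from .saw import SawResult, saw_rank
from .topsis import TopsisResult, topsis_rank

log = logging.getLogger("adrank")

__all__ = ["RunConfig", "RankingReport", "run_full_ranking", "compare_rankings",
           "bundled_drug_smiles"]

FLOAT_FMT = "%.6g"


def bundled_drug_smiles() -> Path:
    """Path to the versioned 12-drug SMILES fixture shipped with the package."""
    return Path(__file__).parent / "data" / "ad_drugs.smi"


@dataclass(frozen=True)
class RunConfig:
    """One full-analysis run.

    Exactly one input source (``smiles`` | ``edge_list`` | ``matrix``) and
    one weight source (entropy by default, or a weights CSV).  Directions
    come from a JSON file, from the QSPR allocation against a property
    table, or default to all-benefit.
    """

    smiles: Optional[str] = None
    edge_list: Optional[str] = None
    matrix: Optional[str] = None
    properties: Optional[str] = None
    directions: Optional[str] = None       # JSON file path
    direction_source: str = "all-benefit"  # all-benefit | file | qspr
    weights: Optional[str] = None          # weights CSV; None -> entropy
    equal_weights_fallback: bool = False
    tie_tol: float = 1e-12
    out_dir: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        sources = [s for s in (self.smiles, self.edge_list, self.matrix) if s]
        if len(sources) != 1:
            raise ValueError("exactly one input source (smiles | edge_list | matrix) required")
        if self.direction_source not in ("all-benefit", "file", "qspr"):
            raise ValueError(f"unknown direction source {self.direction_source!r}")
        if self.direction_source == "file" and not self.directions:
            raise ValueError("direction_source='file' needs a directions path")
        if self.direction_source == "qspr" and not self.properties:
            raise ValueError("direction_source='qspr' needs a properties table")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass(frozen=True)
class RankingReport:
    """Joint result of both ranking methods on one decision matrix."""

    table: pd.DataFrame           # closeness, topsis_rank, total_score, saw_rank
    weights: WeightVector
    direction: CriterionDirection
    topsis: TopsisResult
    saw: SawResult
    kendall_tau: float
    same_rank: List[str]          # alternatives ranked identically by both
    assumptions: List[str]        # logged assumption trail

    def to_markdown(self) -> str:
        lines = ["# Drug ranking report", "", "```",
                 self.table.to_string(float_format=lambda v: f"{v:.4f}"), "```", "",
                 f"Kendall tau-b (TOPSIS vs SAW): {self.kendall_tau:.4f}",
                 f"Same rank in both methods: {', '.join(self.same_rank) or '(none)'}", ""]
        if self.assumptions:
            lines += ["## Assumptions triggered", ""]
            lines += [f"- {a}" for a in self.assumptions]
        return "\n".join(lines) + "\n"


def compare_rankings(r1: Sequence[int], r2: Sequence[int],
                     labels: Optional[Sequence[str]] = None
                     ) -> Tuple[float, List[str]]:
    """Tie-aware Kendall tau-b between two rankings of the same alternatives,
    plus the labels ranked identically by both."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape:
        raise ValueError("rankings cover different alternative sets")
    if labels is None:
        labels = [str(i) for i in range(r1.size)]
    elif len(labels) != r1.size:
        raise ValueError("labels do not match ranking length")
    tau = float(stats.kendalltau(r1, r2, variant="b").statistic)
    same = [lab for lab, a, b in zip(labels, r1, r2) if a == b]
    return tau, same


def _load_matrix(cfg: RunConfig, assumptions: List[str]) -> DecisionMatrix:
    if cfg.matrix:
        return DecisionMatrix.from_csv(cfg.matrix)
    if cfg.smiles:
        graphs = graphs_from_smiles_file(cfg.smiles)
    else:
        graphs = graph_from_edge_list(cfg.edge_list)
    return DecisionMatrix.from_dataframe(indices_table(graphs))


def _resolve_direction(cfg: RunConfig, D: DecisionMatrix,
                       assumptions: List[str]) -> CriterionDirection:
    if cfg.direction_source == "file":
        return CriterionDirection.from_json(D.criteria, cfg.directions)
    if cfg.direction_source == "qspr":
        props = PropertyTable.from_csv(cfg.properties)
        corr = correlate(D.to_dataframe(), props)
        alloc = allocate_property_to_index(corr)
        assumptions.append(f"criterion directions from QSPR allocation: {alloc}")
        return criterion_directions_from_properties(alloc).aligned_to(D.criteria)
    assumptions.append("all criteria treated as benefit (no direction source given)")
    return CriterionDirection.all_benefit(D.criteria)


def run_full_ranking(cfg: RunConfig) -> RankingReport:
    """Execute indices -> entropy weights -> TOPSIS + SAW and write the report.

    Deterministic given the inputs; on failure any partial outputs in the
    output directory are removed.
    """
    assumptions: List[str] = []
    written: List[Path] = []
    try:
        D = _load_matrix(cfg, assumptions)
        direction = _resolve_direction(cfg, D, assumptions)
        if cfg.weights:
            W = WeightVector.from_csv(cfg.weights)
        else:
            W = entropy_weight_vector(D, equal_weights_fallback=cfg.equal_weights_fallback)

        top = topsis_rank(D, W, direction, cfg.tie_tol)
        saw = saw_rank(D, W, direction, tie_tol=cfg.tie_tol)
        for method, res in (("TOPSIS", top), ("SAW", saw)):
            for group in res.ties:
                tied = [res.alternatives[i] for i in group]
                msg = f"{method}: tie among {tied}"
                assumptions.append(msg)
                log.warning(msg)
        for msg in assumptions:
            log.warning(msg)

        tau, same = compare_rankings(top.ranks, saw.ranks, D.alternatives)
        table = pd.DataFrame(
            {"closeness": top.closeness, "topsis_rank": top.ranks,
             "total_score": saw.total_scores, "saw_rank": saw.ranks},
            index=pd.Index(D.alternatives, name="alternative"),
        )
        report = RankingReport(table, W, direction, top, saw, tau, same, assumptions)
        if cfg.out_dir:
            written = _write_outputs(cfg, D, report)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write_outputs(cfg: RunConfig, D: DecisionMatrix,
                   report: RankingReport) -> List[Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, float_format=FLOAT_FMT)
        written.append(p)

    save(D.to_dataframe(), "decision_matrix.csv")
    save(pd.DataFrame({"weight": report.weights.w},
                      index=pd.Index(report.weights.criteria, name="criterion")),
         "weights.csv")
    save(report.topsis.to_dataframe(), "topsis.csv")
    save(report.saw.to_dataframe(), "saw.csv")
    save(report.table, "report.csv")

    sidecar = {
        "weights": dict(zip(report.weights.criteria, map(float, report.weights.w))),
        "directions": dict(zip(report.direction.criteria, report.direction.direction)),
        "closeness": dict(zip(report.table.index, map(float, report.table["closeness"]))),
        "total_score": dict(zip(report.table.index, map(float, report.table["total_score"]))),
        "topsis_rank": dict(zip(report.table.index, map(int, report.table["topsis_rank"]))),
        "saw_rank": dict(zip(report.table.index, map(int, report.table["saw_rank"]))),
        "kendall_tau": report.kendall_tau,
        "same_rank": report.same_rank,
        "assumptions": report.assumptions,
    }
    p = out / "report.json"
    p.write_text(json.dumps(sidecar, indent=2) + "\n")
    written.append(p)
    p = out / "report.md"
    p.write_text(report.to_markdown())
    written.append(p)
    return written
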