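"""End-to-end pipeline and the consolidated run report.

``analyse`` is the library entry point: it takes a factor system and an
aggregated direct-influence matrix and runs every stage in order
(O -> N -> T -> lambda -> A -> R -> loops -> skeleton -> TS/WS ->
UP/DOWN levels -> layers), returning a :class:`RunReport` whose artifacts
all share one factor system.  ``run_pipeline`` wraps it with file input,
output writing and stage logging for the command line.

Reports serialize to JSON deterministically: given the same inputs (and
seed, for synthetic panels) two runs produce byte-identical files.  A
wall-clock timestamp is only included when explicitly supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dematel import (
    CentralityTable,
    compute_centrality,
    compute_total_influence,
    normalize_direct_matrix,
)
from .errors import PipelineError
from .factors import FactorSystem
from .hierarchy import (
    CausalSeries,
    LayerClassification,
    LevelPartition,
    Mode,
    classify_layers,
    extract_levels,
    full_causal_series,
)
from .io import read_labels_csv, read_matrix_csv, write_matrix_csv
from .matrices import DirectInfluenceMatrix, NormalizedInfluenceMatrix, TotalInfluenceMatrix
from .structure import (
    AdjacencyMatrix,
    InfluenceThreshold,
    ReachabilityStructure,
    SkeletonMatrix,
    ValuedSkeleton,
    binarize,
    build_valued_skeleton,
    compute_reachability,
    compute_skeleton,
    compute_threshold,
)

__all__ = ["PipelineConfig", "RunReport", "analyse", "run_pipeline"]

log = logging.getLogger("dematel_taism")


@dataclass(frozen=True)
class PipelineConfig:
    """File-level configuration for a pipeline run."""

    input_matrix: Path | None = None
    labels: Path | None = None
    out_dir: Path | None = None
    precision_influence: int = 3   # N, T, centrality
    precision_skeleton: int = 4    # TS / WS
    threshold_override: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.precision_influence < 0 or self.precision_skeleton < 0:
            raise PipelineError("precision must be >= 0")
        if self.threshold_override is not None and self.threshold_override <= 0:
            raise PipelineError("threshold override must be positive")


@dataclass(frozen=True)
class RunReport:
    """Every artifact of one pipeline run over a single factor system."""

    system: FactorSystem
    O: DirectInfluenceMatrix
    N: NormalizedInfluenceMatrix
    T: TotalInfluenceMatrix
    threshold: InfluenceThreshold
    A: AdjacencyMatrix
    reachability: ReachabilityStructure
    skeleton: SkeletonMatrix
    valued: ValuedSkeleton
    centrality: CentralityTable
    up: LevelPartition
    down: LevelPartition
    layers: LayerClassification
    causal_up: CausalSeries
    causal_down: CausalSeries
    config: PipelineConfig = field(default_factory=PipelineConfig)
    timestamp: str | None = None

    def to_dict(self) -> dict:
        """JSON-ready dictionary with matrices rounded at report precision."""
        p = self.config.precision_influence
        q = self.config.precision_skeleton
        codes = list(self.system.codes)

        def mat(values, dec=None):
            out = np.asarray(values, dtype=float)
            if dec is not None:
                out = np.round(out, dec)
            return [[x for x in row] for row in out.tolist()]

        d = {
            "version": __version__,
            "factors": {
                "codes": codes,
                "labels": {
                    c: {
                        "name": self.system.info(c).name,
                        "dimension": self.system.info(c).dimension,
                        "description": self.system.info(c).description,
                    }
                    for c in codes
                },
            },
            "direct_influence": mat(self.O.values),
            "normalized": mat(self.N.values, p),
            "normalization_denominator": round(self.N.denominator, 6),
            "total_influence": mat(self.T.values, p),
            "threshold": {
                "mean": self.threshold.mean,
                "sd": self.threshold.sd,
                "lambda": self.threshold.lam,
            },
            "adjacency": mat(self.A.values),
            "reachability": mat(self.reachability.R),
            "loops": [list(l) for l in self.reachability.loops],
            "skeleton": mat(self.skeleton.S_general),
            "TS": mat(self.valued.TS, q),
            "WS": mat(self.valued.WS, q),
            "centrality": {
                code: {
                    "D": round(float(self.centrality.D[i]), p),
                    "C": round(float(self.centrality.C[i]), p),
                    "M": round(float(self.centrality.M[i]), p),
                    "Rc": round(float(self.centrality.Rc[i]), p),
                }
                for i, code in enumerate(codes)
            },
            "scatter": [
                {"code": c, "centrality": round(m, p), "cause_degree": round(r, p)}
                for c, m, r in self.centrality.scatter_points()
            ],
            "levels": {
                "UP": [list(level) for level in self.up.levels],
                "DOWN": [list(level) for level in self.down.levels],
            },
            "layers": {
                "root": sorted(self.layers.root),
                "intermediate": sorted(self.layers.intermediate),
                "result": sorted(self.layers.result),
                "active": sorted(self.layers.active),
            },
            "causal_series": {
                "UP": str(self.causal_up),
                "DOWN": str(self.causal_down),
            },
            "config": {
                "precision_influence": p,
                "precision_skeleton": q,
                "threshold_override": self.config.threshold_override,
                "seed": self.config.seed,
            },
        }
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, ensure_ascii=False)


def analyse(
    system: FactorSystem,
    O: DirectInfluenceMatrix,
    *,
    threshold_override: float | None = None,
    config: PipelineConfig | None = None,
    timestamp: str | None = None,
) -> RunReport:
    """Run every pipeline stage on an aggregated direct-influence matrix."""
    if config is None:
        config = PipelineConfig(threshold_override=threshold_override)
    log.info("direct influence matrix: %d x %d", system.n, system.n)
    N = normalize_direct_matrix(O)
    log.info("normalized with denominator %.6f", N.denominator)
    T = compute_total_influence(N)
    thr = compute_threshold(T)
    lam = threshold_override if threshold_override is not None else thr.lam
    log.info("intercept lambda = %.10f (mean %.10f, sd %.10f)", lam, thr.mean, thr.sd)
    A = binarize(T, lam)
    rs = compute_reachability(A)
    log.info("loops: %s", [list(l) for l in rs.loops] or "none")
    sk = compute_skeleton(rs)
    vs = build_valued_skeleton(T, sk, rs)
    cent = compute_centrality(T)
    up = extract_levels(rs, Mode.UP)
    down = extract_levels(rs, Mode.DOWN)
    log.info("levels: UP %d, DOWN %d", len(up.levels), len(down.levels))
    layers = classify_layers(up, down)
    return RunReport(
        system=system, O=O, N=N, T=T, threshold=thr, A=A, reachability=rs,
        skeleton=sk, valued=vs, centrality=cent, up=up, down=down, layers=layers,
        causal_up=full_causal_series(up, rs),
        causal_down=full_causal_series(down, rs),
        config=config, timestamp=timestamp,
    )


def run_pipeline(config: PipelineConfig, timestamp: str | None = None) -> RunReport:
    """File-driven pipeline: read inputs, analyse, write the report bundle.

    With no ``input_matrix`` the bundled NSSI example is analysed.
    """
    if config.input_matrix is not None:
        O = read_matrix_csv(config.input_matrix)
        system = O.system
        if config.labels is not None:
            system = FactorSystem(system.codes, read_labels_csv(config.labels))
            O = DirectInfluenceMatrix(system, O.values)
    else:
        from .datasets import nssi_fixture

        system, O = nssi_fixture()

    report = analyse(
        system, O, threshold_override=config.threshold_override,
        config=config, timestamp=timestamp,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        write_matrix_csv(report.O, out / "direct_influence.csv")
        write_matrix_csv(report.N, out / "normalized.csv", config.precision_influence)
        write_matrix_csv(report.T, out / "total_influence.csv", config.precision_influence)
        write_matrix_csv(report.A, out / "adjacency.csv")
        write_matrix_csv(report.reachability, out / "reachability.csv")
        write_matrix_csv(report.valued.to_frame("TS"), out / "TS.csv", config.precision_skeleton)
        write_matrix_csv(report.valued.to_frame("WS"), out / "WS.csv", config.precision_skeleton)
        report.centrality.to_frame().round(config.precision_influence).to_csv(out / "centrality.csv")
        log.info("report written to %s", out)
    return report
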