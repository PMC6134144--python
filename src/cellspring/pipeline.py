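"""End-to-end embedding pipeline: filter -> normalize -> (optional) feature
selection -> correlation transform -> instance graph -> spring layout ->
figures + run report."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import core_io, graph as graph_mod, layout as layout_mod, preprocess, viz
from .core_io import ClassAssignment, ExpressionMatrix, InstanceGraph, LayoutResult


@dataclass
class PipelineConfig:
    """Every tunable of the embedding pipeline (defaults are sensible for a
    few hundred cells)."""

    min_class_size: int = 5
    feature_selection: bool = False
    rfe_step: int = 20
    cv_folds: int = 5
    correlation_transform: bool = True
    knn_k: int = 3
    shift_k: int = 1
    knn_horizon: int | None = None
    confidence: float = 1.0
    spring_K: float = 1.0
    kk_tol: float = 1e-4
    kk_max_iter: int | None = None
    random_state: int = 0


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    classes: ClassAssignment
    graph: InstanceGraph
    layout: LayoutResult
    report: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class _stage:
    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> None:
        return None

    def __exit__(self, exc_type, exc, tb) -> bool:
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(f"stage {self.name!r}: {exc}") from exc
        return False


def run_pipeline(
    matrix: ExpressionMatrix,
    classes: ClassAssignment,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    with _stage("class_filter"):
        matrix, classes = preprocess.filter_classes(
            matrix, classes, config.min_class_size
        )
    with _stage("umi_normalization"):
        matrix = preprocess.normalize_umi(matrix)
    rfe_info: dict | None = None
    if config.feature_selection:
        with _stage("feature_selection"):
            rfe = preprocess.rfe_select(
                matrix,
                classes,
                step=config.rfe_step,
                folds=config.cv_folds,
                seed=config.random_state,
            )
            matrix = matrix.subset_genes(rfe.selected_gene_indices)
            rfe_info = {
                "n_selected": len(rfe.selected_gene_indices),
                "best_cv_accuracy": rfe.best_accuracy,
            }
    with _stage("correlation_transform"):
        if config.correlation_transform:
            space = preprocess.correlation_transform(matrix)
        else:
            space = core_io.ProfileSpace(
                matrix.values.T, matrix.cell_ids, is_correlation=False
            )
    with _stage("graph_construction"):
        params = graph_mod.GraphParams(
            k=config.knn_k,
            k_shift=config.shift_k,
            horizon=config.knn_horizon,
            confidence=config.confidence,
        )
        instance_graph = graph_mod.build_instance_graph(space, classes, params)
        core_io.validate_graph(instance_graph)
    with _stage("layout"):
        layout = layout_mod.layout_components(
            instance_graph,
            K=config.spring_K,
            tol=config.kk_tol,
            max_iter=config.kk_max_iter,
            seed=config.random_state,
        )
    report = {
        "parameters": asdict(config),
        "n_cells": matrix.n_cells,
        "n_genes": matrix.n_genes,
        "class_sizes": classes.class_sizes,
        "rfe": rfe_info,
        "n_knn_edges": len(instance_graph.edges_of_kind("knn")),
        "n_shift_edges": len(instance_graph.edges_of_kind("shift")),
        "final_energy": layout.final_energy,
        "layout_iterations": layout.iterations,
        "layout_converged": layout.converged,
    }
    return PipelineResult(matrix, classes, instance_graph, layout, report)


def write_outputs(result: PipelineResult, outdir: str | Path,
                  figures: bool = True) -> dict[str, Path]:
    """Write graph, layout, report and (optionally) the layout figure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = list(result.graph.class_labels)
    paths = {
        "graph": core_io.write_graph(result.graph, outdir / "graph.tsv", "tsv"),
        "graphml": core_io.write_graph(
            result.graph, outdir / "graph.graphml", "graphml"
        ),
        "layout": core_io.write_layout(
            result.layout, result.graph.cell_ids, labels, outdir / "layout.tsv"
        ),
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(result.report, indent=2, sort_keys=True) + "\n")
    paths["report"] = report_path
    if figures:
        paths["figure"] = viz.render_layout(
            result.layout, result.graph, labels, outdir / "layout.png"
        )
    return paths
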