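"""Config-driven orchestration of the analysis stages.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
each stage takes either real input paths or a synthetic specification,
never both.  Every run writes a manifest recording the seed, thresholds
and package version so outputs are auditable and byte-reproducible under
a fixed (config, seed) pair.  All stage randomness is derived from one
root seed through named substreams, so a stage rerun alone reproduces its
part of a full run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .coexpression import (
    CorrelationScreenResult,
    ModuleResult,
    ScreenConfig,
    anchor_screen,
    cluster_cells,
    cluster_genes,
    gene_correlation_matrix,
    linkage_to_newick,
    nominate_surface_markers,
)
from .matrix import (
    ExpressionMatrix,
    GeneAnnotation,
    read_expression_table,
    write_expression_table,
    write_report,
)
from .pathway import ColorMapConfig, PathwayDefinition, default_pathway, pathway_reach
from .proliferation import SuppressionAssayResult, read_sample_sheet, suppression_assay
from .synthetic import (
    SyntheticConfig,
    generate_pathway_table,
    generate_single_cell_matrix,
    generate_suppression_experiment,
    write_suppression_experiment,
)

__all__ = ["RunConfig", "run_screen", "run_proliferation", "run_pathway", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    ss = np.random.SeedSequence([int(root_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """End-to-end run description.

    Exactly one of ``expression_path`` / ``synthetic`` may be set for the
    screen stage, and one of ``sample_sheet`` / ``suppression_targets``
    for the proliferation stage.
    """

    outdir: Path = Path("lymphosteroid_run")
    seed: int = 0
    # screen stage
    expression_path: Path | None = None
    annotation_path: Path | None = None
    synthetic: dict[str, Any] | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    # pathway stage
    pathway_table_path: Path | None = None
    pathway_path: Path | None = None
    colormap: ColorMapConfig = field(default_factory=ColorMapConfig)
    # proliferation stage
    sample_sheet: Path | None = None
    suppression_targets: dict[str, float] | None = None
    reference_condition: str = "responder_alone"
    replicates: int = 3
    jitter_sd: float = 0.05
    n_events: int = 5000
    peak_sigma: float = 0.15
    max_generations: int = 6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.expression_path is not None and self.synthetic is not None:
            raise ValueError(
                "config error: give either expression_path or a synthetic spec, not both"
            )
        if self.sample_sheet is not None and self.suppression_targets is not None:
            raise ValueError(
                "config error: give either sample_sheet or suppression_targets, not both"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "screen" in data and isinstance(data["screen"], Mapping):
            data["screen"] = ScreenConfig(**data["screen"])
        if "colormap" in data and isinstance(data["colormap"], Mapping):
            data["colormap"] = ColorMapConfig(**data["colormap"])
        return cls(**data)


def _write_manifest(cfg: RunConfig, stage: str, extra: dict[str, Any]) -> None:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "screen_threshold": cfg.screen.screen_threshold,
            "cell_cluster_threshold": cfg.screen.cell_cluster_threshold,
            "colormap_low": cfg.colormap.low,
            "colormap_high": cfg.colormap.high,
            "fdr_alpha": cfg.screen.fdr_alpha,
        },
    }
    manifest.update(extra)
    path = cfg.outdir / f"manifest_{stage}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n")
    logger.info(
        "stage %s: screen thresholds rho>%s / |rho|>=%s, color map %s-%s FPKM",
        stage,
        cfg.screen.screen_threshold,
        cfg.screen.cell_cluster_threshold,
        cfg.colormap.low,
        cfg.colormap.high,
    )


def _load_screen_inputs(cfg: RunConfig) -> tuple[ExpressionMatrix, GeneAnnotation]:
    if cfg.expression_path is not None:
        expr = read_expression_table(cfg.expression_path)
    else:
        spec = dict(cfg.synthetic or {})
        spec.setdefault("seed", stage_seed(cfg.seed, "screen"))
        expr, truth = generate_single_cell_matrix(SyntheticConfig(**spec))
        cfg.outdir.mkdir(parents=True, exist_ok=True)
        truth.to_json(cfg.outdir / "synthetic_truth.json")
        write_expression_table(expr, cfg.outdir / "expression.tsv")
    if cfg.annotation_path is not None:
        annotation = GeneAnnotation.from_tsv(cfg.annotation_path)
    else:
        annotation = GeneAnnotation()
    return expr, annotation


def run_screen(cfg: RunConfig) -> tuple[CorrelationScreenResult, ModuleResult, ModuleResult]:
    """Load → anchor screen → marker nomination → gene and cell clustering.

    Writes every artifact (screen TSV/JSON, marker list, correlation
    matrix, gene dendrogram in Newick, module assignments, manifest) under
    ``cfg.outdir``.  Any stage failure aborts with the stage named.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        expr, annotation = _load_screen_inputs(cfg)
        stage = "screen"
        screen_cfg = dataclasses.replace(cfg.screen, seed=stage_seed(cfg.seed, "screen_p"))
        screen = anchor_screen(expr, annotation, screen_cfg)
        write_report(screen, cfg.outdir / "screen")
        stage = "marker_nomination"
        markers = nominate_surface_markers(screen)
        write_report(
            [
                {"rank": i + 1, "gene": r.gene, "rho": r.rho, "p": r.p, "q": r.q}
                for i, r in enumerate(markers)
            ],
            cfg.outdir / "surface_markers",
        )
        stage = "gene_clustering"
        corr_genes = sorted(screen.screened_genes | {screen.anchor})
        gene_modules = ModuleResult()
        if len(corr_genes) >= 2:
            corr = gene_correlation_matrix(expr, corr_genes)
            gene_modules = cluster_genes(
                corr,
                screen.anchor,
                threshold=cfg.screen.screen_threshold,
                linkage_method=cfg.screen.linkage_method,
            )
            corr.round(10).to_csv(cfg.outdir / "correlation_matrix.tsv", sep="\t")
            (cfg.outdir / "gene_dendrogram.nwk").write_text(
                linkage_to_newick(gene_modules.gene_linkage, list(corr.index)) + "\n"
            )
        else:
            logger.warning("fewer than 2 screened genes; gene clustering skipped")
        stage = "cell_clustering"
        cell_modules = ModuleResult()
        if screen.cell_cluster_genes:
            cell_modules = cluster_cells(
                expr,
                sorted(screen.cell_cluster_genes),
                screen.anchor,
                linkage_method=cfg.screen.linkage_method,
            )
        else:
            logger.warning("empty cell-cluster gene set; cell clustering skipped")
        write_report(
            ModuleResult(
                modules=gene_modules.modules,
                anchor_module=gene_modules.anchor_module,
                cell_partition=cell_modules.cell_partition,
                anchor_cell_cluster=cell_modules.anchor_cell_cluster,
                anchor_detected_fraction_in_cluster=(
                    cell_modules.anchor_detected_fraction_in_cluster
                ),
            ),
            cfg.outdir / "modules",
        )
        _write_manifest(
            cfg,
            "screen",
            {
                "anchor": screen.anchor,
                "n_genes": expr.n_genes,
                "n_cells": expr.n_cells,
                "input": str(cfg.expression_path) if cfg.expression_path else "synthetic",
            },
        )
        return screen, gene_modules, cell_modules
    except Exception as exc:
        raise RuntimeError(f"screen pipeline failed at stage {stage!r}: {exc}") from exc


def run_pathway(cfg: RunConfig) -> Any:
    """Pathway-completeness scoring of a condition-level FPKM table."""
    stage = "load"
    try:
        pathway = (
            PathwayDefinition.from_yaml(cfg.pathway_path) if cfg.pathway_path else default_pathway()
        )
        if cfg.pathway_table_path is not None:
            expr = read_expression_table(cfg.pathway_table_path)
        else:
            expr = generate_pathway_table(seed=stage_seed(cfg.seed, "pathway"))
            cfg.outdir.mkdir(parents=True, exist_ok=True)
            write_expression_table(expr, cfg.outdir / "pathway_table.tsv")
        stage = "reach"
        result = pathway_reach(expr, pathway, cfg.colormap)
        write_report(result, cfg.outdir / "pathway_reach")
        _write_manifest(cfg, "pathway", {"pathway": pathway.name, "conditions": expr.cell_ids})
        return result
    except Exception as exc:
        raise RuntimeError(f"pathway pipeline failed at stage {stage!r}: {exc}") from exc


def run_proliferation(cfg: RunConfig) -> SuppressionAssayResult:
    """Suppression-assay quantification from events or a synthetic design."""
    stage = "load"
    try:
        if cfg.sample_sheet is not None:
            samples = read_sample_sheet(cfg.sample_sheet)
        else:
            targets = cfg.suppression_targets or {
                "responder_alone": 2.17,
                "coculture_pos": 1.17,
                "coculture_neg": 2.1,
            }
            samples, truth = generate_suppression_experiment(
                targets,
                replicates=cfg.replicates,
                jitter_sd=cfg.jitter_sd,
                sigma=cfg.peak_sigma,
                n_events=cfg.n_events,
                max_generations=cfg.max_generations,
                seed=stage_seed(cfg.seed, "proliferation"),
            )
            sheet = write_suppression_experiment(samples, cfg.outdir / "events")
            truth.to_json(cfg.outdir / "suppression_truth.json")
            logger.info("synthetic suppression events written under %s/", sheet.parent.name)
        stage = "suppression_assay"
        result = suppression_assay(
            samples,
            reference_condition=cfg.reference_condition,
            max_generations=cfg.max_generations,
        )
        write_report(result, cfg.outdir / "suppression")
        _write_manifest(
            cfg,
            "proliferation",
            {
                "reference_condition": cfg.reference_condition,
                "conditions": sorted({s.condition for s in samples}),
            },
        )
        return result
    except Exception as exc:
        raise RuntimeError(f"proliferation pipeline failed at stage {stage!r}: {exc}") from exc
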