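"""Pathway-completeness scoring of condition-level expression.

A steroidogenesis pathway is an ordered chain of metabolite steps, each
requiring one or more enzymes/transporters.  Given per-condition FPKM
values, this module maps each gene to a display intensity (white-to-red
color code) and computes how far along the chain each condition can
proceed — e.g. a Th2-like profile reaches pregnenolone while a Th1-like
profile, lacking Cyp11a1, is blocked one step earlier despite expressing
the entire cholesterol supply machinery.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .matrix import ExpressionMatrix

__all__ = [
    "PathwayStep",
    "PathwayDefinition",
    "ColorMapConfig",
    "PathwayReachResult",
    "colorize_expression",
    "pathway_reach",
    "default_pathway",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayStep:
    metabolite: str
    required_genes: frozenset[str]
    any_of: bool = False

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError(f"step {self.metabolite!r} has an empty gene set")


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered metabolite steps, each gated by a set of required genes."""

    steps: tuple[PathwayStep, ...]
    name: str = "pathway"

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a pathway needs at least one step")

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.steps:
            out |= set(s.required_genes)
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PathwayDefinition":
        steps = tuple(
            PathwayStep(
                metabolite=str(s["metabolite"]),
                required_genes=frozenset(map(str, s["required_genes"])),
                any_of=bool(s.get("any_of", False)),
            )
            for s in data.get("steps", [])
        )
        return cls(steps=steps, name=str(data.get("name", "pathway")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PathwayDefinition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_pathway() -> PathwayDefinition:
    """The bundled cholesterol → pregnenolone steroidogenesis chain."""
    ref = importlib.resources.files("lymphosteroid.data") / "steroidogenesis_pathway.yaml"
    return PathwayDefinition.from_dict(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class ColorMapConfig:
    """White-to-red FPKM color map: ≤ ``low`` is white (0), ≥ ``high`` is
    saturated red (1), linear in between.  ``low`` doubles as the detection
    threshold for pathway completeness."""

    low: float = 3.0
    high: float = 15.0

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError("require 0 <= low < high")


def colorize_expression(value: float, cfg: ColorMapConfig = ColorMapConfig()) -> float:
    """Map one FPKM value to a display intensity in [0, 1]."""
    value = float(value)
    if value < 0:
        raise ValueError(f"negative FPKM value: {value}")
    if value <= cfg.low:
        return 0.0
    if value >= cfg.high:
        return 1.0
    return (value - cfg.low) / (cfg.high - cfg.low)


@dataclass
class ConditionReach:
    intensity: dict[str, float]
    detected: dict[str, bool]
    reach: str
    blocked_at: set[str]


@dataclass
class PathwayReachResult:
    """Per-condition pathway intensities, detection calls, and reach."""

    pathway: str
    conditions: dict[str, ConditionReach] = field(default_factory=dict)

    def reach(self, condition: str) -> str:
        return self.conditions[condition].reach

    def blocked_at(self, condition: str) -> set[str]:
        return self.conditions[condition].blocked_at

    def to_records(self) -> list[dict[str, Any]]:
        out = []
        for cond, r in self.conditions.items():
            for gene in sorted(r.intensity):
                out.append(
                    {
                        "condition": cond,
                        "gene": gene,
                        "intensity": r.intensity[gene],
                        "detected": r.detected[gene],
                        "reach": r.reach,
                        "blocked_at": ";".join(sorted(r.blocked_at)),
                    }
                )
        return out

    def to_summary(self) -> dict[str, Any]:
        return {
            "pathway": self.pathway,
            "reach": {c: r.reach for c, r in self.conditions.items()},
        }


def pathway_reach(
    expr: ExpressionMatrix,
    pathway: PathwayDefinition | None = None,
    cfg: ColorMapConfig = ColorMapConfig(),
) -> PathwayReachResult:
    """Score each condition's progress along the pathway.

    A gene is detected iff its FPKM exceeds ``cfg.low``; a step is satisfied
    if all its required genes are detected (or at least one, when
    ``any_of``).  A condition's ``reach`` is the metabolite of the last step
    in the unbroken satisfied prefix, or ``"none"`` if the first step
    already fails; ``blocked_at`` lists the undetected required genes of the
    first unsatisfied step (empty iff the full chain is satisfied).

    Pathway genes missing from the matrix are treated as undetected with a
    logged warning.  Conditions are scored independently.
    """
    if pathway is None:
        pathway = default_pathway()
    gene_lookup = {g.lower(): g for g in expr.gene_ids}
    missing = [g for g in sorted(pathway.genes) if g.lower() not in gene_lookup]
    if missing:
        logger.warning(
            "pathway genes absent from expression matrix, treated as undetected: %s",
            ", ".join(missing),
        )

    result = PathwayReachResult(pathway=pathway.name)
    for j, cond in enumerate(expr.cell_ids):
        intensity: dict[str, float] = {}
        detected: dict[str, bool] = {}
        for gene in sorted(pathway.genes):
            key = gene.lower()
            if key in gene_lookup:
                val = float(expr.values[expr.gene_ids.index(gene_lookup[key]), j])
            else:
                val = 0.0
            intensity[gene] = colorize_expression(val, cfg)
            detected[gene] = val > cfg.low
        reach = "none"
        blocked: set[str] = set()
        for step in pathway.steps:
            hits = [detected[g] for g in sorted(step.required_genes)]
            ok = any(hits) if step.any_of else all(hits)
            if not ok:
                blocked = {g for g in step.required_genes if not detected[g]}
                break
            reach = step.metabolite
        result.conditions[cond] = ConditionReach(
            intensity=intensity, detected=detected, reach=reach, blocked_at=blocked
        )
    return result
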