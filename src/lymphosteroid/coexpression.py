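"""Marker-anchored co-expression screen and clustering.

Every gene's single-cell expression profile is rank-correlated (Spearman)
against a fixed anchor gene — by default Cyp11a1, the cholesterol
side-chain cleavage enzyme marking steroidogenic cells.  Genes above a
correlation threshold form the screened set; surface receptors among them
are ranked as candidate sorting markers.  Hierarchical clustering of the
gene-gene correlation matrix extracts the anchor's co-expression module,
and clustering cells on the strongly (positively or negatively)
anchor-correlated genes isolates the anchor-expressing subpopulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, GeneAnnotation

__all__ = [
    "ScreenConfig",
    "ScreenRecord",
    "CorrelationScreenResult",
    "ModuleResult",
    "ConstantInputError",
    "spearman_rho",
    "anchor_screen",
    "nominate_surface_markers",
    "gene_correlation_matrix",
    "cluster_genes",
    "cluster_cells",
    "linkage_to_newick",
]

logger = logging.getLogger(__name__)


class ConstantInputError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the anchor-correlation screen.

    ``screen_threshold`` is the positive-ρ cutoff defining anchor-correlated
    genes; ``cell_cluster_threshold`` is the two-sided cutoff (ρ above it or
    at/below its negation) selecting genes for cell clustering.  Strict
    inequality is used at the screen threshold.
    """

    anchor_gene: str = "Cyp11a1"
    screen_threshold: float = 0.3
    cell_cluster_threshold: float = 0.35
    min_detected_cells: int = 3
    p_method: str = "asymptotic"
    n_permutations: int = 999
    seed: int = 0
    fdr_alpha: float = 0.05
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        if not (0 < self.screen_threshold < 1 and 0 < self.cell_cluster_threshold < 1):
            raise ValueError("correlation thresholds must lie in (0, 1)")
        if self.min_detected_cells < 3:
            raise ValueError("min_detected_cells must be >= 3")
        if self.p_method not in {"asymptotic", "permutation"}:
            raise ValueError("p_method must be 'asymptotic' or 'permutation'")
        if self.p_method == "permutation" and self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.linkage_method not in {"average", "complete", "single"}:
            raise ValueError("linkage_method must be one of average/complete/single")


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    p_method: str = "asymptotic",
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation of two vectors with a p value.

    ρ is the Pearson correlation of mid-ranked (average-tie) values.  The p
    value is either the asymptotic t approximation or a permutation p
    (proportion of label permutations with |ρ| at least as large, with the
    +1 continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    rho = float(rho)
    if p_method == "permutation":
        if rng is None:
            rng = np.random.default_rng(0)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ry)
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    return rho, float(p)


@dataclass
class ScreenRecord:
    gene: str
    rho: float
    p: float
    q: float
    category: str
    n_cells_used: int
    passes_screen: bool


@dataclass
class CorrelationScreenResult:
    """Per-gene anchor correlations plus the selected gene sets."""

    anchor: str
    records: list[ScreenRecord]
    screened_genes: set[str]
    cell_cluster_genes: set[str]
    excluded_genes: list[dict[str, str]]
    config: ScreenConfig

    def record(self, gene: str) -> ScreenRecord:
        for r in self.records:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    def to_records(self) -> list[dict[str, Any]]:
        return [
            {
                "gene": r.gene,
                "rho": r.rho,
                "p": r.p,
                "q": r.q,
                "category": r.category,
                "n_cells_used": r.n_cells_used,
                "passes_screen": r.passes_screen,
            }
            for r in self.records
        ]

    def to_summary(self) -> dict[str, Any]:
        return {
            "anchor": self.anchor,
            "n_screened": len(self.screened_genes),
            "n_cell_cluster_genes": len(self.cell_cluster_genes),
            "n_excluded": len(self.excluded_genes),
            "excluded": self.excluded_genes,
        }


def anchor_screen(
    expr: ExpressionMatrix, annotation: GeneAnnotation, cfg: ScreenConfig = ScreenConfig()
) -> CorrelationScreenResult:
    """Correlate every gene against the anchor across single cells.

    Genes that are constant or detected (value > 0) in fewer than
    ``cfg.min_detected_cells`` cells are excluded with a recorded reason.
    Cells where the anchor itself is undetected are retained: their zeros
    carry rank information, and dropping them would bias ρ upward.
    q values are Benjamini–Hochberg across all tested genes.
    """
    anchor_matches = [g for g in expr.gene_ids if g.lower() == cfg.anchor_gene.lower()]
    if not anchor_matches:
        raise ValueError(f"anchor gene {cfg.anchor_gene!r} not present in the matrix")
    anchor = anchor_matches[0]
    a = expr.gene_values(anchor)
    if np.ptp(a) == 0:
        raise ValueError(f"anchor gene {anchor!r} is constant across cells")
    if int((a > 0).sum()) < cfg.min_detected_cells:
        raise ValueError(
            f"anchor gene {anchor!r} detected in fewer than {cfg.min_detected_cells} cells"
        )

    rng = np.random.default_rng(cfg.seed)
    rows: list[tuple[str, float, float, int]] = []
    excluded: list[dict[str, str]] = []
    for gene in expr.gene_ids:
        if gene == anchor:
            continue
        v = expr.gene_values(gene)
        if np.ptp(v) == 0:
            excluded.append({"gene": gene, "reason": "constant"})
            continue
        if int((v > 0).sum()) < cfg.min_detected_cells:
            excluded.append({"gene": gene, "reason": "too_few_detected_cells"})
            continue
        rho, p = spearman_rho(
            v, a, p_method=cfg.p_method, n_permutations=cfg.n_permutations, rng=rng
        )
        rows.append((gene, rho, p, v.size))

    if rows:
        _, qvals, _, _ = multipletests([r[2] for r in rows], method="fdr_bh")
    else:
        qvals = np.array([])
    records = [
        ScreenRecord(
            gene=g,
            rho=rho,
            p=p,
            q=float(q),
            category=annotation.category(g),
            n_cells_used=n,
            passes_screen=rho > cfg.screen_threshold,
        )
        for (g, rho, p, n), q in zip(rows, qvals)
    ]
    records.sort(key=lambda r: (-r.rho, r.gene))
    hi = cfg.cell_cluster_threshold
    return CorrelationScreenResult(
        anchor=anchor,
        records=records,
        screened_genes={r.gene for r in records if r.passes_screen},
        cell_cluster_genes={r.gene for r in records if r.rho > hi or r.rho <= -hi},
        excluded_genes=excluded,
        config=cfg,
    )


def nominate_surface_markers(result: CorrelationScreenResult) -> list[ScreenRecord]:
    """Rank surface-receptor genes by anchor correlation, best first.

    These are the candidate antibody targets for sorting the
    anchor-expressing cells.  Ordering inherits the global (ρ descending,
    gene symbol) tie rule; an empty list is valid.
    """
    return [r for r in result.records if r.category == "surface_receptor"]


def gene_correlation_matrix(
    expr: ExpressionMatrix, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """All-pairs Spearman correlation matrix over the given genes.

    Constant genes are dropped with a warning; at least two usable genes
    are required.  The result is symmetric with a unit diagonal.
    """
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    sub = expr.subset_genes(genes)
    usable = [g for g in sub.gene_ids if np.ptp(sub.gene_values(g)) > 0]
    dropped = sorted(set(sub.gene_ids) - set(usable))
    if dropped:
        logger.warning("dropping constant genes from correlation matrix: %s", ", ".join(dropped))
    if len(usable) < 2:
        raise ValueError("need at least 2 non-constant genes for a correlation matrix")
    vals = np.vstack([sub.gene_values(g) for g in usable])
    ranks = scipy.stats.rankdata(vals, axis=1)
    corr = np.corrcoef(ranks)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2
    return pd.DataFrame(corr, index=usable, columns=usable)


@dataclass
class ModuleResult:
    """Output of gene- or cell-side hierarchical clustering."""

    gene_linkage: np.ndarray | None = None
    modules: dict[str, int] = field(default_factory=dict)
    anchor_module: set[str] = field(default_factory=set)
    cell_partition: dict[str, int] = field(default_factory=dict)
    anchor_cell_cluster: int | None = None
    anchor_detected_fraction_in_cluster: float | None = None
    correlation_matrix: pd.DataFrame | None = None

    def to_records(self) -> list[dict[str, Any]]:
        recs = [
            {"kind": "gene", "id": g, "cluster": c, "in_anchor_module": g in self.anchor_module}
            for g, c in sorted(self.modules.items())
        ]
        recs += [
            {
                "kind": "cell",
                "id": c,
                "cluster": k,
                "in_anchor_module": k == self.anchor_cell_cluster,
            }
            for c, k in sorted(self.cell_partition.items())
        ]
        return recs

    def to_summary(self) -> dict[str, Any]:
        return {
            "anchor_module": sorted(self.anchor_module),
            "anchor_cell_cluster": self.anchor_cell_cluster,
            "anchor_detected_fraction_in_cluster": self.anchor_detected_fraction_in_cluster,
        }


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = sch.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"


def cluster_genes(
    corr: pd.DataFrame,
    anchor: str,
    threshold: float = 0.3,
    linkage_method: str = "average",
) -> ModuleResult:
    """Agglomerate genes on correlation distance and extract the anchor module.

    Distance is d = 1 − ρ with average linkage by default.  Modules are the
    partition obtained by cutting the dendrogram at distance 1 − threshold,
    i.e. clusters whose merge history stays at mean within-module ρ above
    the screen threshold; the anchor module is the member containing the
    anchor.
    """
    if anchor not in corr.index:
        raise ValueError(f"anchor gene {anchor!r} not in correlation matrix")
    if corr.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    if not np.allclose(corr.values, corr.values.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    dist = np.clip(1.0 - corr.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = ssd.squareform(dist, checks=False)
    linkage = sch.linkage(condensed, method=linkage_method)
    flat = sch.fcluster(linkage, t=1.0 - threshold, criterion="distance")
    genes = list(corr.index)
    modules = {g: int(c) for g, c in zip(genes, flat)}
    anchor_cluster = modules[anchor]
    return ModuleResult(
        gene_linkage=linkage,
        modules=modules,
        anchor_module={g for g, c in modules.items() if c == anchor_cluster},
        correlation_matrix=corr,
    )


def cluster_cells(
    expr: ExpressionMatrix,
    genes: Iterable[str],
    anchor: str,
    k: int | None = None,
    linkage_method: str = "average",
) -> ModuleResult:
    """Cluster cells on rank-standardized expression of a gene set.

    Each gene is mid-ranked across cells and scaled to [0, 1] so genes
    contribute on a common, outlier-robust scale.  Cells are agglomerated
    (Euclidean, average linkage); if ``k`` is not given it is chosen to
    maximize the silhouette over k in 2..6.  The anchor cell cluster is the
    cluster with the highest mean anchor expression, and the fraction of
    anchor-detected (anchor > 0) cells falling inside it is reported.
    """
    genes = list(genes)
    if not genes:
        raise ValueError(
            "empty gene set for cell clustering; relax the cell_cluster_threshold"
        )
    if expr.n_cells < 4:
        raise ValueError("need at least 4 cells to cluster")
    sub = expr.subset_genes(genes)
    ranks = scipy.stats.rankdata(sub.values, axis=1)
    n = expr.n_cells
    profile = ((ranks - 1) / (n - 1)).T  # cells x genes in [0, 1]
    linkage = sch.linkage(profile, method=linkage_method, metric="euclidean")

    if k is None:
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            labels = sch.fcluster(linkage, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(profile, labels)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    labels = sch.fcluster(linkage, t=k, criterion="maxclust")

    a = expr.gene_values(anchor)
    cluster_ids = np.unique(labels)
    means = {int(c): float(a[labels == c].mean()) for c in cluster_ids}
    anchor_cluster = max(means, key=lambda c: (means[c], -c))
    detected = a > 0
    frac = (
        float((detected & (labels == anchor_cluster)).sum() / detected.sum())
        if detected.any()
        else 0.0
    )
    return ModuleResult(
        cell_partition={cid: int(c) for cid, c in zip(expr.cell_ids, labels)},
        anchor_cell_cluster=int(anchor_cluster),
        anchor_detected_fraction_in_cluster=frac,
    )
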