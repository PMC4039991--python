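"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study design the
pipeline targets: a small single-cell cohort (default 91 cells split into
a fourth-generation cytokine-positive gate and a second-generation
negative gate) carrying an anchor-correlated gene module expressed in a
steroidogenic subpopulation; archetypal naive/Th1/Th2 pathway expression
profiles; log-normal dye-dilution fluorescence with generation peaks at
halving intervals; and replicated suppression-assay experiments with
target division indices.  All generators are pure functions of their
configuration plus a seed, and planted truth is returned separately from
the analysis-facing data so it can never leak into the pipeline inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats

from .matrix import ExpressionMatrix
from .pathway import ColorMapConfig, PathwayDefinition, default_pathway
from .proliferation import FluorescenceEvents, division_index_batch

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_single_cell_matrix",
    "generate_pathway_table",
    "generate_dye_dilution",
    "generate_suppression_experiment",
    "write_suppression_experiment",
    "latent_pearson_for_spearman",
    "di_targeted_proportions",
]


def latent_pearson_for_spearman(rho_s: float) -> float:
    """Latent Gaussian Pearson correlation giving Spearman ρ after any
    monotone marginal transform: r = 2·sin(π·ρ_S / 6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults for the single-cell generator.

    ``n_cells`` and ``gate_split`` default to the 91-cell cohort (52
    fourth-generation reporter-positive, 39 second-generation negative)
    the screen was designed around.  ``module_rho`` is the target Spearman
    correlation of each module gene with the anchor; ``subpop_shift`` is
    the latent-mean increase (in latent SD units) of anchor and module
    genes inside the steroidogenic subpopulation — the default 3.5 makes
    the on- and off-state latent distributions nearly disjoint, modeling a
    discrete on/off expression program.  ``dropout_rate`` is the excess-zero
    probability at the reference mean expression.
    """

    n_cells: int = 91
    gate_split: tuple[int, int] = (52, 39)
    subpop_fraction: float = 0.3
    module_genes: int = 10
    module_rho: float = 0.5
    background_genes: int = 500
    dropout_rate: float = 0.3
    subpop_shift: float = 3.5
    marginal: Mapping[str, float] = field(
        default_factory=lambda: {"p_zero": 0.3, "mu": 1.5, "sigma": 1.0}
    )
    anchor_gene: str = "Cyp11a1"
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.gate_split) != self.n_cells:
            raise ValueError("gate_split must sum to n_cells")
        if not (0 <= self.module_rho < 1):
            raise ValueError("module_rho must lie in [0, 1)")
        if not (0 < self.subpop_fraction < 1):
            raise ValueError("subpop_fraction must lie in (0, 1)")
        if min(self.n_cells, self.module_genes, self.background_genes) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth, aligned one-to-one with emitted identifiers."""

    module_genes: list[str] = field(default_factory=list)
    background_genes: list[str] = field(default_factory=list)
    subpopulation: dict[str, bool] = field(default_factory=dict)
    generations: np.ndarray | None = None
    condition_effects: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload: dict[str, Any] = {
            "module_genes": self.module_genes,
            "background_genes": self.background_genes,
            "subpopulation": self.subpopulation,
            "condition_effects": self.condition_effects,
        }
        if self.generations is not None:
            payload["generations"] = [int(g) for g in self.generations]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _zi_lognormal_quantile(u: np.ndarray, p_zero: float, mu: float, sigma: float) -> np.ndarray:
    """Quantile function of a zero-inflated log-normal marginal."""
    out = np.zeros_like(u)
    pos = u > p_zero
    v = (u[pos] - p_zero) / (1.0 - p_zero)
    v = np.clip(v, 1e-12, 1 - 1e-12)
    out[pos] = np.exp(mu + sigma * scipy.stats.norm.ppf(v))
    return out


def generate_single_cell_matrix(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a single-cell matrix with a planted anchor-correlated module.

    Anchor and module genes share an equicorrelated latent Gaussian copula
    block whose off-diagonal Pearson correlation is chosen via
    r = 2·sin(π·ρ_S/6) so pairwise Spearman correlations hit
    ``cfg.module_rho`` after the (monotone) marginal transform.  Cells in
    the π-fraction subpopulation additionally receive a latent mean shift
    on the block genes.  Latent quantiles are mapped to a zero-inflated
    log-normal marginal; dropout then adds excess zeros with probability
    logistic in the gene's mean expression.  Background genes are
    independent noise.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.module_genes + 1  # anchor + module
    r = latent_pearson_for_spearman(cfg.module_rho)
    if r >= 1.0 or r <= -1.0 / (k - 1):
        raise ValueError(
            f"module_rho={cfg.module_rho} gives latent r={r:.3f}, outside the "
            f"positive-definite range for a {k}-gene equicorrelated block"
        )

    n = cfg.n_cells
    subpop = np.zeros(n, dtype=bool)
    n_pos = max(1, round(cfg.subpop_fraction * n))
    subpop[rng.choice(n, size=n_pos, replace=False)] = True

    # equicorrelated latent block via a shared factor
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((k, n))
    latent_block = np.sqrt(max(r, 0.0)) * factor[None, :] + np.sqrt(1.0 - max(r, 0.0)) * noise
    latent_block = latent_block + cfg.subpop_shift * subpop[None, :].astype(float)

    latent_bg = rng.standard_normal((cfg.background_genes, n))
    latent = np.vstack([latent_block, latent_bg])

    # per-gene quantile map through the zero-inflated log-normal marginal;
    # the shift is applied before the probability transform so shifted
    # cells land in the upper marginal quantiles
    m = cfg.marginal
    u = scipy.stats.norm.cdf(latent)
    expr = np.vstack(
        [
            _zi_lognormal_quantile(u[i], m["p_zero"], m["mu"], m["sigma"])
            for i in range(latent.shape[0])
        ]
    )

    # excess-zero dropout, logistic in gene mean around the marginal mu
    if cfg.dropout_rate > 0:
        gene_mean = np.log1p(expr).mean(axis=1)
        ref = float(np.median(gene_mean))
        logit0 = np.log(cfg.dropout_rate / (1 - cfg.dropout_rate))
        p_drop = scipy.special.expit(logit0 - 1.0 * (gene_mean - ref))
        drop = rng.random(expr.shape) < p_drop[:, None]
        expr = np.where(drop, 0.0, expr)

    gene_ids = (
        [cfg.anchor_gene]
        + [f"MOD{i + 1:03d}" for i in range(cfg.module_genes)]
        + [f"BG{i + 1:04d}" for i in range(cfg.background_genes)]
    )
    cell_ids = [f"cell{i + 1:03d}" for i in range(n)]

    # gate labels: subpopulation cells preferentially occupy the
    # later-generation positive gate, mirroring the sort design
    n_g4p = cfg.gate_split[0]
    order = np.argsort(~subpop, kind="stable")  # subpop cells first
    gate = np.empty(n, dtype=object)
    gate[order[:n_g4p]] = "G4P"
    gate[order[n_g4p:]] = "G2N"
    cell_meta = {c: {"gate_label": str(g)} for c, g in zip(cell_ids, gate)}

    matrix = ExpressionMatrix(gene_ids, cell_ids, expr, cell_meta)
    truth = SyntheticTruth(
        module_genes=gene_ids[1 : cfg.module_genes + 1],
        background_genes=gene_ids[cfg.module_genes + 1 :],
        subpopulation={c: bool(s) for c, s in zip(cell_ids, subpop)},
    )
    return matrix, truth


DEFAULT_ARCHETYPES: dict[str, dict[str, float]] = {
    # per-metabolite-step FPKM levels; "high" is well above the saturated
    # color threshold, "low" below the white threshold
    "naive": {},
    "Th1": {
        "cholesterol": 20.0,
        "outer-membrane cholesterol": 20.0,
        "matrix cholesterol": 20.0,
    },
    "Th2": {
        "cholesterol": 20.0,
        "outer-membrane cholesterol": 20.0,
        "matrix cholesterol": 20.0,
        "pregnenolone": 20.0,
    },
}
_BASAL_FPKM = 1.0


def generate_pathway_table(
    archetypes: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    pathway: PathwayDefinition | None = None,
) -> ExpressionMatrix:
    """Condition × pathway-gene FPKM table from archetypal profiles.

    Each archetype maps metabolite steps to an FPKM level applied to every
    gene of that step; unlisted steps sit at a basal 1 FPKM (below the
    white/detection threshold).  The defaults encode: naive — the whole
    pathway shut down; Th1 — cholesterol supply and mitochondrial import
    expressed but the side-chain cleavage step silent; Th2 — everything
    through pregnenolone expressed, downstream enzymes silent.  Gaussian
    noise (truncated at 0) is added when ``noise_sd > 0``.
    """
    if pathway is None:
        pathway = default_pathway()
    if archetypes is None:
        archetypes = DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)
    conditions = list(archetypes)
    genes = sorted(pathway.genes)
    step_of = {g: s.metabolite for s in pathway.steps for g in s.required_genes}
    values = np.empty((len(genes), len(conditions)))
    for j, cond in enumerate(conditions):
        spec = archetypes[cond]
        for lvl in spec.values():
            if lvl < 0:
                raise ValueError("archetype levels must be non-negative")
        for i, g in enumerate(genes):
            values[i, j] = float(spec.get(step_of[g], _BASAL_FPKM))
    if noise_sd > 0:
        values = np.maximum(0.0, values + rng.normal(0.0, noise_sd, values.shape))
    return ExpressionMatrix(genes, conditions, values)


def generate_dye_dilution(
    proportions: Sequence[float],
    g0_center: float = 12.0,
    sigma: float = 0.15,
    n_events: int = 5000,
    seed: int = 0,
    condition: str = "",
    replicate: str = "",
) -> tuple[FluorescenceEvents, SyntheticTruth]:
    """Simulate dye-dilution fluorescence events.

    Each event's generation is drawn from ``proportions``; its fluorescence
    is ``2^(g0_center − generation + N(0, sigma))`` — log-normal peaks at
    exact halving intervals.
    """
    proportions = np.asarray(proportions, dtype=float)
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("generation proportions must sum to 1")
    if (proportions < 0).any():
        raise ValueError("proportions must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    gens = rng.choice(proportions.size, size=n_events, p=proportions)
    values = np.exp2(g0_center - gens + rng.normal(0.0, sigma, n_events))
    events = FluorescenceEvents(values=values, condition=condition, replicate=replicate)
    truth = SyntheticTruth(generations=gens)
    return events, truth


def di_targeted_proportions(target_di: float, max_generations: int = 6) -> np.ndarray:
    """Generation proportions whose division index equals ``target_di``.

    Uses a one-parameter geometric tilt in precursor space: precursor
    fractions q_i ∝ t^i give DI(t) = Σ i·t^i / Σ t^i, continuous and
    strictly increasing from 0 (t→0) to max_generations (t→∞); t is solved
    numerically.  Cell fractions follow as p_i ∝ q_i·2^i.
    """
    G = max_generations
    if target_di < 0 or target_di >= G:
        raise ValueError(f"target DI {target_di} unreachable with {G} generations")
    i = np.arange(G + 1, dtype=float)
    if target_di == 0:
        q = np.zeros(G + 1)
        q[0] = 1.0
    else:
        def di_of(log_t: float) -> float:
            w = np.exp(i * log_t - np.max(i * log_t))
            return float((i * w).sum() / w.sum())

        log_t = scipy.optimize.brentq(lambda lt: di_of(lt) - target_di, -40.0, 40.0, xtol=1e-12)
        q = np.exp(i * log_t - np.max(i * log_t))
        q /= q.sum()
    p = q * np.exp2(i)
    return p / p.sum()


def generate_suppression_experiment(
    di_by_condition: Mapping[str, float],
    replicates: int = 3,
    jitter_sd: float = 0.05,
    g0_center: float = 12.0,
    sigma: float = 0.15,
    n_events: int = 5000,
    max_generations: int = 6,
    seed: int = 0,
) -> tuple[list[FluorescenceEvents], SyntheticTruth]:
    """Simulate a replicated suppression assay.

    For each condition and replicate, the target division index is
    jittered (Normal, truncated at 0), converted to a generation
    distribution by :func:`di_targeted_proportions`, and rendered as
    fluorescence events.  Truth records each replicate's realized target.
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    for cond, di in di_by_condition.items():
        if di < 0:
            raise ValueError(f"target DI for {cond!r} must be non-negative")
    root = np.random.default_rng(seed)
    samples: list[FluorescenceEvents] = []
    effects: dict[str, float] = {}
    for cond in di_by_condition:
        for rep in range(1, replicates + 1):
            sub = np.random.default_rng(root.integers(0, 2**31 - 1))
            target = max(0.0, di_by_condition[cond] + sub.normal(0.0, jitter_sd))
            props = di_targeted_proportions(target, max_generations)
            ev, _ = generate_dye_dilution(
                props,
                g0_center=g0_center,
                sigma=sigma,
                n_events=n_events,
                seed=int(sub.integers(0, 2**31 - 1)),
                condition=cond,
                replicate=f"r{rep}",
            )
            samples.append(ev)
            effects[f"{cond}/r{rep}"] = float(target)
    truth = SyntheticTruth(condition_effects=effects)
    return samples, truth


def write_suppression_experiment(
    samples: Sequence[FluorescenceEvents], outdir: str | Path
) -> Path:
    """Write per-sample single-column event files plus a sample sheet TSV.

    Returns the sample-sheet path; files round-trip through the
    proliferation readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        fname = f"events_{s.condition}_{s.replicate}.txt"
        np.savetxt(outdir / fname, s.values, fmt="%.6f")
        rows.append((fname, s.condition, s.replicate))
    sheet = outdir / "sample_sheet.tsv"
    with open(sheet, "w") as fh:
        fh.write("file\tcondition\treplicate\n")
        for fname, cond, rep in rows:
            fh.write(f"{fname}\t{cond}\t{rep}\n")
    return sheet
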