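# Methods

This note records the statistical model behind each analysis stage, the
default parameters and why they hold those values, the numerical
choices, and the known limitations. Defaults encode the biological
regime the package was designed for (mouse Th2 cultures profiled by
single-cell RNA-seq/qPCR and dye-dilution flow cytometry); they are all
overridable.

## 1. Input handling and Ct normalization

Expression matrices are dense genes × cells arrays with validated,
unique identifiers; values must be finite and non-negative. Dense TSV/CSV
(either orientation) and MatrixMarket sparse triplets are supported.
Error messages name the offending row/column so malformed files can be
fixed without reading a stack trace.

Single-cell qPCR reports a cycle threshold (Ct) per gene and cell, with
undetected reactions encoded as NaN. Normalized expression is

```
e = max(0, LOD − Ct),  default LOD = 28 cycles
```

i.e. cycles-above-the-limit-of-detection, so `e` is linear in
log2(template abundance) and undetected wells map to 0. Ct values above
the LOD are clipped to 0 with a warning rather than rejected: they occur
in real plates and carry no quantitative information.

## 2. Anchor-correlation screen

Each gene is tested against the anchor (*Cyp11a1*) with Spearman's ρ —
Pearson correlation of tie-averaged ranks — because single-cell
expression is zero-inflated and non-Gaussian, and only monotone
association is biologically claimed. p values are asymptotic by default;
an exact-style permutation option (`p_method="permutation"`, add-one
corrected) exists for small n. Benjamini–Hochberg q values control the
FDR across the whole screen.

Thresholds:

* `screen_threshold = 0.3` — genes with ρ > 0.3 constitute the screen's
  hit list and the gene-module clustering set.
* `cell_cluster_threshold = 0.35` — genes with ρ > 0.35 **or**
  ρ ≤ −0.35 form the gene set used for cell clustering, so
  anti-correlated program genes also inform the partition.
* `min_detected_cells = 3` — genes detected in fewer cells are excluded
  (reported with an exclusion reason) since their ranks are
  uninformative.

Genes are ranked by descending ρ; surface-marker nomination simply
filters the ranked list to the `surface_receptor` annotation category.

**Gene modules.** Average-linkage hierarchical clustering on the
distance 1 − ρ between screened genes, cutting the dendrogram at
distance 1 − `screen_threshold`; the anchor module is the cluster
containing the anchor. (A literal "smallest cluster whose internal mean
ρ exceeds the threshold" is degenerate — a singleton always qualifies —
so the cut-height formulation is used; it reproduces the intended
behaviour on planted-block examples.)

**Cell clusters.** Cells are represented by their rank-standardized
(per-gene ranks mapped to [0, 1]) profiles over the ±0.35 gene set,
clustered with Euclidean average linkage; the number of clusters is
chosen by maximal silhouette over k = 2..6. The anchor cell cluster is
the one with the highest mean anchor expression.

## 3. Pathway-completeness scoring

The steroidogenesis pathway is an ordered list of metabolite steps, each
carrying the gene set needed to produce it (`any_of` steps need one
member). The default definition covers cholesterol synthesis/uptake,
outer- and inner-membrane cholesterol transport, pregnenolone synthesis
(*Cyp11a1*), and downstream steroid conversion (*Cyp17a1*, *Hsd3b1*).

FPKM values pass through the color scale used for pathway heatmaps:

```
intensity(v) = clip((v − low) / (high − low), 0, 1),  low = 3, high = 15 FPKM
```

A gene counts as detected when its value exceeds `low`. A condition's
**reach** is the last metabolite of the unbroken prefix of satisfied
steps; `blocked_at` lists the missing genes of the first unsatisfied
step. Genes absent from the table are treated as undetected, with a
logged warning, so partial tables degrade predictably.

## 4. Generation deconvolution and the suppression assay

Dye dilution halves a covalent dye per division, so log2 fluorescence
forms peaks at `g0 − i` for generation *i*. The deconvolution model is a
1-D Gaussian mixture with **means fixed** on that lattice, one shared
free σ, and free weights, fitted by EM; fixing the means is what makes
the fit identifiable at realistic peak overlap. Details:

* `g0` (undivided-peak position) is auto-detected as the brightest KDE
  mode when not given. The KDE kernel width is fixed at 0.12 log2 units:
  automatic (Scott) bandwidth scales with the full dye-dilution spread
  and merges generation peaks spaced 1 unit apart, which erases the
  small undivided peak of a highly divided sample.
* EM initialization starts σ at min(data SD, 0.25) with weights from
  nearest-mean counts. A broad-σ start (wider than the peak spacing)
  leaves responsibilities near-uniform and can trap EM in a
  single-broad-blob local optimum.
* Convergence is declared at a per-event log-likelihood change below
  1e-8 (the total log-likelihood scales with event count, so an absolute
  threshold would never trigger at large n).
* Events dimmer than the last modeled peak by more than half a division
  (autofluorescence floor) are outside the model; they are counted into
  the last generation with a warning.
* A hard nearest-peak assignment mode exists for QC; exact midpoints tie
  to the lower (less divided) generation.

**Division index.** With generation counts `n_i`, precursors are
`n_i · 2^{-i}` and

```
DI = Σ i · n_i · 2^{-i} / Σ n_i · 2^{-i}
```

the mean number of divisions per starting cell. **Percent suppression**
of a condition relative to the reference is `100 · (1 − DI_cond /
DI_ref)`. Replicate DIs are compared with an unpaired two-tailed t test
(classic equal-variance form by default, matching standard practice for
triplicate suppression assays; `welch=True` drops that assumption).
Within one assay the undivided-peak position is estimated once, as the
brightest mode found in any sample: dye loading is shared across wells,
and the undivided peak can be nearly absent from highly divided samples.

## 5. Synthetic data generator

The generator exists so every recovery claim can be tested against known
truth; its defaults mirror the experimental regime the analyses target.

**Single-cell matrix.** A Gaussian copula: the anchor and the module
genes share an equicorrelated latent factor with Pearson
r = 2·sin(π·ρ_S/6), the exact inversion giving target Spearman ρ_S
(default 0.5) after any monotone marginal transform. Latent normals map
through a zero-inflated log-normal quantile function (p_zero = 0.3,
log-mean 1.5, log-sd 1.0 — a caricature of single-cell RNA-seq counts),
then logistic-in-mean dropout at rate 0.3. Default scale is 91 cells
split 52/39 across two sorting gates (fourth-generation cytokine⁺ /
second-generation cytokine⁻), with 500 background genes. A planted
subpopulation (default fraction 0.3) receives a latent mean shift of
3.5 SD on the module genes before the marginal transform; 3.5 makes the
on- and off-state latent distributions nearly disjoint, i.e. a discrete
on/off expression program rather than a graded shift, which is what a
separable anchor⁺ subpopulation means. Truth (module membership,
subpopulation labels) is returned separately and never written into the
emitted expression table.

**Pathway tables.** Archetypal profiles — naive (basal 1 FPKM
everywhere), Th1 (pathway expressed up to, but not including,
*Cyp11a1*), Th2 (expressed through *Cyp11a1*, not downstream) — at
20 FPKM for "on" genes, optionally with truncated Gaussian noise.

**Dye-dilution events.** `2^(g0 − generation + N(0, σ))` with σ = 0.15
and g0 = 12 by default (typical CellTrace-style peak width and
position). `di_targeted_proportions` solves a one-parameter geometric
tilt in precursor space (Brent root-finding) for a generation
distribution whose DI equals an arbitrary target exactly, which lets the
suppression-experiment generator target DI pairs such as 2.17 vs 1.17
and lets tests compare against analytic suppression values. Replicate
jitter (SD 0.05) perturbs the target DI per replicate.

## 6. Determinism and reporting

All randomness flows from a single root seed through named substreams
(`stage_seed`, CRC-32 of the stage name fed into `SeedSequence`), so a
stage rerun alone reproduces its slice of a full run and a full rerun is
byte-identical — logs carry no timestamps, and floats are written at 10
significant digits through a single reporting path that emits twin
JSON/TSV files. Manifests record the package version, seed, and every
threshold in force.

## Limitations

* The copula generator models one equicorrelated module plus independent
  background genes; it does not simulate multiple interacting modules,
  library-size variation, or batch effects.
* Auto-detection of the undivided peak assumes the brightest KDE mode is
  generation 0; a sample with essentially zero undivided cells *and* no
  companion sample in the assay can defeat it — pass `g0_center`
  explicitly in that case.
* The mixture model fixes peak spacing at exactly one log2 unit; dyes
  with measurable label transfer or quenching would need a free-spacing
  extension.
* Asymptotic Spearman p values are approximate below ~10 cells; use the
  permutation option there.
* Pathway scoring is transcript-level: it asserts enzyme expression, not
  flux, and treats the detection threshold (3 FPKM) as sharp.
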