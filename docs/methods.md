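# Methods

This note records the models, parameter choices and numerical conventions
behind `hippolink`, and what the synthetic-data tests do and do not
establish about real data.

## Differential-expression model

Counts are modelled as negative binomial, NB(μ_gj, α_g), with
Var = μ + αμ² (α = 0 is the Poisson limit). For a contrast
(factor, A, B) the per-gene model is a log-link GLM

log μ_gj = log s_j + x_jᵀ β_g,

with offsets log s_j from **median-of-ratios size factors** (reference =
per-gene geometric mean over genes positive in every sample; a documented
`allow_pseudo_reference` fallback exists for sparse matrices). The design
contains an intercept, the A-vs-B indicator and treatment-coded covariates
(the pipeline adjusts for `stage`). Fitting is iteratively reweighted least
squares, vectorised across genes (batched 2×2/3×3 solves), weights
w = μ/(1 + αμ), coefficients clipped at |β| ≤ 15 on the natural-log scale so
genes expressed in only one group get a large-but-finite fold change with a
large standard error. Two-sided Wald p-values use the normal reference;
genes with all-zero counts get NaN p and are excluded from the BH
denominator. `significant` means BH-adjusted p < 0.05.

**Dispersion** is method-of-moments within replicate groups on normalized
counts, α̂ = max(0, (s² − m̄)/m̄²), pooled across groups by residual degrees
of freedom, then shrunk 50/50 toward a trend α(μ) = a₀ + a₁/μ fitted by
least squares across genes. With no replicated group anywhere the engine
falls back to a constant α = 0.1 with a warning — a deliberate, visible
degradation rather than a silent one. Fold-change shrinkage, Cook's
filtering and independent filtering of reference NB engines are
intentionally not replicated; a cross-check test confirms that fold-change
estimates correlate > 0.98 with an independent NB engine on strong planted
effects and that strong calls overlap > 90%.

Two known behaviours worth stating. (i) At 3 + 3 replicates raw Wald
p-values are mildly anti-conservative (~6–7% below 0.05 under the null);
after BH the false-positive *fraction* on an all-null matrix is far below
0.05, which is the property the pipeline relies on. (ii) Median-of-ratios
normalization carries a small composition bias when DE is one-sided: with
15% of genes planted up 4-fold, recovered log2FC centres near 1.84 rather
than 2.0. This is shared with the standard implementations of this
normalization and is why the recovery requirement is ±0.3 on the mean.

## Variance-stabilising transform and PCA

The VST used for PCA and outlier screening is log2(count/s_j + 1) — a
monotone, variance-stabilising surrogate chosen for transparency; it is not
the fitted-dispersion VST of reference engines. PCA runs on per-gene
centred, unscaled VST values (the standard expression-PCA convention);
variance fractions are computed over all components and sum to 1 within
1e-9; component signs are fixed by forcing each component's
largest-magnitude loading positive, making score tables reproducible across
BLAS builds. Factor attribution is the one-way ANOVA R² (between-group SS /
total SS) of a metadata factor on each component's scores.

## Outlier-control screening

The study removed one control library with anomalously low marker
expression by inspection; here the decision is an explicit rule. Marker
expression is size-factor normalized and log2(x+1)-transformed — on the log
scale a multiplicative suppression is additive and NB noise is roughly
homoscedastic, so a 10× suppression sits ~10 robust SDs out — and a control
is flagged when it deviates from the median of its peer controls (same cell
type, all stages) by more than k = 3 scaled MADs (1.4826·MAD). Strata with
fewer than 3 controls are skipped with a warning. With 9 peers the MAD
itself is noisy, so the screen has a per-library false-flag rate of a few
percent; it is a screen, not a test, and flagged libraries are simply
excluded from DE.

## Concordance algebra and reported percentages

Two DE results over the same gene universe are partitioned into shared-up,
shared-down, opposite (significant in both, discordant sign) and the two
exclusives; the five sets are disjoint and cover the significant union by
construction. `shared_fraction` = 100·|shared| / |sig_A ∪ sig_B|; genes
significant in both directions count as shared by default (they are DE
under both conditions) with a flag to exclude them — both conventions round
to the same integer on the study's germ-line counts. Reported percentages
round half-away-from-zero to the printed precision (integer for shared
fractions, one decimal for up/down excess = 100·(n_up − n_down)/n_down).

## Enrichment

One-sided hypergeometric tail P(X ≥ k) with population = the declared
universe, re-implemented over `scipy.stats.hypergeom` rather than wrapped
from an annotation framework. Filters follow the published settings:
sets with < 30 genes (within the universe) are dropped before testing and
before BH; GO-style collections are called at BH padj < 0.01, KEGG-style at
0.05. The separate q-value of the original toolchain is collapsed to BH
only (q-value estimation is estimator-dependent); term-hierarchy
propagation is out of scope — collections are flat term → gene tables.

## Peak annotation

All internal coordinates are 0-based half-open; GTF is converted at the
parser and nowhere else. The promoter window is interpreted symmetrically:
[TSS − 1500, TSS + 1500 + 1), i.e. 3,001 bases including the TSS base,
because "the 1,500 bp flanking the TSS" does not disambiguate upstream-only
from symmetric; an `upstream` mode ([TSS−flank, TSS+1) on +, mirrored on −)
is provided. A peak is in a promoter iff it shares ≥ 1 base with ≥ 1 window
(no minimum-overlap fraction); multi-window peaks go to the overlapped gene
with the TSS nearest the peak midpoint, ties to the lexicographically
smaller gene ID. Nearest-gene mapping (|midpoint − TSS|, same tie rule) is
available as an explicit fallback, but the putative-target definition is
promoter containment. Intersection statistics count membership multiplicity
over the union: unique (= 1), common-to-all (= n_sets), common-to-≥2.

## Regulatory network

Edges are typed: `tfgene` (directed, regulator → target) and `ppi`
(undirected, stored once as a canonical sorted pair and expanded to two
arcs at traversal time). Duplicate (source, target, type) triples are
dropped with a count; a tfgene and a ppi edge between the same pair coexist
(distinct semantics) but any path uses each step once. Self-loops are kept
in the edge set, flagged, and ignored during search. Shortest-path search
is BFS on the directed expansion returning *all* shortest node sequences in
lexicographic order (capped, default 1000, truncation flagged);
unreachable → length ∞ with an empty list. Connectors are the interior
nodes of the shortest paths; "unique connector" means length exactly 2 with
a single connector. A direct src→dst edge is reported as length 1 with an
empty connector set rather than skipped.

## Synthetic-data generator

The generator's defaults encode the study conditions rather than
convenience values:

- **Design**: 48 libraries — soma 3 stages × 3 genotypes × 3 replicates
  (27), germ controls 3 × 3 (9), germ knockdowns at mid/late only 2 × 2 × 3
  (12). The composition of the 48 is not itemised in the source study; this
  map is one consistent reconstruction, and the two single-replicate
  early-germ knockdown libraries can be generated (`include_early_germ_knockdowns`,
  total 50) but are excluded from DE, as in the study.
- **Counts**: NB with gene-wise dispersion (default α = 0.05, a typical
  well-replicated bulk value), lognormal baselines scaled to an expected
  2×10⁵ counts/library over 2,000 genes (a desk-scale stand-in for a fly
  transcriptome), lognormal library size factors (σ = 0.15).
- **Planted structure**: ~30% of genes carry a cell-type effect
  (N(0, 2) log2 units — the dominant axis, emulating the observed
  cell-type-dominated PC1); 15% carry a stage-linear effect in soma only;
  250 germ-concordant genes at |log2FC| = 2 with down-biased signs (70/30),
  1 germ-opposite gene, 120 soma-exclusive genes per knockdown, 4
  soma-opposite genes — mirroring the qualitative Venn structure of the
  study (high germ concordance with a single opposite gene; mostly
  exclusive soma response with four opposite genes).
- **Markers**: genes named `hpo`, `yki`, `chinmo` with the study's
  qualitative responses (hpo self-knockdown −4.1; yki self-knockdown −1.5
  and −0.8 under germ *hpo* RNAi; chinmo unaffected), floored at a robust
  baseline (0.2% of library size) because the pathway genes are reliably
  detected in real libraries; markers carry no latent cell-type/stage
  effects so the outlier screen sees a clean peer group.
- **Outlier**: one mid-stage germ control has its `yki` expectation
  multiplied by 0.1.
- **Peaks**: per-peak Bernoulli(promoter_fraction) placement into or
  strictly outside TSS ± flank windows, so the realised fraction is exactly
  binomial; pipeline datasets plant 0.72/0.70/0.74, inside the observed
  69–75% range.
- **Network**: random TF→gene and PPI edges around the planted motif
  ppi(hpo–chinmo), tfgene(chinmo→yki), tfgene(chinmo→hpo),
  tfgene(yki→chinmo); post-generation validation removes and redraws any
  random edge creating a direct hpo–yki connection or a second ≤2-step
  route, with a bounded retry budget.

What the generator does **not** emulate: fragment-level and GC biases, gene
length effects, raw reads, batch structure, correlated gene modules, a
second genome assembly (no liftOver), or realistic GO/KEGG topology.
Passing tests therefore demonstrate that the implementations recover what
was planted under an NB world with independent genes — they do not certify
performance on real accession data, whose headline counts are explicitly
out of scope.

## Numerical conventions and problem sizes

IRLS: ≤ 50 iterations, convergence at max |Δβ| < 1e-8, ridge 1e-8 on the
normal equations; Wald p from the normal tail. BH: step-up with NaNs
excluded from m, capped at 1. Rounding of reported percentages:
half-away-from-zero. Tie-breaks are lexicographic everywhere (nearest-gene
assignment, path ordering) so outputs are order- and platform-stable.
Simulation sizes used by the tests and the acceptance script — 2,000 genes
× 48 libraries, 3v3 contrasts, 2,000 peaks, ~350-node networks, 200-graph
oracle sweeps — were chosen as the smallest sizes at which the planted
effects are comfortably identifiable; the full suite runs in well under a
minute on one CPU.

## Design choices made where the design was open

- The per-figure stratification of the study's DE contrasts (per-stage vs
  pooled) is not asserted anywhere; the engine supports both (`--stratify`,
  covariate adjustment) and the pipeline pools stages with a stage
  covariate.
- The soma exclusive percentages printed in the source (75%/55%/20%) cannot
  be reconstructed exactly from the printed marginal counts under any
  single denominator convention, so they are not computed or asserted;
  the shared-fraction and excess statistics, which do reconcile, are.
- The real DroID-scale network sizes are internally inconsistent in the
  source text and are not modelled; the network module is size-agnostic.
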