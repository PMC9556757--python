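# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `coexmap`.

## Study design and data model

The unit of analysis is an `ExpressionStudy`: a log-scale expression matrix
(genes × samples), a sample design (animal, sex, brain region, treatment),
and a per-animal trait table. The design assumed throughout is
animal-matched multi-region sampling: each animal contributes one sample
per region, so cross-region questions can be asked at the animal level.
Expression is consumed already log-normalized; `log2_cpm` provides a
log2(CPM + 0.5) helper for integer counts. Gene identifiers are opaque
strings — no annotation database is consulted. The trait schema declares
which traits count as "memory" traits (defaults: D1 and D2 discrimination
indexes and novel-object exploration time) versus "social" (social
preference, percent); the grouping is configurable because it is a
scientific choice, not a formal one.

## Differential expression

Each gene is fit by OLS against either `~ treatment` or
`~ sex + treatment + sex:treatment` (coding VEH=0/THC=1, F=0/M=1).
Residual variances are moderated by the standard empirical-Bayes scheme:
writing e_g = log s²_g − ψ(d/2) + log(d/2), the prior degrees of freedom d₀
solve ψ′(d₀/2) = var(e) − ψ′(d/2) (Newton inversion of the trigamma
function; d₀ = ∞ when the excess variance is non-positive) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). Moderated t uses the posterior
variance with d₀ + d degrees of freedom. BH FDR is computed by an explicit
step-up (cross-checked in the tests against statsmodels). A gene is a DEG
when FDR < α (strict) **and** |logFC| ≥ lfc_min (defaults 0.05 and 0.4,
read literally from the calling rule the pipeline implements); logFC is on
the log2 scale. Under the null the moderated p-values are uniform
(KS-checked at 2000 genes, n = 12, ten seeds in the suite).

This OLS + moderation stack is the package's own choice of DE engine; it
does not model count-level dispersion (no NB GLM) or batch structure.

## Coexpression modules

Unsigned adjacency |r|^β by default (signed-hybrid optional; negative
correlations zeroed before powering). β is the smallest power whose
scale-free fit R² (signed regression of log₁₀ p(k) on log₁₀ k over 10
equal-width degree bins) reaches 0.8; when no power reaches the target —
typical for data without within-module hub structure — selection falls
back to the conventional default (6 unsigned, 12 signed-hybrid) with a
warning, because chasing the maximal-R² power drifts to the top of the
range and washes out topological-overlap contrast.

TOM is computed densely; clustering is average linkage on 1 − TOM. The cut
is static and parameter-free by default: intra-module merges populate the
low heights, noise attachment and module-module merges the high ones, and
the cut is placed at the midpoint of the largest gap in the upper half of
the merge-height distribution. A quantile cut and a fixed-height cut
remain available. Clusters below `min_module_size` (default 30, the usual
convention) become "grey". Eigengenes are the first PC of the
sample-standardized member genes, unit-norm, sign-oriented to correlate
positively with the module mean; modules whose eigengene dissimilarity
1 − r falls below `merge_height` (default 0.25) are merged iteratively,
closest pair first. Labels are assigned from a fixed color palette by
decreasing size, with numbered fallbacks after palette exhaustion, making
partitions byte-reproducible.

The static gap cut is a deliberate simplification of the dynamic hybrid
tree cut: on planted-block benchmarks it recovers modules at ARI ≥ 0.8 in
over 90% of runs across loadings 0.7–0.9 and noise SD 0.2–0.4, and sends
essentially all genes to grey on structure-free data. It does not attempt
nested-module resolution, which dynamic cutting can provide.

## Module taxonomy and cross-region map

Eigengene–variable correlations are Pearson (point-biserial against the
treatment dummy), with p from t = r√((n−2)/(1−r²)). P-values are
deliberately uncorrected: the taxonomy reports nominal p < 0.05, and an
optional BH layer exists but is off by default. A module is
*treatment-correlated* at p(treatment) < α; *cognitive* if additionally
some memory trait has p < α; *social-correlated* analogously. Cross-region
edges correlate eigengenes joined on animal id within one sex, pooling
both treatment arms (n = 12 in the default design); `partial_treatment`
residualizes the treatment dummy out of both eigengenes first as a
sensitivity mode. An edge qualifies at |r| > 0.5 (strict) and p < 0.05
(strict); a module is *interconnected* when it has a qualifying edge to a
treatment-correlated module. Connectivity tallies count qualifying edges
per region pair split by correlation sign.

## RRHO

Signatures are −log₁₀(p)·sign(logFC) with p floored at 1e-300. The
stratified construction splits each signature by sign first, ranks each
quadrant list by |score| (gene id as tie-break), and scores each grid cell
by the hypergeometric tail of the top-set overlap over the common-gene
universe, signed positive for enrichment and negative for depletion, in
log space. The grid step defaults to max(1, n_common/100); resolution is a
presentation choice and does not affect the per-cell statistic.

## GWAS integration

Marker dependency filtering greedily keeps the lowest-p marker and
discards markers with r² > 0.5 to it, with lexicographic tie-breaks, so
output is independent of input order. Markers map to every gene whose span
± 50 kb (default) contains them. MSEA uses top-p quantile cutoffs
{10,…,50}% of the pruned markers: Q = Σᵢ (Oᵢ − Eᵢ)/√(Eᵢ + 1), where Oᵢ is
the module's marker count below the i-th quantile and Eᵢ the uniform
expectation. Significance comes from size-matched random gene sets drawn
from the mapped universe (gene-label permutation preserves per-gene marker
multiplicity), with add-one smoothing, BH across modules, and an
association call at FDR < 0.05 — a declared default. The locus filter for
gene-level association labels is strict p < 0.001. The multi-cutoff
statistic and the κ = 1 stabilizer follow the established marker-set
enrichment formulation; module overlap percentages are
100·|associated ∩ reference|/|associated|.

## Key-driver analysis

Candidates are nodes with ≥ 5 genes in their depth-1 directed
out-neighborhood (regulator → target semantics; undirected optional).
Each candidate's overlap with the module is scored by the hypergeometric
tail over the node universe excluding the candidate, BH across candidates,
drivers called at FDR < 0.05. This plain hypergeometric neighborhood test
was chosen over weighted multi-layer variants because it is exactly
testable by enumeration; it ignores edge weights and multi-step influence
beyond the chosen depth.

## Synthetic-data generator

Expression follows a Gaussian latent-factor model on the log scale:
x_gs = λ_g f_m(a(s)) + ε, ε ~ N(0, σ²), with one factor per planted module
per animal, f ~ N(0, 1), shifted by δ for treated animals. The unit
factor variance is the scale convention: treatment effects δ and trait
couplings β are in factor-SD units. λ_g is constant per module by default;
an optional per-gene range λ_g = λ·U(lo, hi) creates within-module hub
structure (and is what makes a scale-free fit attainable — a
constant-loading block model cannot look scale-free). Cross-region
couplings set f_B = w·f_A + √(1−w²)·η at the animal level, which is what
makes cross-region eigengene correlation meaningful. Traits are
t(a) = Σ_m β_m f_m(a) + τ·THC(a) + N(0, 1). GWAS markers live in
exchangeable LD blocks (constant r² within, 0 between); planted-signal
markers draw p = U^(1+γ) (γ = 0 is uniform; γ = 6, the default, puts the
median planted p near 0.01). The directed network grows by preferential
attachment over a shuffled node order (so module genes are not the
high-degree core by construction), then each planted hub gains direct
edges to 90% of its module. Every generator consumes an independent
substream of the config seed and is bit-reproducible. An optional NB layer
(mean exp(x), dispersion 0.1) produces counts for the normalization
helper.

What the generator does **not** emulate: real expression distributions,
mean–variance coupling, batch effects, realistic LD maps, or biologically
structured networks. Passing benchmarks therefore demonstrates correctness
and calibration of the machinery, not performance on real tissue.

## Benchmark problem sizes

The benchmark sweeps (in `coexmap.benchmarks`) use 80–200 genes, modules
of 20–50 genes, 12–24 samples, 600–800 markers and 150-node networks, with
100 Monte-Carlo seeds per rate — sizes at which every run takes well under
a second and full sweeps finish in minutes on one CPU while leaving the
per-run statistics at the power regime of the emulated design.

One benchmark deserves comment: at the joint effect sizes δ = 1,
β_trait = 1.5, σ = 0.3, n = 12 animals, the *cognitive* flag (treatment
**and** memory both at p < 0.05) is recovered in roughly a third of runs,
not most of them. This is a property of the design, not a bug: with a
unit-variance animal-level factor, δ = 1 gives an expected point-biserial
correlation of 0.45 with treatment, while p < 0.05 at n = 12 requires
|r| > 0.576 (a two-sample t with d = 1 at six animals per arm has ~35%
power). Detecting such effects reliably needs either larger shifts
(δ ≈ 2 reaches near-certain flagging) or more animals.

## Pipeline

`run-all` derives one seed per stage by hashing the stage name with the
global seed (SHA-256, reduced below 2³¹), so stages are independently
reproducible and the whole output tree is byte-identical across reruns.
The YAML config is validated against the full default tree; unknown keys
are rejected with a closest-match suggestion. The manifest records the
config, its hash, the seed, and per-stage row counts and wall times.
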