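# Methods

This note records the statistical model behind each component, the
parameters that matter, and the design choices made where the procedure was
genuinely open — in the spirit of the methods documentation of packages like
statsmodels or msprime. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The SpliZ score

**Rank models.** Every splice site that appears in junctions with ≥ 2
distinct partner sites is an anchor, in both directions: donors anchor over
their acceptors and acceptors over their donors. Partners are ranked by
unsigned genomic offset |partner − anchor| (rank 1 = nearest). Distances are
unsigned and strand does not flip ranks, so "rank 1 = shortest intron" holds
on both strands and a negative score always means shorter-than-average
introns. Two distinct partners on the same side of an anchor cannot be
equidistant; if opposite-side partners ever tie, the tie breaks by ascending
coordinate (logged). Anchor rank moments μ_s and σ_s are computed once over
all reads of the dataset, each read weighted equally, using the population
(ddof = 0) standard deviation, so the residuals (r − μ_s)/σ_s have exactly
zero mean and unit variance over the anchor's reads. Anchors with a single
partner or zero rank variance are excluded (with a logged count); moments
are never computed per cell type, because the score measures deviation from
the population average.

**Score.** For a cell-gene pair, each junctional read contributes one
residual at its donor anchor and one at its acceptor anchor, whenever each
end has a model. The score is Σz/√N over the N collected residuals. The √N
scaling is the simplest choice that gives the score unit variance under
independent read sampling, matching the approximately-N(0,1) null the
downstream tests assume; residual dependence between the two ends of a read
and between reads of one cell (biological usage variability) inflates the
variance mildly, which the null-calibration tolerances absorb. A score is
reported only for pairs with ≥ `min_reads` (default 5) spliced reads.

**Dot-plot summary.** `weighted_average_rank` reports, per cell and anchor,
the read-count-weighted mean partner rank in [1, K] — the quantity shown in
dot/box summaries and quantile-binned trajectory plots.

## SpliZVD and SpliZsites

The residual matrix of a gene has one row per cell with computable SpliZ
and one column per modeled anchor (ascending coordinate; (position, role)
pairs). The entry is the cell's **mean** read residual at the anchor — means
rather than sums bound entries independently of depth — and 0 where the cell
has no reads there, zero being the population-mean residual. Columns are
mean-centered before decomposition. The per-cell SpliZVD is the projection
of the row onto the first right singular vector; the vector's sign is fixed
so its largest-|loading| component is positive, for reproducibility across
linear-algebra backends. SpliZsites are the ≤ 3 columns with the largest
|loading|, ties broken by ascending coordinate. For a single-anchor gene
with equal per-cell depth, SpliZVD is an affine function of SpliZ (the
suite asserts this).

**Annotation status.** A site is at an annotated exon boundary when its
coordinate exactly equals an exon start or end (1-based closed intervals).
It is annotated as alternatively spliced when that boundary belongs to a
proper nonempty subset of the gene's transcripts **or** pairs with more than
one annotated partner boundary across transcripts — the weakest operational
rule consistent with the category. Region classification takes precedence
CDS > 5′UTR/3′UTR (exonic, outside the CDS span, sided by strand) >
non-coding (exonic in a transcript without CDS, or intronic) > intergenic
(gene absent or outside every transcript span).

## Differential splicing

Cells group either by cell type (tissue + compartment + annotated type) or
by compartment (pooled across tissues). Groups need ≥ 10 computable cells;
genes need ≥ 2 eligible groups.

**Screen.** The phrase "distribution of medians as a null" is
operationalized as the asymptotic law of the median of n iid N(0,1)
variables, N(0, π/(2n)). Each eligible group gets a two-sided p; the gene
screen statistic is the Šidák combination 1 − (1 − p_min)^G. This analytic
screen is cheap and only has to be accurate near 0.05.

**Permutation.** Genes passing the 0.05 screen get a label-permutation
p-value: group labels are permuted across the gene's computable cells (in
eligible groups, so group sizes — and hence eligibility — are invariant),
the Šidák statistic is recomputed per permutation, and
p = (1 + #{stat ≤ observed})/(1 + B) with B = 1000 by default and adaptive
early stopping once 50 exceedances accumulate (the estimate is already
precise where it matters; the floor is 1/(B+1)). Statistics are compared
with a relative tolerance because they span many orders of magnitude. An
exhaustive-enumeration variant over all distinct label arrangements is
provided for small inputs and is checked against an independent brute-force
oracle in the suite.

**Calling.** BH correction is applied across all tested genes per run
(permutation p where computed, screen p otherwise). A gene is significant
when BH p < 0.05, the effect size (largest-magnitude eligible group median)
exceeds 0.5 (3.5 when scoring with SpliZVD, whose scale is not normalized),
and, in cell-type mode, some tissue+compartment context contains two
eligible groups whose medians differ by ≥ 0.5. In compartment mode the
extra gate is a consistency requirement: the per-tissue medians of the
extreme compartment (tissues with ≥ 10 computable cells) must all share the
pooled sign.

**Concordance.** Replicate concordance is the Pearson correlation of
matched (gene, group) medians over genes significant in both runs (error
below 3 matched pairs); the effect-size sweep repeats it over a grid of
effect cutoffs applied to BH-passing genes, reporting NaN where fewer than
3 matched pairs remain.

## Subpopulations

Under within-type homogeneity the SpliZ of one gene is approximately a
single Gaussian; hidden splicing states make a mixture fit better. For
≥ 20 values (a configurable floor; below that a variance per component
cannot be estimated sensibly), Gaussian mixtures with k = 1..5 are fit by
EM with 10 seeded restarts per k, keeping the best ICL. ICL is the
integrated complete-data likelihood approximation: log-likelihood −
½·(3k−1)·log n − assignment entropy. Component variances are floored at
10⁻⁶ × sample variance against degeneracy.

**Component-count choice.** The selected k maximizes ICL (ties to the
smaller k). A knee search proper applies only when the ICL curve is
monotone increasing — there the k with the most negative discrete second
difference is taken, falling back to the first k whose marginal gain drops
below 5% of the total gain when the increasing curve has no concave point.
(An unconditional curvature rule was tried first and rejected: on noisy
curves from ~30 cells it fires on any interior bump of an essentially
decreasing curve, splitting null genes.)

**Separation gate.** A split is accepted only when every component pair has
Bhattacharyya distance D = (μ₁−μ₂)²/(4(σ₁²+σ₂²)) + ½ln((σ₁²+σ₂²)/(2σ₁σ₂))
above 0.5, else k is decremented and refit until k = 1. Two guards make the
gate honest at droplet depth, where the score distribution is a lattice
(few distinct values per cell): (1) separation is measured with component
variances floored at 1, the read-sampling variance of a single score under
within-state homogeneity — a fitted component narrower than its own
sampling noise is measuring count quantization, not biology; (2) a
component with fewer than 3 hard-assigned cells is degenerate (its variance
sits on the regularization floor) and fails the gate outright. The cost is
insensitivity to genuinely close states (Δμ ≲ 2 score units), which at this
depth are indistinguishable from quantization anyway.

**Two-read purity test.** At a two-partner anchor, let p̂ be the pooled
fraction of reads to the designated (default: majority) partner. Among
cells with exactly two reads at the anchor, the probability that *all* are
pure under independent Binomial(2, p̂) sampling is (1 − 2p̂(1−p̂))ⁿ.
Observed purity far in excess of this indicates per-cell splicing states
rather than stochastic binary inclusion.

## Trajectories

Genes with computable SpliZ in ≥ 100 pseudotime-bearing cells are screened
by Spearman correlation (average-rank ties; p via the t-approximation,
adequate at n ≥ 100 — an exact permutation is unnecessary above the gate).
Bonferroni correction uses the number of genes actually tested. A gene is
called when |ρ| > 0.1 and the corrected p < 0.05. Quantile summaries split
cells into Q equal-count pseudotime bins (Q ≥ 2) and report per-bin means.

## Conservation

The comparable set I contains the species-A SpliZsites whose genes have
computable SpliZ in species B (orthology via an explicit two-column symbol
map, exact matches only) and whose coordinates convert uniquely under the
supplied LiftOver table (non-unique conversions are dropped at load time, in
both directions). The null probability that site i is shared is 1/Nᵢ, with
Nᵢ the gene's number of distinct splice sites carrying junctional reads, so
the expected sharing fraction is (1/I)Σ1/Nᵢ. The observed count is referred
to the exact upper tail of Binomial(I, expected) — an approximation, since
the per-site probabilities differ; only the mean-probability binomial is
implemented, not a Poisson-binomial. The three-species enrichment test
multiplies the per-species significant-gene fractions (over genes with
computable SpliZ in ≥ 20 cells of some cell type) and evaluates
1 − CDF(x; n, p_all), i.e. the strict tail P(X > x) exactly as
conventionally printed; an inclusive P(X ≥ x) variant is available by flag
and the variant used is recorded in the output.

## Compartment classification

Cells with computable SpliZ for every panel gene and an allowed compartment
label are clustered by k-means (k = 3 by default, 10 seeded restarts);
clusters map to compartments by minimum-cost bipartite matching on the
confusion matrix (Hungarian algorithm — the exact optimum of "assign so as
to minimize classification error", and deterministic).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
cells of labelled types emit junctional reads whose partner choice follows
a per-cell multinomial usage vector, itself a Dirichlet perturbation of the
cell type's vector. Per cell and gene, total reads are negative binomial
(default mean 10, dispersion 2 — droplet-like overdispersion that exercises
the 5-read computability gate), split uniformly across the gene's anchors.
Defaults were chosen once as the study conditions: Dirichlet concentration
100 (per-cell usage standard deviation ≈ 0.05 at a balanced site — mild
within-type heterogeneity consistent with the approximately-normal null the
method assumes), two donor anchors × two partners per null gene with
per-gene base usage drawn U(0.2, 0.8), and a star topology (each acceptor
partners a single donor), so each read contributes one residual. Optional
blocks plant pseudotime drift (usage blends logistically between two
vectors, steepness 8) and hidden within-type subpopulations (a stated-
proportion mixture of two usage vectors). Every planted signal — which
genes differ across types and in which direction, which anchors vary, each
cell's hidden subpopulation, each drift's sign — is recorded in a
`PlantedTruth` object sufficient for recovery scoring without re-reading
the configuration. Infinite concentration is supported as the exact
no-noise limit.

What it does **not** emulate: base-level reads and alignment artifacts,
3′ coverage bias, unspliced reads, intron retention, ambient RNA, doublets,
or gene-gene correlation. Passing tests therefore demonstrate the
statistical machinery under the generative model the method itself assumes,
not robustness to alignment- or chemistry-level artifacts of real data.

## Problem sizes, determinism, degenerate inputs

The suite's calibration runs use 500 exchangeable genes over 4 cell types ×
50 cells (two types per tissue+compartment context, so the within-context
gate is exercised), ≈ 70,000 computable cell-gene pairs; recovery runs use
planted usage shifts of 0.4 at single-anchor genes (200 cells/group, 20
seeds), one 0.6-shifted anchor among four inert ones (2 × 100 cells, depth
15, 50 seeds), a 50/50 subpopulation at usage 0.9 vs 0.1 (240 cells), and a
logistic 0.9 → 0.1 drift over 500 cells at depth 20. These sizes give each
check comfortable statistical margin while keeping the whole suite around a
minute of CPU.

All randomness flows through `numpy.random.default_rng` seeds carried in
configs and function arguments; equal seeds give byte-identical tables and
identical fits. Degenerate inputs fail loudly: empty junction tables,
zero-partner anchors, all-zero residual matrices, fewer cells than clusters
or bins, invalid probabilities and malformed input rows all raise with the
offending gene, line or value named. Duplicate (cell, junction) rows are an
error rather than being summed, so upstream double-counting cannot pass
silently. Coordinates are 1-based everywhere and never reinterpreted.

## Known limitations

- The √N scaling treats a read's two anchor residuals and a cell's repeated
  draws as independent; the realized null variance is therefore slightly
  above 1 (the calibration run reports it).
- The screen p-value relies on the asymptotic median law; for groups near
  the 10-cell floor it is only a screen, and the permutation p supersedes it.
- Subpopulation detection is blind to states closer than about two score
  units at droplet depth (see the noise-floored gate above).
- The conservation binomial treats heterogeneous 1/Nᵢ probabilities as
  their mean.
- Orthology is exact symbol matching; naming gaps across species reduce the
  comparable set rather than being rescued.
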