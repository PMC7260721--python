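# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Preprocessing

Quantile normalization replaces each value by the across-sample mean of
the values at its rank, so all columns share one distribution.  Ties are
resolved by the midrank convention: tied entries receive the mean of the
reference values of the ranks they jointly occupy, which is deterministic
and symmetric.  The operation is idempotent, and with tie-free columns
every column's sorted vector equals the reference exactly.  Inputs are
assumed background-corrected log2 intensities (RMA-style upstream
processing); background-correction models and missing-value imputation
are out of scope and missing values are an error.

Probe collapsing drops probes with no locus match or an ambiguous
(multi-locus) match.  Several probes resolving to one locus are combined
by the per-sample arithmetic mean of their log2 values (symmetric,
order-independent); a `max_mean` alternative keeps the probe with the
highest average intensity.  Collapsing happens before differential
expression.

## Differential expression

Each study is a two-group linear contrast: log2FC = mean(treatment) −
mean(control), pooled within-group variance s²_g on d = n_t + n_c − 2 df
(pooled, not Welch — matching the linear-model framing; each group needs
≥ 2 replicates).  The empirical-Bayes layer assumes the hierarchical
model s²_g | σ²_g ~ σ²_g χ²_d / d with σ²_g ~ s₀² d₀ / χ²_{d₀}.  Writing
e_g = log s²_g − ψ(d/2) + log(d/2), moments give

    Var(e) = ψ′(d/2) + ψ′(d₀/2),
    E(e)   = log s₀² + ψ(d₀/2) − log(d₀/2),

so d₀ comes from inverting the trigamma on the excess spread (Newton
iteration) and s₀² from the mean.  When the observed spread does not
exceed the χ²-only spread the prior is a point mass: d₀ = ∞ and the
statistic is referred to the standard normal with variance pinned at the
geometric-mean-based s₀².  d₀ = 0 is accepted in the statistic layer as
the unmoderated limit (ordinary pooled t).  Genes with zero residual
variance are handled by shrinkage — the posterior variance is strictly
positive whenever s₀² is.

DEG gates follow the published thresholds: |log2FC| strictly greater
than 1 and BH FDR below 0.05, both configurable.  Two-sided calls,
since induced and suppressed genes are both of interest.

## Cross-study combination

Within a stress type, per-study two-sided p-values are combined by the
weighted inverse-normal method on directional one-sided p-values:
p_one = p_two/2 on the observed sign, z_i = sign_i · Φ⁻¹(1 − p_one,i),
z = Σ wᵢ zᵢ / √(Σ wᵢ²) with wᵢ = √nᵢ, two-sided normal tail for the
combined p.  Boundary p-values are clamped to ε = 1e-15 with a logged
warning.  p-combination was chosen over effect-size pooling as the
default because it is robust to scale differences across array
platforms; fixed-effect inverse-variance pooling of log2FCs is available
for parity.  Direction conflicts are not filtered — the signed z handles
them — and a per-gene direction-consistency score is reported.

A gene is *common nutrient-responsive* when its combined p < 0.05 in at
least two stress types.  The cut-off applies to the unadjusted combined
p (an `--adjust` flag applies BH first).  When study tables carry DEG
flags, a stress only counts for genes with fold-change-gated DEG support
in ≥ 1 of its studies.  This choice matters: without it, a gene specific
to one stress passes a second stress's 5% type-I gate with probability
1 − 0.95^(S−1) ≈ 0.10 for S = 3 stress types, which floods the common
set with stress-specific genes; re-testing the DEG lists (rather than
every measured gene) removes that leak while leaving the pure
p-combination calibration untouched for tables without flags.

## Set statistics

Overlapping coefficient |A∩B| / min(|A|, |B|) ∈ [0, 1]; undefined
(error) for empty sets.  Enrichment is the upper-tail hypergeometric
P(X ≥ |A∩B|) with population N = |universe|, successes |A|, draws |B| —
the observed count included, the standard enrichment convention.  The
universe is an explicit required argument and is always reported: a
hypergeometric tail without its N is meaningless, and published overlap
p-values are generally irreproducible precisely because N goes
unreported.  Venn partitioning enumerates all 2^k − 1 membership regions
for 2–3 sets; counts sum to |union| by construction.

## Profiles, PCA, clustering

Gene profiles are stress-type mean log2FCs.  k-means (default k = 5)
uses Lloyd's algorithm with k-means++ seeding, best of `n_init = 10`
restarts by within-cluster SS, Euclidean distance on the raw log2FC
scale (no row standardization by default — the columns already share
units; a z-score flag exists).  The implementation asserts that the
objective never increases between iterations; an emptied cluster is
re-seeded from the point farthest from its centroid.  Groups are renamed
G1..Gk by decreasing size for stable reporting.  PCA is the SVD of the
column-centered matrix; variance shares sum to 1; a constant matrix is
flagged degenerate (zero total variance) rather than an error.  Dataset
similarity is assessed by PCA of the studies × common-gene log2FC
matrix.

## Co-expression network

All gene pairs are scored by Pearson r across the assembled compendium
(all samples of all studies jointly); each p comes from the exact
transform t = r √((n−2)/(1−r²)) on n−2 df, two-sided; the whole pair
family is BH-adjusted (Bonferroni available) and edges with adjusted
p < 0.0005 are kept with the signed r as weight.  Zero-variance genes
are excluded with a warning; undirected edges are stored once (u < v).
Hubs are nodes ranked by degree, ties broken lexicographically.

## Directed TF→target network

For each target gene, an ensemble of `n_trees = 1000` regression trees
predicts the target from the candidate regulators (the TF list minus the
target itself).  Trees are grown on bootstrap samples, unlimited depth,
min 2 samples per leaf; at each split a candidate subset of size
⌈√(#regulators)⌉ is drawn *without replacement* with probability
proportional to the per-(TF, target) prior weight (Gumbel top-k
sampling), uniformly when no priors are given — so uniform priors
recover the plain ensemble-of-trees scheme and informative priors
generalize it.  Edge importance is the total variance reduction credited
to each regulator, summed over trees and normalized per target to sum
to 1.  Importance by impurity reduction, not permutation, matching the
ensemble-of-trees convention.  The tree kernel is compiled with numba;
determinism contract: identical seed and identical input row/column
ordering give bit-identical scores (per-tree streams derive from the
master seed in input order).  Thresholding keeps the top-n edges or
those above a score cut-off (exactly one selector).

## Synthetic data generator

The generator emulates a public-microarray compendium: per (stress,
study) one genes × (2 × replicates) log2 matrix; per-gene baselines
drawn once per stress and shared across its studies (cross-study
correlation); independent Gaussian noise (sd 0.25 by default) on the
log2 scale; responders per stress (20% of genes) with one sign and one
magnitude per (gene, stress) — |N(2, 0.5²)| log2 units — reused across
that stress's studies so directional combination is coherent.  A common
pool (60% of each stress's responders) responds in exactly two stress
types and *is* the ground-truth common-responsive set; remaining
responders are stress-specific and disjoint across stresses.  Two
genotype-effect sets (180 and 130 genes) are planted with fixed
intersections (20 and 40) against the pool.  Replicates default to
3 per group — a typical small-array design; the per-dataset replicate
counts of the emulated compendium are not published, so this is an
explicit configurable guess.  All randomness derives from one master
seed through per-study substreams; identical seeds give bit-identical
output.

The regulatory layer is separate: TF expression iid N(0, 1) over 60
samples; each of the 100 targets is a weighted sum of 1–3 TF parents
(weights ±Uniform(0.75, 1.25) × signal sd 1.0) plus N(0, 1) noise —
noise comparable to a single regulator's contribution, a
benchmark-like signal-to-noise ratio at which inference is informative
but not saturated.  The prior table places `prior_accuracy` (default
0.8) of each target's mass on its true parents, the rest uniform on
non-parents; accuracy 1 puts zero weight off the true edges.

What the generator does **not** emulate: probe-level intensities, batch
or platform effects, sample-to-sample distribution shifts,
count-based RNA-seq noise, correlated (hub-driven) expression in the
multi-study layer, or feedback/indirect regulation in the GRN layer.
Passing recovery tests on this data therefore demonstrates correctness
of the statistical machinery under its own assumptions, not performance
on real arrays.

One observable consequence: the simulated matrices are already on a
common scale, so the pipeline's quantile-normalization step — designed
for arrays with genuinely different distributions — can only distort.
With 20% of genes shifted by ±2 log2 units in treatment columns, forcing
identical distributions perturbs null genes near the tails, which adds a
few false calls (manifest FDR against truth ≈ 0.05–0.13 by seed, versus
≈ 0 when the combination is run on the raw simulated matrices).  This is
the well-known mixture-distortion caveat of quantile normalization under
dense differential expression, reproduced faithfully rather than hidden.

## Phenotype formulas

Wavy root index = root path length / vertical depth (≥ 1 by the input
invariant; 1 = straight root).  Growth-arrest fraction = arrested /
germinated with a Wilson 95% interval.  qRT-PCR relative expression uses
the 2^−ΔΔCt model with amplification efficiency fixed at 2 (no
efficiency parameter is exposed because none is published for the
assays being mirrored); ΔCt = Ct_target − Ct_reference per condition,
ΔΔCt = ΔCt_treatment − ΔCt_control; replicate fold changes are
summarized by the geometric mean (means are taken on the log2 scale).

## Problem sizes and tolerances

Default analysis scale: 2000 genes × 3 stresses × 4 studies × 6 samples
for the end-to-end workflow; 10,000 genes for null calibration; 20,000
variances for hyperparameter recovery; 20 TFs × 100 targets × 60 samples
× 1000 trees × 10 seeds for network recovery — sizes at which every
recovery statistic is stable while a full test run stays in the minutes
range on one CPU.  Numerical tolerances: BH and hypergeometric values
are checked to 1e-10–1e-12 against enumeration oracles; trigamma
inversion iterates to 1e-10 relative; k-means declares convergence at a
1e-10 relative objective change; boundary p-values clamp at 1e-15.

## Known limitations

- The moment estimator of (d₀, s₀²) assumes a common residual df across
  genes (true for complete two-group designs; unbalanced missingness is
  not modeled).
- Fixed-effect combination only; no random-effects model or
  heterogeneity statistics (I², Q).
- The co-expression stage computes all-pairs correlations jointly across
  the compendium; per-condition networks require subsetting by the
  caller.
- The GRN stage assumes regulators are measured in the same matrix as
  targets and scores only TF→gene edges; no time-lagged or
  bootstrap-confidence variants.
- Quantile normalization under dense differential expression is
  anticonservative (see above); with real compendia where most genes are
  null this effect is small.
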