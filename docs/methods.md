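# Methods

`vertiseq` re-implements, as a reusable and tested pipeline, the statistical
analysis of a longitudinal mother–child 16S amplicon study: vaginal swabs at
pregnancy week 24, week 36 and at birth, plus the child's feces and airway
samples at one week of age. The package's core contribution is the
weighted-ratio (WR) enrichment statistic for vertical transfer with its
permutation null; everything around it (diversity, ordination, PERMANOVA,
co-occurrence, rank tests) is the standard analysis such a study runs.

## Data model and filters

Counts are an OTU × sample integer matrix with per-sample metadata
(subject, compartment ∈ {vaginal, feces, airway}, timepoint ∈ {w24, w36,
birth, week1}); vaginal samples carry pregnancy timepoints and child samples
carry week1 — this pairing is enforced as an invariant. Samples with fewer
than 2000 reads are dropped before analysis; the boundary is strict, so a
sample with exactly 2000 reads is kept. "Presence" downstream always means
count > 0 with no relative-abundance floor. Rarefaction is a single
multivariate-hypergeometric draw per sample (subsampling without
replacement), seeded. Taxa unassigned at a rank aggregate under their
deepest assigned ancestor as `unclassified_<ancestor>`.

## Vertical transfer and the WR statistic

For one child compartment, each OTU is cross-tabulated over the n dyads as
mother presence × child presence. Only OTUs whose presence count lies
strictly between 0 and n on *both* margins are eligible; because the margins
do not change when the pairing is permuted, the eligible set is identical
across all null draws (asserted in tests). Each eligible table gets

- a sample odds ratio OR_i, with the Haldane–Anscombe +0.5 added to all four
  cells if and only if some cell is zero (so log OR is always finite);
- a two-sided Fisher exact p_i under the probability-mass ≤ observed rule,
  computed by exact integer enumeration of the fixed-margin hypergeometric
  support (rational arithmetic, so ties are counted exactly). The
  enumeration is cached per margin triple, which makes the permutation null
  a table lookup per OTU per draw.

The enrichment statistic is

    WR = Σ_{i: OR_i > 1} ln(OR_i)·ln(p_i)  /  Σ_{i: OR_i < 1} −ln(OR_i)·ln(p_i)

Natural logs are used; WR is invariant to the log base since it is a ratio
of products of two logs (asserted in a test). OTUs with OR_i = 1 enter
neither sum and p_i = 1 contributes weight 0. If the denominator is empty
or zero while the numerator is not, WR is flagged +∞ (and 0 in the mirror
case); when both sums are zero the statistic is indeterminate and reported
as NaN. Under no mother–child association the expectation of WR is 1.

The null distribution scrambles the mother→child assignment by uniform
permutation (identity allowed, not derangements), re-runs the full per-OTU
scan and recomputes WR, B = 999 times by default; the one-sided upper-tail
p is (1 + #{WR_null ≥ WR_obs}) / (B + 1), with +∞ ordered above every
finite draw.

Descriptors: Spearman correlation of mean maternal birth abundance with
ln OR; and a phylogenetic-signal test implemented as a Spearman Mantel test
between patristic distances and pairwise |Δ ln OR|, with leaf-label
permutations. The Mantel variant is this package's choice for an otherwise
under-specified "phylogenetic placement vs transfer odds" analysis, and its
R² is not expected to match any particular published value. Dyad similarity
is additionally tested as the mean matched mother–child beta distance
against the scrambled-pair null (one-sided lower tail). Odds ratios are
clipped to [0.01, 100] for volcano-plot export only — never before WR.

## Diversity, ordination, inference

Richness counts OTUs with positive counts; Shannon entropy uses natural
log; Faith's PD is rooted-inclusive (the path to the supplied root counts),
matching the common implementation of the original definition. UniFrac
(unweighted, and weighted in its normalized [0,1] variant), Faith's PD and
the Mantel test are delegated to scikit-bio; Jaccard acts on presence sets,
Bray–Curtis on counts, and Jensen–Shannon divergence uses natural log
without the square root (finite without pseudocounts).

PCoA eigendecomposes −½·J·D²·J; axes with eigenvalue ≤ 1e−10 × the largest
are dropped and proportions explained are over the positive eigenvalues.
PERMANOVA is the sequential-sums-of-squares (adonis-style) form on the
Gower-centered matrix: terms enter in call order, pseudo-F uses the
full-model residual, and p-values come from free permutation of samples —
a faithful reproduction of the standard tool's default even though the
design is repeated-measures, not an endorsement. Alpha-diversity variance
splits use sequential two-way ANOVA with subject fitted before timepoint,
mirroring "variance allocated to the individual mother"; the reverse order
is available via the `order` argument.

## Genus-level tests

The test family is the top 15 genera by mean relative abundance across all
vaginal samples (the averaging rule is this package's choice).
Kruskal–Wallis compares the three timepoints; paired Wilcoxon (within
mother, exact for n ≤ 25 after dropping zero differences, normal
approximation with continuity correction above) covers two-timepoint
contrasts; mothers missing a timepoint are dropped from that contrast, not
imputed. Benjamini–Hochberg q-values are computed within the top-15 family
only, so removing a genus outside the family leaves the others' q
unchanged. The +1e−06 pseudocount log10 transform exists purely for
display export.

## Sharing and co-occurrence

The compartment partition assigns every observed OTU to one of the seven
Venn regions (an OTU is "in" a compartment iff present in ≥ 1 of its
samples) and attributes read fractions over the grand total of reads.
SparCC is implemented from the original algorithm: per inner iteration,
fractions are drawn Dirichlet(count + 1) per sample; log-ratio variances
t_ij = var(log x_i/x_j) give basis variances by solving the linear system
under the sparsity assumption; up to 10 rounds exclude the most strongly
correlated pair (|r| > 0.1); the estimate is the elementwise median over 20
inner iterations, clipped to [−1, 1]. Constant OTUs get correlation 0 with
a warning. Per-compartment matrices combine as the pairwise maximum, and
edges are pruned at signed r > 0.2, so strong negative correlations are
excluded by design.

## Synthetic cohorts

The generator emulates the study design rather than fitting any dataset:
57 dyads by default, five samples per dyad, 300 OTUs on a random
bifurcating tree partitioned into five named monophyletic clades
(Lactobacillales, Clostridiales, Enterobacteriales, Bacteroidales,
Bacillales) with exponential branch lengths. Vaginal expected compositions
give the Lactobacillales clade a share following
expit(logit(0.8) − 0.5·t) for t = 0, 1, 2 — dominance declining toward
birth — with within-clade weights softmax of a cohort profile plus
per-subject Normal(0, 1) log offsets shared across that subject's
timepoints (the individual signature). Child communities mix the mother's
birth composition masked to the transfer-prone clades (weight π, default 0;
0.3 in the signal preset) with a compartment-specific environmental pool
fixed per cohort; the airway pool is sparser than the feces pool, echoing
the lower airway richness seen in infant data. Counts are
Dirichlet-multinomial with precision 200 (a realistic overdispersion
level; the real study specifies no count model) at lognormal depths with
median 40,000 (sd 0.35 on the log scale); the test preset lowers the
median to 2,000 so full calibration runs stay fast. All randomness flows
from one seed; identical config + seed reproduces byte-identical outputs.

What the simulator does not model: strain-level structure, read-depth
confounding with timepoint, taxonomic misclassification, or cross-dyad
household effects beyond the shared environmental pools. Passing
calibration tests therefore demonstrates correctness and calibration of
the statistics under this generative model, not the effect sizes of any
real cohort.

## Problem sizes and numerical choices

Calibration experiments run 200 replicate cohorts at the shallow-depth
preset for the null (mean observed WR, permutation-p uniformity with
B = 199) and 50 seed-paired cohorts for signal recovery; these sizes give
Monte-Carlo error comfortably inside the tolerance bands while keeping a
full run in minutes on one core. Fisher enumeration is exact rational
arithmetic; PCoA/PERMANOVA linear algebra uses standard double precision
with an eigenvalue retention tolerance of 1e−10 relative and 1e−9 absolute
checks on SS decompositions. Degenerate inputs (constant alpha values,
constant ordination axes, constant SparCC OTUs, empty scans) return flagged
or degenerate results rather than silently misleading numbers.

## Known limitations

- The WR permutation test treats dyads as exchangeable; covariates
  (delivery mode aside) are not adjusted.
- SparCC inner/exclusion defaults (20/10) follow the original algorithm;
  no parameter search is performed.
- PERMANOVA ignores the repeated-measures structure, as the reproduced
  analysis did.
- Negative-eigenvalue corrections (Lingoes/Cailliez) are out of scope; the
  affected axes are simply dropped.
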