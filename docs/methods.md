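# Methods

`daisygen` re-implements, as one tested pipeline, the population-genomic
and morphometric workflow used to assess a fragmented, clonally capable
threatened plant sampled from ~25 collection localities nested in three
strongly diverged genetic groups: reduced-representation SNP filtering,
ploidy screening from allelic read balance, kinship-based pruning,
diversity and inbreeding statistics, F<sub>ST</sub>/neighbour-joining
divergence, cluster-number selection, hierarchical AMOVA, leaf-shape
metrics, and spatially conditioned genotype–environment redundancy
analysis.  Because the workflow is exercised end to end on synthetic
data with known truth, every stage is testable as a parameter-recovery
problem.

## Synthetic data model

Genotypes come from a two-level Balding–Nichols hierarchy.  An ancestral
frequency p₀ ~ Uniform(`ancestral_maf_range`) is drawn per biallelic
locus; each group's frequency is Beta-distributed with mean p₀ and
variance p₀(1−p₀)·F<sub>groups</sub>; locality frequencies nest inside
groups the same way with F<sub>localities</sub>.  Genotypes follow the
inbreeding model P(het) = 2pq(1−F<sub>IS</sub>).  The defaults (3
groups × 8 localities × 7 diploids, 10,000 SNPs, F<sub>groups</sub> = 0.3,
F<sub>localities</sub> = 0.05, F<sub>IS</sub> = 0.15, mean depth 20×)
emulate the scale of the field study the pipeline targets.  Key
consequences used by the tests:

* expected Weir–Cockerham θ between groups equals F<sub>groups</sub>;
* the AMOVA strata have expected variance shares
  F<sub>CT</sub> : (1−F<sub>CT</sub>)F<sub>SC</sub> :
  (1−F<sub>CT</sub>)(1−F<sub>SC</sub>)F<sub>IS</sub> : remainder;
* locality Gis estimates F<sub>IS</sub>.

Missingness is injected uniformly at random (default 5%); the real
mechanism in reduced-representation data (allele dropout, coverage) is
not modelled, so tests validate estimator correctness under random
missingness only.  There is no linkage: LD pruning is exercised with
duplicated/correlated columns rather than a recombination map.  Read
depths are Poisson per genotype; at heterozygous sites the reference
fraction is drawn from the ploidy's dosage set ({1/2}, {1/3, 2/3},
{1/4, 1/2, 3/4}) and reads are Binomial; homozygous sites use a
sequencing-error rate ε = 0.01, which makes dosage histograms realistic
at the extremes.

The per-locality environment is a gradient along x plus independent
locality-level noise (`env_noise_sd`, default 0.3).  The non-spatial
component matters: a genotype–environment cline planted on a pure
function of the coordinates would be absorbed entirely by the spatial
conditioning polynomials, so the cline loci shift their frequencies (on
the logit scale, by `gea_slope` per environment unit) in response to
this full environment value.  Leaf measurements are group-specific
truncated multivariate normals with a shared ovality, so genuine group
separation lives on the size axis.

## Filtering cascade

Order: (1) genotypes with depth < 10 are masked missing, (2) sites with
MAF < 0.1 over non-missing calls are dropped, (3) sites with > 25%
missingness, (4) individuals with > 25% missingness.  Masking precedes
the MAF filter because masking changes the denominator of MAF;
computing MAF afterwards makes the cascade idempotent.  All thresholds
are strict in the direction printed above.  LD pruning slides a
50-SNP window in steps of 5; within a window the member of the
strongest r² > 0.8 pair with higher missingness (ties: larger index) is
removed until no pair exceeds the threshold — deterministic by
construction.

The negative-F filter targets excess heterozygosity (the signature of
paralogous loci stacked into one locus).  Per site F = 1 − Ho/He with
He in Nei's unbiased form (2n/(2n−1))·2p̂q̂.  The null re-pairs the 2N
observed allele copies into N genotypes at random.  Because F is
monotone in the heterozygote count at fixed allele counts, the
permutation distribution is the distribution of the het count under
random perfect matching, which has a closed-form pmf (verified against
brute-force enumeration); the test draws `negf_n_perm` samples from it.
One-tailed p = P(F_perm ≤ F_obs); sites with F < 0 and p < 0.05 are
removed.  The null is discrete, so p-values are conservative rather
than exactly uniform; tests assert ECDF(α) ≤ α + 0.02 and approximate
uniformity of the mid-p transform.

## Ploidy inference

Visual inspection of per-individual read-balance histograms is replaced
by a formal comparison: under ploidy k the per-site likelihood is an
equal-weight Binomial mixture over k's dosage set (components clamped to
[0.02, 0.98] against sequencing error), summed in log over heterozygous
sites with depth ≥ 10.  The call is the argmax hypothesis if it leads by
≥ 10 log-units; otherwise "ambiguous"; fewer than 100 usable sites
yields "no-call" rather than a guess.  On simulated data (depth ≥ 20,
≥ 500 sites) recovery exceeds 95% over 60 individuals spanning all
three ploidies.

## Kinship

The KING-robust between-individual estimator
φ̂ = (N<sub>het,het</sub> − 2N<sub>opposing hom</sub>) /
(N<sub>het</sub>(i) + N<sub>het</sub>(j)) is computed over
pairwise-complete loci via matrix products, giving exactly 0.5 for
identical genotypes and ~0.25 for first-degree pairs.  Pruning at the
conventional 0.177 cutoff (2^(−5/2), the midpoint between first- and
second-degree expectations on the log scale) removes, greedily, the
individual in the most over-threshold pairs (ties: higher missingness,
then larger index).  Negative φ̂ is retained: inbreeding depresses the
estimator (fewer shared heterozygous loci, more opposing homozygotes),
so strongly inbred localities show negative within-locality means — a
directional fact the tests assert.

## Diversity

Locality Ho and He (Nei-unbiased) are across-locus means; Gis =
1 − mean(Ho)/mean(He) (ratio of means, the G-statistics convention).
Localities with fewer than two individuals are excluded.  The Gis
permutation test reuses the allele re-pairing null jointly across loci,
two-tailed on |Gis|.

## Divergence and clustering

Pairwise F<sub>ST</sub> is Weir & Cockerham's θ: per-locus
variance components a (among populations), b (among individuals), c
(within individuals) from sample sizes, frequencies and observed
heterozygosity, with θ̂ = Σa/Σ(a+b+c); loci are dropped pairwise when a
population lacks data.  Raw (possibly negative) values are kept;
clamped values feed the NJ distance.  Neighbour joining is Saitou–Nei
with negative branch lengths clamped to zero and the deficit moved to
the sister branch, preserving the joined pair's path length; output is
validated against closed-form three-taxon solutions, tree-additive
matrices, and scikit-bio's implementation.  Cluster number is chosen by
k-means on PC scores of the mean-imputed centred dosage matrix (PCs
retained to 90% variance by default), scoring
BIC(K) = n·ln(WSS/n) + K·ln(n) over K = 1..K_max with 20 seeded
restarts; assignment probabilities come from shrinkage LDA on the
leading PCs (capped at min(80, n−K)).

## AMOVA

Each locus contributes a nested random-effects ANOVA on its 2N allele
copies (0/1 coded): groups ⊃ localities ⊃ individuals ⊃ copies.  Sums
of squares convert to variance components through expected-mean-square
coefficients valid for unbalanced designs (individuals missing a call
simply contribute no copies at that locus).  Components are summed over
loci; F-analogues are F<sub>CT</sub> = a/T, F<sub>SC</sub> = b/(b+c+d),
F<sub>IS</sub> = c/(c+d), and the within-individual row's F is
1 − %var(within)/100.  Percent variance floors negative components at
zero and renormalises to 100; raw components are reported alongside.
Uncertainty: delete-one-locus jackknife SDs, percentile bootstrap over
loci, and stratified permutations — allele copies re-paired within
localities (F<sub>IS</sub>; computable in closed form from the total
het count, so it vectorises over permutations), individuals shuffled
among localities within groups (F<sub>SC</sub>), whole localities
shuffled among groups (F<sub>CT</sub>).  Correctness is checked against
a Monte-Carlo oracle that decomposes variance directly from resimulated
frequency hierarchies, independent of the sums-of-squares estimator.

## Leaf morphometrics

From length L, width W and width location WL (all mm):
LA = (L·W/2) + ((L−WL)·2/2), implemented exactly as printed; the second
term reduces to (L−WL) and may be shorthand for a triangle term
(L−WL)·W/2, available as `formula="width-corrected"`.  Ovality = WL/L
(~0.5 oval, <0.5 heart-shaped, >0.5 ginkgo-shaped); ratio = L/W; √LA is
used in multivariate analyses for residual normality.  Half-width
measurements (folded leaves) are doubled first.  The six-trait vector
(L, W, WL, √LA, ovality, L/W) enters a centred/scaled PCA followed by
one-way ANOVA and Tukey HSD on PC1/PC2 across groups.

## Redundancy analysis

The response (locality × SNP frequency matrix, or leaf traits) is
column-centred and regressed on explanatory variables by least squares;
r² is the constrained share of variance.  For partial RDA both response
and explanatory matrices are residualised on the conditioning set
(centred coordinate monomials up to total degree 3: x, y, x², xy, y²,
x³, x²y, xy², y³), and r² is taken relative to the residualised
response.  pseudo-F = (constrained/q)/(residual/(n−q−c−1)).  The
permutation test permutes rows of the residualised response and
re-residualises each permuted copy on the conditioning before computing
F (reduced-model scheme); skipping that re-residualisation deflates the
null and is wildly anticonservative.  The implementation reproduces
vegan's `rda` to six decimals on fixed test data (r², pseudo-F,
adjusted R²).  Forward selection adds the candidate with the smallest
permutation p while p < α; variance partitioning uses adjusted R²
(Ezekiel) of the env, space and joint models, reporting raw fractions
(slightly negative values are an adjusted-R² artefact).  Environmental
collinearity screening keeps a greedy subset with pairwise |r| < 0.7.

## Pipeline

`run_pipeline` executes simulate/ingest → filter → ploidy → kinship →
diversity → structure → AMOVA → leaves → RDA from one YAML config, any
stage skippable.  Clustering and ordination run on the filtered but
unpruned individuals; kinship pruning is applied before diversity,
F<sub>ST</sub> and AMOVA, where related individuals would bias the
statistics.  Identical config and seed give identical reports (content
hash recorded).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so recovery
tolerances are meaningful: 2,000–5,000 loci and 50–200 individuals for
estimator recovery, 99–10,000 permutations depending on the test,
20–50 seeds for calibration/power/coverage claims, K scans to 10.  The
RDA power check uses 25 localities × 12 individuals, a 50-locus cline
with slope 3 on the logit scale, and environment noise 0.3 — with fewer
localities the realized environment is occasionally near-collinear with
the degree-3 spatial surface and no method can separate them.  Degenerate
inputs are handled explicitly: monomorphic sites are untested by the
negative-F filter, zero-variance sites cannot be "linked" in LD pruning,
localities with one individual report missing diversity/kinship, strata
with a single unit contribute no variance component, and rank-deficient
explanatory matrices are reduced by pivoted QR.

## Limitations

The generator omits linkage, allele dropout, genotyping-error structure
and spatially autocorrelated environments beyond one gradient; passing
tests demonstrate estimator correctness under the stated model, not
robustness to those real-data features.  The AMOVA missing-data and
negative-component conventions follow the documented choices above;
other software may differ in detail.  The published field results
themselves (per-locality Ho/He/F, Table-style AMOVA and RDA values)
depend on the original unreleased reads and are not reproduced here;
the pipeline's behaviour is validated on synthetic truth instead.
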