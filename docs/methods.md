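# Methods

This note documents the statistical models and numerical choices behind
breedkit: what each stage computes, which parameters matter, and what
the synthetic benchmarks do and do not demonstrate.

## Genotype encoding

Genotypes are read from tab-delimited HapMap text (eleven fixed metadata
columns followed by one column per individual) and encoded as
alternate-allele dosages in {0, 1, 2}, with NaN for missing calls
(`NN`, `N`, `--`). The alternate allele is the second allele of the
`alleles` column; when that column is malformed the minor allele
observed in the data stands in, with ties broken by ASCII order so that
dosages are deterministic. Both two-letter (`AG`) and single-IUPAC
(`R`) call dialects are supported and auto-detected from call width.
The strand column is ignored and alleles taken as written. Monomorphic
SNPs are kept at read time; per-SNP statistics exclude them because
they carry no discriminative information.

## Sample-size recommendation

The per-breed sample-size rule models breed discrimination at one SNP
as a two-proportion test on allele counts: detect an allele-frequency
difference `delta` between two breeds (2n alleles each) at two-sided
size `alpha` with the target power. The normal-approximation count

    n_alleles = (z_{1-alpha/2} + z_{1-power})^2 (p1 q1 + p2 q2) / delta^2

is converted to individuals (ceil of half) and then verified against
the exact power — the rejection probability of the z-test under the
joint Binomial(2n, p1) x Binomial(2n, p2) outcome distribution — and
raised until the exact power clears the target. Defaults delta = 0.2,
alpha = 0.05, power = 0.8; this is a deliberately simple, documented
effect model, not an attempt to model the multivariate classifier's
power. When the target power falls below the test size the formula
degenerates and the recommendation floors at one individual.

## Embeddings

PCA operates on the per-SNP mean-imputed, column-centred dosage matrix
(optional unit-variance standardisation; centring-only is the default,
as is conventional for genotype PCA). Explained-variance percentages
are eigenvalues over the *total* variance, so the full spectrum sums to
100. Classical MDS is Torgerson double centring of squared distances
with negative eigenvalues truncated to zero. UMAP is delegated to
umap-learn with a fixed `random_state`; it is a published algorithm this
package merely invokes. All PCA/MDS axes are sign-fixed so the
largest-magnitude loading (or coordinate) is positive, which makes
outputs reproducible across linear-algebra backends.

## Distances and trees

The individual-level distance is allele sharing: one minus
identity-by-state similarity, i.e. the mean of |g_i - g_j|/2 over SNPs
typed in both individuals. The field's tree methods do not prescribe a
genotype distance; this choice is documented and swappable.

Neighbor-Joining follows Saitou–Nei agglomeration and is exact on
additive matrices (verified against a path-length oracle over random
trees). BioNJ uses the same selection criterion with the
variance-weighted matrix reduction (lambda clamped to [0, 1]); on
exactly additive input it coincides with NJ. UPGMA is average linkage
with node height d/2, producing rooted ultrametric trees. Numerical
conventions: agglomeration ties break at the lowest (row, col) index
pair; negative NJ branch estimates are clamped to zero with the deficit
moved to the sibling edge. Branch support is by SNP bootstrap —
resampling SNP columns with replacement, rebuilding, and reporting the
percentage of replicates containing each internal bipartition (clade,
for the rooted UPGMA case). FastME is intentionally unsupported.

## Admixture model

Ancestry is inferred under the standard unsupervised admixture
likelihood: genotype g_ij ~ Binomial(2, sum_k q_ik f_kj), maximised by
EM over the ancestry matrix Q and cluster allele frequencies F.
Missing genotypes are skipped in the likelihood. F is clamped to
[1e-6, 1 - 1e-6] each iteration; convergence is |delta loglik| < 1e-6
or 500 iterations; the best of 5 random restarts is returned, and the
stored likelihood trace is non-decreasing (the EM guarantee, asserted
in tests). K = 1 has a closed form and skips iteration.

K is selected by masked-entry cross-validation: hide a fraction
(default 0.1) of non-missing entries, fit on the rest, predict hidden
dosages as 2·(QF), and score mean squared error averaged over
replicates (default 3); the chosen K is the argmin, lowest K on ties.
Label switching between fits is resolved by Hungarian assignment on
column correlations.

A note on identifiability at small n: with 20 diploid individuals per
population the binomial sampling noise in any per-population frequency
estimate is ~0.07 per SNP, so F recovery is judged against the realized
sample frequencies (which the EM tracks to ~0.005 RMSE on the K=3
benchmark) rather than the generative parameters.

## SNP panel selection

Association scores per SNP: chi-square (Pearson, no continuity
correction, df = C-1) and Fisher's exact test on the 2 x C allele-count
table (alleles by breed, missing calls omitted); mutual information and
information gain, in bits, on the genotype-class (0/1/2) distribution.
Fisher p-values are exact by full enumeration of the fixed-margin
distribution for up to 3 breeds and 60 alleles, otherwise estimated
from 1e5 seeded Monte-Carlo fixed-margin tables; two-sided p sums the
probabilities of tables at most as probable as the one observed.
Ranking is by ascending p (test methods) or descending statistic, ties
by SNP id; no multiple-testing correction is applied because selection
is by rank, not significance — raw p-values are reported for
transparency. Redundancy pruning is a greedy scan in rank order
dropping any SNP whose squared Pearson dosage correlation
(pairwise-complete) with an already-kept SNP exceeds the threshold
(default r² = 0.9). Panels are the top fraction (round(fraction·m)) or
an explicit count of the pruned ranking.

## Classification, calibration and one-class screening

Classifiers: k-nearest neighbours (k = 5), random forest (500 trees),
RBF SVM with probability outputs, and XGBoost (200 rounds, depth 6) —
fixed, documented defaults with no automatic tuning. Missing panel
dosages are imputed with training means. Cross-validation schemes:
stratified k-fold (default 5), repeated stratified k-fold (default
5 x 5, the "randomized k-fold" reading), and leave-one-out (refused
above 10,000 individuals). Metrics are pooled over out-of-fold
predictions: accuracy, unweighted Cohen's kappa, and macro one-vs-rest
AUC (a class absent from the truth is excluded from the macro average
with a warning).

The raw top-class probability P is recalibrated through the tuning
parameter alpha (default 2):

    t = P^a / (P^a + (1-P)^a)
    z = t                   if P > 0.5
    z = t + a (0.5 - t)     if P <= 0.5

implemented verbatim. Two quirks are worth flagging: at alpha = 2 the
transform satisfies the mirror identity z(P) = z(1-P), and the
P <= 0.5 branch is non-monotone in P for alpha > 1 and can exceed 1 for
large alpha (e.g. alpha = 4, P = 0.3); the reported z-score is clamped
to [0, 1] with the raw value kept alongside for audit.

The one-class screen rejects queries unlike any training breed. The
score of a genotype under breed b is the mean per-SNP binomial
log-likelihood of its dosages under b's smoothed panel allele
frequencies (f = (alt + 1)/(2n + 2)). The threshold per breed is the
1st percentile (lower order statistic) of the training individuals' own
scores, computed leave-one-out: each calibration score removes the
individual's alleles from the frequency estimate first. Without the
leave-one-out step, training scores are optimistically biased and a
quarter of genuine held-out individuals can fall below threshold; with
it, calibration and query scores are exchangeable. A query with more
than 50% missing panel SNPs fails outright as low-quality. Assignment
happens first, screening is applied under the assigned breed.

## Synthetic data

The generator draws breeds from the Balding–Nichols island model: an
ancestral frequency p_j ~ Uniform(0.05, 0.95) per SNP, breed
frequencies f_kj ~ Beta(p_j(1-F)/F, (1-p_j)(1-F)/F) with F the
configured FST, and dosages ~ Binomial(2, f_kj); admixed individuals
draw from the mixture frequency q·F. This matches the admixture
likelihood above exactly, which makes parameter-recovery tests
coherent. Alleles are fixed A (ref) / G (alt), positions synthetic, and
geography decorative. The model deliberately omits linkage
disequilibrium, selection, genotyping-platform error structure and
unbalanced missingness patterns — passing benchmarks on it demonstrates
correctness of the algorithms under the island model, not performance
on any particular real livestock panel, where LD between panel SNPs and
uneven breed divergence will generally make discrimination harder.

## Benchmark problem sizes

The headline synthetic benchmark uses 10 breeds x 20 individuals at
FST = 0.15 with 2,000 SNPs, a top-500 chi-square panel, and random
forest under stratified 5-fold CV — a desk-scale analog of a
SNP-chip-sized study, chosen so the whole experiment runs in well under
a minute. The admixture recovery benchmark uses K = 3, FST = 0.2,
60 individuals, 1,000 SNPs (300 SNPs for the replicated K-selection
runs); the one-class benchmark 5 breeds at FST = 0.3 with 40 training
and 10 held-out individuals per breed and a 1,000-SNP panel. All
benchmarks are seeded end to end; identical seeds reproduce fixtures,
CV reports and prediction tables byte for byte.
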