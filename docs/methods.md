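# Methods

This note records the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic generator does and does
not emulate, and the numerical conventions and known limitations a user
should be aware of.

## Forest kernel

Trees are scikit-learn `DecisionTreeRegressor`s, but all quantities the
analysis rests on are computed by this package from per-tree bootstrap
records rather than taken from library conveniences, because published
importance definitions differ in scaling:

* Bootstrap: size-n samples drawn with replacement (≈64% unique
  individuals per tree, ≈36% out of bag).
* OOB prediction: for individual i, the mean prediction over trees whose
  bootstrap missed i. Individuals never OOB (possible at very small
  `n_trees`) are flagged and excluded from the error, never imputed.
* PVE = 100 × (1 − OOB-MSE / var(y)), with var(y) using the n−1
  denominator (the R `randomForest` "% Var explained" convention). PVE is
  never clipped: a model worse than the mean goes negative.
* Permutation importance of SNP j: for each tree, permute j's values
  among that tree's OOB samples, recompute the tree's OOB squared error,
  average the increase over **all** trees (trees that never split on j
  contribute exactly zero — hence a constant column scores exactly 0), and
  scale by 100 / baseline OOB MSE. Units are "% of baseline OOB MSE";
  negative values are meaningful noise indicators.

Defaults: `n_trees=1500` (prediction accuracy saturates well below this at
the target data scale); `min_node_size=5`, the conventional regression
minimum leaf size; `mtry="sqrt"` (⌊√p⌋). `mtry="third"` (⌊p/3⌋, the R
regression default) is noticeably better for subset selection when the
signal is sparse, and `tune_mtry` picks from {⌊√p/2⌋, ⌊√p⌋, ⌊2√p⌋} by mean
OOB PVE over three seeded refits (ties to the smaller value).

Reproducibility: every randomized routine takes a seed; nested stages
derive sub-seeds with `derive_seed(master, *context)` (SeedSequence with
crc32-hashed string keys), so whole runs are bit-identical under one
master seed and all derived seeds stay below 2³¹.

## Structure adjustment

OLS of the trait on an intercept plus the first K−1 ancestry columns (the
Kth is collinear through the row-sum constraint); the adjusted trait is
grand mean + residuals, so its mean is preserved and its variance can only
shrink. The fit is closed-form least squares (`numpy.linalg.lstsq`); the
absorbed share is reported as R². The adjustment is idempotent. Both
adjusted and unadjusted branches are first-class in the pipeline, because
when ancestry tracks the same environmental gradient as the trait,
adjustment removes real adaptive signal along with the confounding — the
gap between branches is itself informative.

## Backward purging and baselines

The start set is the top `start_k=50` SNPs by full-model importance
(generous, so loci with weak main effects but strong interactions are not
excluded up front). Each step refits the forest `replicates=3` times with
distinct derived seeds, averages the per-SNP importances and the PVE, and
removes the SNP with minimum mean importance (ties to the
lexicographically smaller id, for determinism), down to 2 SNPs. The
trajectory records the set, mean PVE and purged SNP per size; no plateau
is auto-detected — the subset size to report is the user's choice.

Random baselines draw subsets of sizes {2, 5, 10, 15, 20} uniformly
*without replacement within a draw* (duplicated predictor columns are
degenerate), 10 draws per size, and report mean PVE per size.

## Epistasis scan

Per replicate r (of 5), a baseline forest on all k SNPs is fitted first;
then each SNP j is removed and the forest refitted. The delta for ordered
pair (i, j) is importance_i(without j) − importance_i(baseline of the same
replicate) — a paired design, chosen because pairing removes between-seed
variance (the alternative, one global baseline, was rejected; the
replicate-level t-test is over changes). Deltas are tested with a
two-sided one-sample t (df = R−1 = 4) and FDR-adjusted over all k(k−1)
ordered pairs. Both directions are tested; an undirected edge enters the
network iff min(q_ij, q_ji) < α, with direction and weight (|mean delta|,
in importance units) from the more significant direction. Significant but
sign-discordant directions are reported and excluded from the graph. The
full ordered-pair table is always exported for asymmetry inspection.

**Known limitation — anticonservative null.** The scan's replicates refit
the *same* dataset; only forest randomness varies between them. Remove-one
importance shifts have a nonzero systematic component even under a purely
additive architecture (split-slot competition between predictors, ancestry-
induced correlation, and renormalization by each fit's own OOB MSE), so
with enough trees the paired t-test flags such shifts as significant:
measured on additive-only simulations, ~11% of ordered pairs reach q<0.05
at the nominal 5% level. Planted interactions do carry the expected
signature (the true pair has the largest |delta| and a strongly negative,
synergistic shift), but edge lists should be read as a ranking of
interaction strength, not as FDR-calibrated discoveries.

**Sign conventions.** A synergistic (jointly contributing) pair shows
negative deltas — removing one partner collapses the other's importance; a
product-model pair sized at ~10% of trait variance is detected with the
correct sign in ~8/10 seeds at n=400. The converse expectation, that a
"redundancy" pair (either locus suffices) shows positive (antagonistic)
deltas, holds only for loci that are *correlated*: for independently drawn
loci an either-suffices trait is variance-superadditive at every carrier
frequency (each locus alone explains q(1−q)(1−q_b)² of an OR-indicator
whose joint variance is s(1−s), s = 1−(1−q_a)(1−q_b), always larger), so
the measured shift is synergistic there too. Genuine antagonism arises
from inter-locus LD (one locus substituting for the other), which this
generator deliberately does not model (below).

## Genotypic LD test

Composite (genotypic) LD between unphased SNPs is tested on the r×c joint
genotype count table with G = 2·Σ obs·ln(obs/exp) over non-empty cells,
and a Monte-Carlo permutation p-value, (1 + #{G_perm ≥ G_obs})/(n_perm+1),
permuting one column across individuals (default n_perm=10000;
+1-smoothing keeps p > 0, which FDR needs). This replaces Markov-chain
exact tests of the same null with a simpler, fully seeded procedure that
is adequate at n ≈ 400. Missing genotypes are excluded pairwise
(pre-imputation values are used); a pair monomorphic among complete cases
is untestable and recorded as p = 1 when annotating a network. q-values
are computed over exactly the network's edges — the question is whether
the *interacting* pairs are also in LD, not a genome-wide scan.

## Statistics primitives

One-sample t: t = mean/(sd/√n) with the n−1 sd; degenerate inputs follow
fixed conventions (zero spread, zero mean → (0, 1); zero spread, nonzero
mean → ±∞, p=0, logged). Storey q-values use the fixed-λ (0.5) estimator
pi0 = #{p > λ}/((1−λ)m), clipped to [1/m, 1] — a spline-smoothed λ grid
adds nothing at family sizes ≤ 380 — followed by the min-forward
recursion; with pi0 forced to 1 the transform is exactly
Benjamini–Hochberg.

## Synthetic data

Balding–Nichols frequencies (ancestral f ~ U(0.05, 0.95); per-population
f_k ~ Beta(f(1−F)/F, (1−f)(1−F)/F) with F the differentiation parameter,
default 0.1), Dirichlet(0.2) admixture rows over K=3 populations, and
binomial genotypes on the admixed frequencies — the minimal standard model
of a structured sample, defaults at the target data scale (n=410, p=339).
Phenotype = intercept (250, a Julian-day-like location) + additive +
epistatic + cline + Gaussian noise, with noise variance solved so the
non-noise components hold `h2_target` (default 0.4) of the summed
component variances; reported variance shares are marginal component
variances over that sum (cross-component covariance is not attributed).

Additive effect magnitudes are U(0.5, 1.5)·`beta_sd` with random sign, so
every causal SNP carries a genuinely small-to-moderate effect; a Gaussian
effect law was rejected because it plants near-zero "causal" SNPs that no
method can distinguish from noise. Epistasis codes (all centered):
product (g_a−ḡ_a)(g_b−ḡ_b); complementation, both loci carrying an
alternate allele; redundancy, either locus carrying one. The structure
effect is a length-K coefficient vector applied to Q (a latitudinal-cline
surrogate); cline and epistatic pairs default to absent so every planted
effect is an explicit choice.

Not emulated: linkage/LD blocks along chromosomes (loci are independent
within populations; admixture is the only source of between-locus
correlation), genotyping error, selection, and family structure. A green
simulation test therefore establishes behaviour under idealized
independent-locus architectures, not under tight LD between causal and
tag SNPs.

With ~2% of trait variance per causal SNP (20 causal, h2 = 0.4) at n=400
among p=300 SNPs, a substantial fraction of causal loci fall below the
maximum-order-statistic noise floor of the null SNPs (~3% r² among 280
nulls, higher under admixture): complete recovery of the causal set is
impossible in principle at this design, and the purge's ~11–12/20
recovered in the top-20 slightly exceeds what a univariate-correlation
oracle achieves on the same data.

## Pipeline and runtime choices

`run_pipeline` executes load/simulate → (adjust) → full forest → purge →
baselines → top-k → epistasis scan → LD annotation → export, writing
TSV/JSON/SIF artifacts and a manifest (config hash excluding the output
path, seed, version, artifact list); reruns under the same config are
bit-identical. Stage failures write a `FAILED` marker and abort with the
stage name.

Test and example runs use 60–300-tree forests rather than the production
default of 1500: tree count affects the Monte-Carlo noise of PVE and
importance, not their definitions, and the scaled settings keep the full
suite near 15 minutes on one CPU.
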