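# Methods

This note documents the statistical procedures implemented in
`aerotransfer`, the parameter choices that matter, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Depth equalization

Observed richness from denoised amplicon data grows with read count, so all
samples are subsampled to a common depth before any diversity comparison.
Subsampling is **without replacement**: each retained sample's column is a
multivariate hypergeometric draw from its original reads, so drawn counts
never exceed the originals, expectations are proportional to the original
composition, and a sample already at the target depth passes through
unchanged. Samples below the target depth are dropped and listed. The
default analysis depth is 20,000 reads.

Each sample's random stream is derived from `(seed, sample_id)` by hashing
(blake2b → 31-bit child seed), so results are independent of sample order
and of which other samples are present.

## Negative-control decontamination ("prevalence" contrast)

Reagent and handling contaminants dominate low-biomass negative controls
but appear only sporadically in true samples. For each feature we form the
2×2 presence/absence table (present = ≥ `presence_min` reads, default 1)
across negative controls versus true samples and score it with the
**two-sided Fisher exact test**. A feature is called a contaminant when its
score is at or below the threshold (default 0.1, a conventional choice for
prevalence-based decontamination) *and* its prevalence fraction in controls
is at least its prevalence in true samples. The direction guard matters:
without it, any taxon confined to true samples with a wildly asymmetric
table would be flagged. Fisher's exact test is used rather than an
asymptotic chi-squared statistic because control groups in dust studies are
modest (tens of samples), where exact tail probabilities are preferable.

## Alpha diversity

Observed richness is the count of features with nonzero reads; the Shannon
index is H = −Σ pᵢ ln pᵢ on the sample's proportions (natural log; the base
is configurable). Both are computed on the depth-equalized, decontaminated
table. Group contrasts use the Mann–Whitney rank-sum test with average
ranks on ties: exact enumeration when the pooled size is ≤ 12 with no ties,
otherwise the normal approximation with tie and continuity corrections.
Pairwise p-values are reported raw by default (a Holm step-down option
exists but is off), matching the common presentation of pairwise diversity
panels.

## Beta diversity in Aitchison geometry

Counts carry only relative information. Each sample is closed and
centered-log-ratio transformed, clrᵢ = ln(cᵢ + δ) − mean ln(c + δ), with an
additive pseudocount δ = 0.5 by default to handle zeros; because all
samples sit at a common depth after subsampling, a constant pseudocount
perturbs all samples comparably. Euclidean distance between CLR vectors is
the Aitchison distance — a true metric, invariant to per-sample scaling and
feature order.

PCoA uses Gower double-centering, B = −½ J D² J, and an eigendecomposition;
coordinates are eigenvectors scaled by √λ for positive eigenvalues.
Negative eigenvalues are reported but not corrected (no Cailliez/Lingoes),
because Aitchison matrices are Euclidean by construction and negative mass
beyond round-off indicates an input problem rather than something to hide.

ANOSIM ranks all n(n−1)/2 distances (average ranks on ties) and computes
R = (mean between-group rank − mean within-group rank) / (n(n−1)/4).
Significance comes from label permutations with fixed group sizes:
p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm) with 999 permutations by
default, giving the familiar p = 0.001 floor. When the number of distinct
label orderings is small (≤ 20,000) the null is enumerated exactly instead
of sampled.

## Matched home–stable transfer ranking

The transfer statistic asks whether a farmer's home is *specifically*
similar to that farmer's own stable, over and above the general similarity
of homes and stables. Farms with both a home and a stable sample define the
matching; all stables of the livestock type serve as alternatives.

* **row_wise** (default): the matched distance d(homeᵢ, stableᵢ) is ranked
  within {d(homeᵢ, stableⱼ) ∀ j}; rank = 1 + #{closer alternatives}, ties
  counting ½. Under no transfer the rank is exactly uniform on
  1..n_stables, so the expected rank-1 fraction is 1/n_stables — this is
  why row-wise is the default: "rank 1" coincides per home with "more
  similar than every non-associated stable", and the null is clean.
* **global**: the matched distance is ranked within the pooled set of all
  non-matching home–stable distances plus itself. Retained because the
  phrase "ranked among all non-matching pairs" is genuinely ambiguous
  between the two universes; neither is asserted as canonical.

The cohort statistic is the fraction of rank-1 pairs. Its null distribution
is obtained by randomly permuting the home→stable assignment among matched
farms and re-ranking (default 999 draws);
p = (1 + #{null fraction ≥ observed}) / (1 + draws). When every pair shares
the same number of alternatives, the closed-form binomial tail
P(X ≥ k), X ~ Bin(n_pairs, 1/(n_alternatives+1)) is reported alongside.
Ranks are invariant under any strictly monotone transform of the distances.

When a farm has two samples of one environment (seasonal repeats), the
first in metadata order is used and the repeat is logged; the generator
sidesteps the issue by producing at most one home and one stable per farm.

## Synthetic data generator

Each environment e has a base log-abundance profile
b_e = s_e · (√(1−w)·t + √w·u_e), where t is a template shared by all
environments, u_e an environment-private direction, w ∈ [0,1] the
**divergence** weight, and s_e the **sharpness**. A sample's latent
composition is softmax(b_e + σ ε) with per-sample Gaussian noise ε — a
logistic-normal community. Sharpness controls observed richness at fixed
depth (steeper profile → fewer detectable features); σ controls
within-environment scatter; w controls between-environment separation.

Matched homes mix compositions: home = (1−τ)·(own draw) + τ·(own stable's
realized composition). Transfer acts on latent compositions, not counts, so
τ has a clean airborne-mixing interpretation and rank-one fractions are
monotone in τ. Counts are multinomial at a per-sample depth drawn
gamma-Poisson with configurable mean and coefficient of variation.

Negative controls are dominated by a dedicated contaminant feature block
(each contaminant present with probability `prevalence_in_controls`,
lognormal abundance) plus a faint sparse leak (2% weight over ~30 random
biological features per control); contaminants cross into true samples with
probability `prevalence_in_samples` at ~0.2% relative abundance. Taxonomy
strings are synthetic placeholders with a realistic seven-rank hierarchy
(some lineages truncated at genus or family, always prefix-complete).

The **study-shaped preset** fixes group sizes at 65 suburban homes, 40 cow
stables, 38 cow farmers' homes, 81 pig stables, 82 pig farmers' homes, and
43 negative controls (29 matched cow farms, 77 matched pig farms), 2,000
features, depths overdispersed around 25,000 reads (CV 0.1) so subsampling
to 20,000 retains most but not all samples. Cow environments get flatter
profiles than pig environments (cow home the flattest, pig stable the
steepest), encoding the designed richness ordering; cow farms get a larger
transfer fraction (τ = 0.25) than pig farms (τ = 0.10). Per-sample σ = 1.2
and divergence w = 0.35 were chosen for partial between-environment
overlap. Real dust-community dispersions are unknown; these are
order-of-magnitude choices.

### What the generator does not emulate

* **Concentration of measure.** With ~2,000 features carrying independent
  logit noise, between-sample distances concentrate tightly, so even modest
  environment shifts separate groups almost perfectly: preset ANOSIM R
  values run near 1 and rank-one fractions run far above what field cohorts
  show at comparable τ. Real communities have low effective dimensionality
  (correlated taxa, a few dominant gradients) and many unmodelled noise
  sources (outdoor air, seasonal drift, 14-day integration). Passing tests
  therefore demonstrate correctness, calibration, and monotonicity of the
  statistics — not that the generator reproduces field effect sizes.
* No read-level artifacts (chimeras, primer trimming, length filtering) —
  the generator starts where denoising ends.
* No compositional bias between environments' extraction efficiency, and no
  DNA-concentration information (so only the prevalence, not the frequency,
  flavour of decontamination is meaningful on it).

## Numerical choices and degenerate inputs

* Ties: average ranks throughout (ANOSIM, rank-sum); matched-pair ranking
  counts ties as ½, keeping results deterministic on tied inputs.
* Permutation p-values use a 1e-12 tolerance on the ≥ comparison to avoid
  round-off flipping a hit.
* All-zero samples are rejected in alpha diversity and closure; all-equal
  distance matrices give R = 0 (all ranks tied) and a flat PCoA.
* Subsampling at exactly the available depth returns the sample unchanged
  (no RNG draw), so full-depth subsampling is the identity.
* Seeds: every stage seed is a 31-bit blake2b hash of the top-level seed
  plus a stage/sample label; no global RNG state is used anywhere.

## Problem sizes used in the test suite

Replicated simulation checks run on reduced cohorts chosen to keep the
suite fast while leaving the assertions well-powered: null calibration uses
500 replicates of 10-farm cohorts at 100 features and depth 1,000; the
transfer-power check uses 100 replicates of 20-farm cohorts at 300 features
and depth 20,000; monotonicity ladders use 50 replicates per setting of
8-farm cohorts. Contaminant recovery and the structural checks run on the
full study-shaped preset.

## Limitations

* ANOSIM permutation p-values are sampled (except in the small-instance
  exact regime); repeated runs with different seeds jitter p near
  thresholds.
* The binomial closed form for the transfer test treats pair ranks as
  independent; the permutation null, which does not, is the primary
  p-value.
* The prevalence score tests each feature marginally; jointly distributed
  contamination (whole-well swaps) is out of scope.
* BIOM-format input is not implemented; TSV/CSV is the normative path.
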