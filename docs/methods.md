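# Methods

This note documents the statistical models behind `cusipop`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Weir–Cockerham θ

For a biallelic locus observed in r populations with nᵢ genotyped diploids,
allele frequency pᵢ and heterozygote frequency hᵢ per population, the
estimator forms the weighted mean frequency p̄, the frequency variance s²,
the mean heterozygosity h̄, the average sample size n̄ and its
size-correction n_c, and from them the three variance components

- a — among populations,
- b — among individuals within populations,
- c — within individuals (h̄/2),

exactly as in the 1984 variance-components formulation. The multilocus
estimate is the ratio of sums θ = Σa / Σ(a+b+c), not the mean of per-locus
ratios, which makes it invariant to duplicating loci and robust to
near-monomorphic loci. Conventions:

- Per-locus nᵢ counts only genotyped individuals; a locus genotyped in
  fewer than two populations, or with mean sample size ≤ 1, is skipped.
- Negative components and (slightly) negative multilocus θ are legitimate
  finite-sample outcomes and are reported as-is.
- Loci with a+b+c = 0 (monomorphic across all populations) are excluded
  from the ratio.

The test suite checks the implementation against a second, independently
written scalar transcription of the same formulas on ~1,000 random genotype
count tables, against the analytic endpoints (θ = 1 for fixed alternate
alleles, θ = 0 for identical all-heterozygote populations), and against the
generator's drift parameter (below).

## Permutation null for differentiation

Exchangeability under the no-differentiation null is enforced directly:
genotype rows are fixed, population labels are reshuffled preserving the
observed group sizes, and multilocus θ is recomputed per iteration
(default 1,000). The p-value is (1 + #{θ_null ≥ θ_obs}) / (1 + n_perm) —
the add-one convention avoids p = 0 and counts ties as extreme — and the
null 95th percentile is reported as the rejection cutoff. For cohorts small
enough to enumerate, an exhaustive mode scores every distinct split and
returns the exact tail proportion. Calibration is verified empirically:
across 200 panmictic synthetic cohorts of 16+17 individuals at 100 loci,
θ_obs clears the null 95th percentile at close to the nominal 5% rate.

## Diversity statistics

Hₑ uses the plug-in 1 − Σp² with no small-sample correction, matching the
convention of the population-statistics stage that typically precedes this
kind of analysis; an unbiased 2n/(2n−1) variant is available for
sensitivity checks. Fᵢₛ = 1 − Hₒ/Hₑ is undefined (and excluded from
summaries) where Hₑ = 0. Summary tables report locus means and sample SDs
(n−1); the two populations are compared metric-by-metric with a two-sample
t test on the per-locus values. Welch's unequal-variance form is the
default everywhere — it is the only safe default when locus sets and
variances differ between populations — with the pooled-variance form
available as an option.

## Admixture model

The sampler implements the standard admixture mixture model for unphased
diploid biallelic genotypes:

- Z (cluster of origin of every allele copy) | Q, P — categorical;
- P (cluster allele frequencies) | Z — Beta-conjugate update, with prior
  either symmetric Beta(λ, λ) or, with correlated frequencies enabled, the
  F-model prior Beta(p_A(1−F_k)/F_k, (1−p_A)(1−F_k)/F_k) around ancestral
  frequencies p_A;
- Q (ancestry proportions) | Z — Dirichlet(α + counts);
- α — Metropolis with a Gaussian proposal on the log scale (Jacobian
  included), single α shared across individuals, uniform(0, 10] prior;
- F_k and p_A — Metropolis with reflected-range Gaussian proposals,
  uniform priors on (0.001, 0.999).

Missing genotypes contribute nothing to the likelihood (no imputation).
The traced quantity is ln P(X | P, Q) including the heterozygote binomial
coefficient; the per-K evidence is mean − variance/2 of the post-burn-in
trace, the standard harmonic-style summary that ΔK selection expects.
Posterior summaries are plain post-burn-in means without thinning.

Two sweep profiles are used: the full-study profile of 5,000 burn-in /
50,000 sampling sweeps is the configuration default, and a desk profile of
500 / 2,000 sweeps is used by the test suite and the acceptance script.
The desk profile was fixed once, before any recovery experiment, on the
grounds that the sampler mixes in tens of sweeps on data sets of this size
(two populations × ≤50 individuals × ≤500 loci); at that scale it recovers
ancestry (mean max-Q ≈ 0.99 against generator truth), ranks lnP(2) above
lnP(1) on structured data, and lands ΔK on the true K.

Label switching across replicate runs is resolved by exhaustively
permuting cluster columns (K ≤ 6) to maximize the summed per-column
Pearson correlation with the first run; a zero-variance column contributes
zero correlation.

On genuinely unstructured data the learned α grows and Q rows flatten, so
mean max-Q at K = 2 stays well below hard-assignment levels (~0.55 in
practice) — the sampler does not hallucinate clusters.

## ΔK selection

For contiguous K with ≥ 2 replicate evidence values each, ΔK(K) =
|mean(K+1) − 2·mean(K) + mean(K−1)| / sd(K), using the sample SD. ΔK is
undefined at the range endpoints and wherever sd = 0 (logged and excluded
from the argmax). Ties break toward smaller K, i.e. toward parsimony. The
statistic is invariant to shifting all evidence values by a constant, and
positive scaling leaves the argmax unchanged; both are property-tested.
No posterior Pr(K) is computed — ΔK is the only selection criterion
offered.

## Morphometric stage

Welch's t per trait with Welch–Satterthwaite df and two-sided p; the
significance flag uses 0.05. PCA is an SVD of the centered (and by default
unit-variance, n−1-denominator) trait matrix, so with scaling the
eigenvalues sum to the number of traits. Component signs follow the
largest-absolute-loading-positive rule so loadings are reproducible across
BLAS implementations. Both scaled and unscaled modes are provided.
Comparisons to two-decimal published values round half-even at 2 dp.

## Synthetic data generator

Genotypes follow the F-model: p_A ~ Uniform(0.1, 0.9) per locus,
population frequencies Beta-drifted with parameter F_k (F = 0 is accepted
as the exact panmixia limit), individual ancestries either one-hot
(α = 0) or Dirichlet(α), and genotypes two independent Bernoulli allele
draws at probability Σ_k q_ik p_kl, with independent per-cell missingness.
The F-model was chosen over coalescent simulation deliberately: it is the
same prior family as the correlated-frequency clustering model, and for a
symmetric two-population design E[θ] ≈ F, giving closed-form targets for
recovery tests without external simulators. Beta-moment identities
(E[p_k] = E[p_A], Var(p_k − p_A) = F·E[p_A(1−p_A)]) are property-tested.

Morphometric tables are multivariate normal with a common inter-trait
correlation ρ (positive-definite for ρ ∈ (−¼, 1)), population-specific
means and SDs, truncated at zero by redrawing (which preserves means at
realistic coefficients of variation, unlike taking absolute values).
At ρ near 1 the scaled PCA has a dominant PC1 with proportion
≈ (1 + 4ρ)/5.

The study-shaped fixture bundles 16 admixed "west" + 17 unadmixed "east"
individuals at 77 biallelic loci (F = 0.3, 10% missing) with a matching
morphometric table (ρ = 0.99; snout longer in the west, fore limb larger
in the east, all western SDs inflated ~1.8×). Trait means/SDs are plausible
small-mongoose carcass lengths in cm. The fixture reproduces the study
design's qualitative pattern — moderate θ, two clusters with an admixed
west, opposite-direction snout/forelimb differences, wider western PC1
range — but not every printed magnitude: in particular, the
opposite-direction mean shifts between populations add variance orthogonal
to the shared size axis, so the fixture's PC1 carries ~85–90% of the
variance rather than >99%.

What the generator does **not** emulate: linkage between loci, RAD-locus
dropout or allele-specific missingness (missingness is uniform at random),
genotyping error, within-population substructure or relatedness, and
non-normal trait distributions. Passing recovery tests therefore show the
estimators are correct under the model's own assumptions, not that real
data meet those assumptions.

## Numerical conventions and degenerate inputs

- Allele codes are recoded to dense 0..k−1 per locus on ingestion
  (rank-preserving, VCF REF stays 0); half-called genotypes are coerced to
  fully missing with a logged count rather than rejected.
- Sampled allele frequencies are clipped to [1e−6, 1−1e−6] before logs.
- Q rows are renormalized after each Dirichlet draw; row sums are exact to
  1e−9.
- The empirical null 95th percentile uses linear interpolation
  (`numpy.quantile` default).
- All stochastic entry points take an explicit seed (an int, or a tuple of
  ints for replicate scans, passed to `numpy.random.default_rng`); fixed
  seeds give bit-identical results, which is asserted in the tests.
- Degenerate inputs fail loudly: empty populations, all-missing matrices,
  no variant loci, K exceeding the cohort, non-contiguous K ranges,
  non-positive lengths, zero-variance traits under scaling.

## Problem sizes

The test suite and acceptance script run everything at desk scale chosen
as the package's own validation conditions: calibration over 100–200
cohorts of 16+17 individuals × 100 loci with 500–1,000 permutations;
θ recovery at 2×50 individuals × 500 loci over 10–20 seeds per F;
clustering recovery at 2×25 × 200 loci with the 500/2,000 sweep profile,
20 seeds for ancestry/evidence and 10 replicate scans for ΔK.

## Known limitations

- The admixture sampler supports biallelic loci only, no linkage model,
  no use of prior population information, and exhaustive label alignment
  only to K = 6.
- Only two-population permutation testing is implemented; pairwise θ
  matrices over more populations are future work.
- No haplotype-based F statistics, no HWE exact tests, no bootstrap CIs
  over loci, no kernel-smoothed sliding-window statistics.
- GENEPOP export regroups individuals into population blocks, so row
  order (not content) can differ after a round trip.
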