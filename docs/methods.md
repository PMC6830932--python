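# Methods

This note documents the statistical models, conventions, numerical choices
and known limitations of `panelassoc`. It is the package's own account of
its methods; every number quoted here is computed by the test suite or
`scripts/acceptance.py`.

## Genotype coding and orientation

Genotypes are coded 0/1/2 as copies of the **minor** allele, with a distinct
missing sentinel. "Dominant" therefore always means dominant for the minor
allele (carriers vs non-carriers) and "recessive" means minor-allele
homozygotes vs the rest. The minor allele is defined once, on the combined
case+control sample, with a lexicographic tie-break (the alphabetically
later allele is called minor at exactly 0.5): a single orientation keeps
odds-ratio directions consistent across every analysis, and re-reading a
dataset can never flip it. The control-sample allele frequency is still the
one used by the MAF QC filter, since frequency filters are meant to reflect
the population, not case enrichment. Count triples are ordered
hom-minor / het / hom-major; coordinates are 1-based throughout.

## Variant QC

Filters run in a fixed order — control MAF < 0.05, call rate < 0.94,
control-sample Hardy–Weinberg exact test, then r² > 0.994 redundancy
pruning — and each variant is reported under the first filter it fails, so
the accounting identity `n_final + Σ exclusions = n_input` always holds.
HWE is tested in controls only: association at a true risk locus distorts
case-sample genotype proportions, and control-only testing is the field
convention. The HWE significance threshold defaults to 0.05/n with n the
panel size but is an explicit parameter, because studies drawing a panel
from a larger array sometimes Bonferroni-correct over the array-wide
variant count instead; the right denominator is a study-design question the
software cannot decide.

The HWE exact test conditions on the observed allele counts: the number of
heterozygotes then has probability proportional to
`n! / (n_hm! n_het! n_hM!) · 2^n_het`, and the two-sided p sums all
outcomes no more probable than the observed one. The implementation works
in log-space with a relative tie tolerance of 1e-12 when deciding tail
membership; an exact-rational enumeration oracle bounds its error below
1e-12 over every triple with total ≤ 50 (measured ~7e-15).

Redundancy pruning scans left-to-right in position order per chromosome and
drops a variant when its EM-based r² with any retained earlier variant
exceeds the threshold, keeping the first-seen member of each redundant set;
the scan is idempotent.

## Relatedness

IBD sharing is estimated by the standard method-of-moments decomposition of
per-variant IBS states given allele frequencies, with the
without-replacement finite-sample corrections (each pair's four alleles are
treated as draws from the observed allele pool). State probabilities are
clamped to [0,1] and renormalized, and PI_HAT = P(IBD=1)/2 + P(IBD=2).
Pairs above PI_HAT 0.25 (duplicates, first/second-degree relatives) are
resolved by dropping the lower-call-rate member (ties: later panel order),
iterating until a full recheck passes.

**Noise at desk scale.** PI_HAT noise scales roughly as 1/√(variants), and
the clamp at zero turns symmetric noise into a small upward drift for
unrelated pairs (≈0.05 mean at 1,000 variants). Production studies estimate
IBD on hundreds of thousands of pruned SNPs, where this is negligible; the
package's tests and examples size their panels (≥ 800–1,000 variants)
accordingly and tolerate occasional false flags near the threshold.

## Ancestry

Classical metric MDS (double-centered squared IBS-distance matrix,
eigendecomposition) produces components ordered by decreasing eigenvalue,
with signs fixed so each component's largest-magnitude loading is positive
— output is deterministic across runs. Outlier removal fits a bivariate
normal by sample mean/covariance to a chosen component pair (default
c1/c3) and removes points whose fitted density falls below a quantile of
all fitted densities (default 0.01; quantile 0 removes nothing, and the
removed count is monotone in the quantile). Components are transformed
first; the default is a rank-based normal-score transform, which is robust
to the heavy tails that motivate transformation but compresses extreme
points — when outliers are isolated and far, the `identity` transform
recovers them exactly and is what the acceptance checks use. The component
pair is a parameter because which component separates populations is a
property of the data, not the method.

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated by EM over the
double-heterozygote phase ambiguity, initialized at linkage equilibrium,
iterated to an absolute frequency change < 1e-10 (cap 1,000 iterations).
D = p_AB − p_A p_B, D′ = |D|/D_max with the sign-dependent bound, and
r² = D²/(p_A p_a p_B p_b). Missing data are handled pairwise-complete.
When no double heterozygotes exist the EM solution equals direct haplotype
counting, and r² equals the squared genotype-code correlation; both
identities are asserted in tests.

D′ confidence bounds come from a profile likelihood: allele frequencies are
fixed at their sample estimates, the sign of D at the EM solution, and the
multinomial log-likelihood of the observed 3×3 genotype table is evaluated
on a 101-point grid of D′ in [0,1]; exponentiated and normalized, the 5th
and 95th weighted percentiles are reported (refining to 1,001 points moves
the bounds by < 0.01). Blocks use a simplified Gabriel-style rule: a pair
is "strong LD" when CI_low ≥ 0.7 and CI_high ≥ 0.98, and blocks are
maximal runs of consecutive variants in which ≥ 95% of informative pairs
are strong, assigned greedily longest-first without overlap. This
deliberately omits Haploview's recombination-pair bookkeeping — blocks are
descriptive output here, and the simplified rule captures the CI-bound
semantics at a fraction of the complexity.

## Single-SNP tests

Collapsed dominant/recessive tests use the Pearson chi-square **without**
continuity correction — the uncorrected statistic is the one that
reproduces published PLINK-style model tests (the Yates-corrected variant
is available but non-default, and demonstrably does not match). Odds
ratios are the 2×2 cross-product with the Woolf log-scale CI; with a zero
cell the OR is flagged undefined unless the optional Haldane–Anscombe +0.5
correction is enabled (off by default). A covariate-free logistic
regression cross-check is provided; its exp(β) equals the cross-product OR
to 1e-8, as it must.

The max test takes max(χ²_dominant, χ²_recessive) and obtains its p by
permuting phenotype labels with genotypes fixed, using the add-one rule
p = (1 + #{stat\* ≥ stat})/(n_perm + 1), which keeps p in
[1/(n_perm+1), 1]. Panel-wide correction is Westfall–Young max-T: each
permutation recomputes every variant's statistic and records the
experiment-wide maximum; the corrected p compares the observed statistic
against that maximum distribution and therefore never undercuts the
pointwise permutation p from the same draws. Family-wise error on a
100-variant null panel at the study's sample sizes measures ≈0.065–0.075
at α = 0.05 over 200 replicates of 2,000 permutations — within binomial
noise of nominal.

## Conditional two-SNP analysis

For a (test, target) pair the sample is partitioned by the test SNP's three
genotypes; within each stratum the target SNP's 2×K genotypic test runs
after dropping empty genotype columns, and a stratum that is degenerate
(fewer than two nonempty genotype columns, or a single-phenotype stratum)
contributes (0, 0) so degrees of freedom are never inflated. "Suitably
combining" the strata is implemented as the sum of the independent stratum
chi-squares with summed df — the natural reading of a partition-based
combination — and the per-stratum pieces are exposed so alternatives can be
composed. With a monomorphic test SNP the statistic reduces exactly to the
marginal genotypic test.

Test SNPs are the four panel variants with the smallest
permutation-corrected p across three statistics (genotypic, phenotype-
indicator one-way ANOVA F, and max(dominant, recessive)); each family is
corrected by min-P/max-T from a shared permutation stream, each variant
scores its minimum corrected p, and ties break toward the larger observed
statistic then panel order. The scan over all (test, target) pairs is
corrected family-wise by min-P: per permutation the scan-wide minimum
p is recorded, and a pair's corrected p is the fraction of permutations
undercutting its observed p. Statistic families with heterogeneous degrees
of freedom are compared on the p-value scale for exactly this reason.

## Synthetic data

The generator emulates a retrospective candidate-panel study; its defaults
(435 cases, 138 controls, 895 variants, MAF uniform on [0.01, 0.5], 1%
missingness, disease prevalence 0.01) are the cohort conditions the package
is designed around.

* **Effect variants.** Penetrance models multiply per-genotype disease odds
  by (1, OR, OR) dominant, (1, 1, OR) recessive or (1, OR, OR²) genotypic;
  the baseline penetrance is solved so the population prevalence matches,
  and Bayes inversion yields P(genotype | case) and P(genotype | control) —
  the distributions a retrospective design samples from. The collapsed
  population odds ratio then equals the configured OR *exactly* (an
  algebraic identity, tested), and estimates at n = 435/138 recover it
  without systematic bias (geometric-mean estimates ≈ 2.24–2.29 for a
  configured 2.2; Woolf CI coverage 0.95).
* **LD blocks** use first-order copying of a latent uniform along each
  haplotype (retain with probability ρ, else redraw), which preserves each
  variant's marginal MAF exactly while inducing decaying positive
  dependence — sufficient to exercise r² pruning and CI-based block
  calling without coalescent machinery. Near-perfect blocks need ρ ≥ ~0.99
  and moderate MAFs to be called exactly.
* **Relatives** share one parental haplotype (parent-offspring-like,
  PI_HAT ≈ 0.5); **duplicates** are exact genotype copies (missingness is
  applied afterwards, so duplicate rows share genotypes but not missing
  patterns); **ancestry outliers** redraw all genotypes from HWE at MAFs
  shifted by a configurable amount (clamped to [0.01, 0.99]). All planted
  structure has deterministic placement recoverable from the config, and
  identical configs produce identical matrices.
* **Planted two-locus effects** (`simulate_combo_pair`) use a pure-epistasis
  construction: both SNPs' marginal genotype distributions are identical
  across groups, and the groups differ only in how the target SNP's
  genotypes associate with the test SNP's strata, with the flagged
  combination (test-SNP carrier AND target hom-major) at exactly the
  configured case/control proportions (defaults 0.13 vs 0.01). A carrier
  contrast confined to the single combination cell cannot reach
  headline-scale significance at 138 controls — the informative stratum
  holds only ~16 of them — so the construction spreads the contrast across
  strata while nulling the marginals, the scenario the conditional test is
  designed to detect. At the default design MAFs (0.35 test, 0.10 target)
  the conditional p has median ≈ 5e-7 and falls below 1e-4 in ≈95–97% of
  replicates at n = 435/138.

**What the generator does not model:** genuine coalescent genealogy and
recombination maps, allele-frequency spectra with rare-variant excess,
genotyping batch effects, sex chromosomes, and case-control imbalanced
missingness. Passing tests therefore demonstrate the statistical machinery
under idealized sampling, not robustness to those real-data artifacts.

## Numerical and edge-case conventions

* Zero-margin 2×2 tables: statistic 0, p 1, flagged degenerate.
* Permutation p-values always use the (1 + count)/(n + 1) rule.
* Comparisons against observed statistics in permutation loops carry a
  1e-12 slack so float noise cannot flip a tie.
* EM and MDS are deterministic; all Monte-Carlo paths take explicit seeds
  and are reproducible bit-for-bit.
* Monomorphic variants: LD is a distinct domain error (`LDUndefinedError`),
  not a numeric failure; in `.ped` reading a monomorphic variant gets a
  placeholder minor-allele label (`X*`) so the type invariant holds.
* Problem sizes in tests (panels of 12–1,000 variants, 80–600 samples,
  500–20,000 permutations, 200–1,000 replicates) are chosen so the full
  suite runs in well under a minute per module on one CPU while leaving
  each statistical check adequately powered.

## Known limitations

* The D′ CI is a profile-likelihood approximation holding allele
  frequencies fixed; it is not Haploview's exact estimator, and block calls
  can differ from Haploview's on borderline pairs.
* The conditional scan's min-P correction treats the scan as one family;
  restricting targets (e.g., to other genes) is supported but changes the
  family and hence the corrected p.
* PI_HAT at panel scale is noisy (see above); exclusion decisions near the
  threshold should be reviewed when the variant count is small.
* Covariate-adjusted association is out of scope: tests are contingency-
  table based, and the logistic module is covariate-free by design.
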