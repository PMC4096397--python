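# Methods

## The trait and its QC

The quantitative trait is the per-CpG methylation fraction in whole blood,
measured per sample with a read depth. Cells below 10× depth are masked;
CpGs with valid measurements in fewer than 80% of samples are dropped;
analysis is restricted to autosomes by default and to *variable* CpGs,
those with across-sample SD ≥ 0.1 (sample SD, n−1 denominator — the
conventional estimator; sites with fewer than two values have undefined SD
and are dropped). All thresholds are inclusive (≥). The filters are
idempotent and commute, which the test suite asserts. No cell-composition
correction is applied: the trait is deliberately the average methylation of
all cells in the tissue. Strand concordance (`preprocess.strand_concordance`)
summarizes agreement between the two independently captured strands of the
same CG dinucleotide — an internal technical replicate — and applies no
filtering.

The 80% presence rule is evaluated *after* depth masking, so a low-depth
cell counts as missing for the coverage rule.

## Mid-parent–offspring heritability

Per CpG, OLS of the child's value on the mean of the two parents over all
trios where all three values are present; the slope estimates h², with a
two-sided t-test on the slope (CpGs with < 3 trios or no mid-parent spread
are untestable). Heritable: h² > 0.2 (strict), ≥ 10 trios, BH q < 0.05.

Choices the data model leaves open, and what this package does:

* Trios sharing parents are independent regression points (the study pools
  52 trios from 22 families without correction); the permutation machinery
  in the mQTL stage, not the MPO stage, is where familial dependence is
  handled.
* BH is computed across **all** CpGs with a defined p-value, not only the
  h²/trio-qualifying candidates — conservative, and stated explicitly. The
  alternative order (adjust only among candidates) is available via
  `fdr_after_h2_filter=True`.
* The slope test is two-sided; the h² > 0.2 rule supplies directionality.

A CpG is a **SNP-CpG** when any polymorphic SNP coincides with the C
position or C+1 (the G). Family-specificity of the variant is not
re-checked; any polymorphic overlap suffices. On synthetic cohorts this
classification is exact because the generator never places background SNPs
on a CpG dinucleotide. Heritable non-SNP CpGs within 1 kb (default) of each
other are merged into clusters by single linkage.

For a purely dosage-driven CpG (methylation = baseline + β·dosage plus
read-sampling noise) the expected MPO slope has the closed form

    E[ĥ²] ≈ β²pq / (β²pq + σ²ₑ/2),

where 2pq is the founder dosage variance, cov(child, one parent) = β²pq
under random mating, and σ²ₑ is the per-sample measurement variance
(≈ E[m(1−m)]/depth for binomial read sampling). The acceptance suite checks
recovery of this expectation to ±0.15 over 200 replicate cohorts of 52
trios at depth 100; the per-CpG sampling SD of a 52-trio slope is itself
≈ 0.14, so the ±0.15 band is assessed on the replicate mean.

## cis-mQTL scan

Pairs with |SNP − CpG| ≤ 1 Mb (distance signed as SNP pos − CpG C pos;
window on the absolute value). Genotypes are additive alt-dosages; a
missing dosage drops the sample for that pair; pairs with < 3 complete
observations or zero genotype variance are skipped. The asymptotic p is the
slope t-test. The empirical p is the plain fraction of permutations with
|t_perm| > |t_obs| (zero is reportable; (k+1)/(n+1) smoothing is available
behind a flag). BH is applied within a scan over all tested pairs, on the
empirical p when permutations were run.

**Family-aware permutation.** Whole-family phenotype blocks are permuted
among families of identical size, then member labels are shuffled within
each family; samples without pedigree information form singleton blocks.
This preserves the within-family correlation structure under the null, in
the spirit of family-based permutation tests (PLINK QFAM); the exact QFAM
between/within decomposition is not replicated, and no equivalence is
asserted. Under a family-structured null (family-shared noise on every
CpG), empirical p-values are uniform: the acceptance suite checks the KS
statistic over > 1,000 pairs against the 1% critical value.

SNP QC: MAF from all non-missing samples pooled (kept iff MAF ≥ 0.05);
exact Hardy–Weinberg test (Levene–Haldane conditional distribution, summing
heterozygote-count probabilities ≤ the observed configuration's) computed
on founders when a pedigree is available, kept iff p > 0.001 (strict).
Mendel errors are counted per SNP × trio as genotype combinations
impossible under one-allele-per-parent transmission.

## Allele-specific methylation

One 2×2 table (allele × methylated) per (sample, SNP, CpG) from fragment
records; fragments exist only where the sample is heterozygous. Two-sided
Fisher exact p by the point-probability rule (scipy), called with p < 0.001
and |Δ| > 0.2, both strict; Δ is computed from raw fractions, unsmoothed.
Tables with fewer than 5 fragments on either allele are skipped by default
(configurable down to 1): with fewer fragments the allele fractions are too
unstable to interpret as a methylation difference. Multiple CpGs on one
read are tested per-CpG, not pooled. Merging across individuals groups by
CpG, counts distinct supporting samples, and records whether all samples
agree on which allele is hypomethylated; merging is idempotent and
order-independent. Note that at the strict p < 0.001, the discrete Fisher
test needs roughly 25 fragments per allele to reach 99% detection of a
0.9-vs-0.1 allelic difference; at 15 per allele power is ≈ 93%.

## vSNPs and VMRs

Per cis pair, the sample variance of methylation within each genotype class
is regressed on the codes (0, 1, 2): slope = (v₂ − v₀)/2, t with 1 residual
df. Untestable when fewer than 3 classes are present or any class has fewer
than `min_group_n` = 3 samples (a variance needs ≥ 2 points; 3 adds
stability). Group variances are unweighted by default (class sizes differ;
the data model does not specify a weighting).

A three-point regression is intrinsically noisy, so single pairs are never
reported: a VMR is a maximal run of ≥ 5 CpGs, consecutive among the
*analyzed* CpGs, spaced ≤ 200 bp, all with |t| ≥ the cutoff and a shared
slope sign, for one SNP. The false positive rate of the whole procedure is
estimated by re-running it on matrices with permuted sample labels
(breaking genotype linkage, preserving per-CpG marginals; family-block
permutation is available via the mQTL machinery but the global shuffle is
the default exchangeable null). The t cutoff defaults to calibration: scan
a fixed grid (1.5 … 12) from permissive to strict and take the first cutoff
whose estimated FPR (mean permuted calls / observed calls) is ≤ 0.10. When
no cutoff meets the target — typical when few VMRs exist and one spurious
permuted call dominates the ratio — the calibration returns the cutoff with
the smallest estimated FPR among those still producing calls (ties toward
the stricter cutoff), because a cutoff that calls nothing controls FPR only
vacuously. When nothing is called anywhere, the most permissive grid value
is returned. VMRs whose spans lie within 100 kb edge-to-edge (inclusive)
merge into clusters by single linkage; overlapping VMRs driven by different
vSNPs merge deliberately.

## Comparison and annotation

CpG sets are keyed by (chrom, 1-based C position); overlap fractions with
empty denominators are NaN, never 0. Distance histograms bin |SNP − CpG|
with inclusive upper edges; a distance beyond the last edge is a window
violation and an error. For region annotation, a CpG at 1-based position p
becomes the 0-based half-open interval [p−1, p), so a CpG at a BED interval
start is inside and at its end is outside; a CpG overlapping several labels
counts once per label, and a CpG overlapping none gets the fallback label
(default "intergenic"). Enrichment is the ratio of label shares,
significant over background; labels with zero background share are
undefined. The label vocabulary is supplied by the user's BED, not
hard-coded.

## Synthetic cohorts

The generator emulates the structure of a padlock-probe family methylome
study: 22 nuclear families with 2–3 children (96 samples, 52 trios) by
default; founders drawn in Hardy–Weinberg proportions at per-SNP MAFs
uniform on a configurable range; children inheriting one allele per parent
uniformly (zero Mendel errors by construction). Per sample and CpG,

    latent = baseline + Σ cis β·dosage + family noise + residual noise,

clamped to [0, 1]; at SNP-CpG sites the observed latent is scaled by
(2 − dosage)/2; observed fractions are Binomial(depth, latent)/depth with
per-cell Poisson depth, or exactly the latent in infinite-depth mode
(`read_depth=None`), which exists for analytic tests. Baselines are
Beta-distributed (default Beta(2, 2): the analyses operate on variable,
intermediate-methylation CpGs). The default residual SD of 0.15 makes
unplanted CpGs pass the SD ≥ 0.1 variability filter, as the analyzed sites
in such a study do. Family noise is drawn once per family per designated
CpG — a heritable but non-genetic signal class that MPO should find and
SNP-based mapping should not. vSNP blocks replace the residual SD with a
per-genotype-class SD over a run of consecutive CpGs laid out at 100 bp
spacing. Fragment simulation emits `depth` fragments per heterozygous
(sample, SNP) at each effect CpG, allele fair, methylation Bernoulli with
the allele's probability (for a cis effect β per allele, the haploid
probabilities are baseline and baseline + 2β, consistent with the diploid
mean; for a SNP-CpG the alt-allele probability is 0).

Randomness is split into one `numpy` Generator stream per (stage, seed) —
layout, MAF, pedigree, genotypes, methylome, fragments — so enlarging one
stage never perturbs another, and everything is bit-reproducible given the
seed.

What the generator does **not** emulate: bisulfite conversion errors,
sequence-level reads, imprinting/parent-of-origin effects, cell-composition
heterogeneity, LD between SNPs, trans effects, and genome-scale site
counts. Passing tests therefore demonstrate correct recovery of the planted
generative classes at desk scale, not the study's genome-wide tallies,
which depend on a real cohort.

## Problem sizes and determinism

The test and acceptance workloads use deliberately small cohorts chosen as
the smallest sizes at which each statistical check is informative: 200
replicate cohorts of 52 trios at depth 100 for MPO recovery; ~1,200 null
pairs × 200 permutations for mQTL calibration and 40 replicates × 1,000
permutations for power; 30 replicate 200-sample cohorts for VMR recovery.
The pipeline stamps every output with a configuration hash and derives
per-stage seeds from the base seed, so identical inputs and configuration
give byte-identical outputs (asserted in the suite).

## Known limitations

* The MPO stage ignores familial correlation between trios sharing parents;
  h² estimates for family-correlated non-genetic signals are positively
  biased by design (that is what distinguishes MPO from the SNP-based
  methods).
* The variance regression's 1-df t-score is a screening statistic, not a
  calibrated test; all inference is deferred to the permutation FPR.
* The exact HWE filter on founders assumes the founders are unrelated.
* Empirical p-values at n_perm permutations are granular at 1/n_perm;
  BH on them is conservative near zero.
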