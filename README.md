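# pedmeth

Genome–methylome interaction analysis in nuclear pedigrees.

`pedmeth` treats CpG methylation (a fraction in [0, 1] measured by targeted
bisulfite sequencing) as a quantitative trait in family cohorts and asks, in
four complementary ways, how much of its inter-individual variability is
genetic:

1. **Mid-parent–offspring (MPO) heritability.** For each CpG, the child's
   methylation is regressed on the mean of its two parents across all
   complete trios; the OLS slope estimates the narrow-sense heritability
   h². A CpG is called heritable when h² > 0.2 with at least 10
   contributing trios and a Benjamini–Hochberg q < 0.05. Heritable CpGs
   whose dinucleotide itself carries a polymorphic SNP (the C or the G
   position) are classified as *SNP-CpGs*: one allele destroys the
   methyltransferase substrate, so each alt allele contributes zero
   methylation.
2. **cis-mQTL mapping.** Every CpG–SNP pair within 1 Mb is tested by
   least-squares regression of methylation on additive allele dosage
   (0/1/2). SNPs pass QC at MAF ≥ 0.05 and exact Hardy–Weinberg p > 0.001,
   with a Mendel-error report over all trios. Because family members are
   correlated, empirical p-values come from permutations that shuffle
   whole-family phenotype blocks among families of equal size and then
   member labels within families; BH FDR is applied over all tested pairs.
3. **Allele-specific methylation (ASM).** Within a single heterozygous
   individual, read fragments spanning both the SNP and a CpG are tallied
   into a 2×2 allele × methylation table; ASM is called when the two-sided
   Fisher exact p < 0.001 and the between-allele methylation difference
   exceeds 0.2. Events are merged across individuals with support counts
   and direction-consistency flags.
4. **Variance-QTLs (vSNPs) and variably methylated regions (VMRs).** Some
   SNPs modulate the *variance* rather than the mean of nearby methylation.
   Per cis pair, the methylation variance within each genotype class
   (AA/AB/BB) is regressed on the genotype code; because each regression
   has only three points, a VMR requires ≥ 5 adjacent CpGs (≤ 200 bp
   spacing) agreeing in direction, with the t cutoff calibrated so the
   permutation-estimated false positive rate stays ≤ 10%. VMRs within
   100 kb are grouped into clusters.

A synthetic cohort generator (`pedmeth.synthetic`) emulates the structure
of such a study — 22 nuclear families, 96 samples, 52 parent–child trios,
Hardy–Weinberg founders, Mendelian transmission, binomial read-depth noise —
and plants SNP-CpGs, cis effects, vSNP blocks and family-shared non-genetic
noise with recorded ground truth, so every stage has a parameter-recovery
test surface without any external download.

## Worked example

The `analysis/` scripts run the full study on a simulated cohort, writing
tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_qc_filter.py
python analysis/03_heritability_mpo.py
python analysis/04_mqtl_scan.py
python analysis/05_allele_specific_methylation.py
python analysis/06_variance_qtl.py
python analysis/07_compare_annotate.py
```

Script 01 simulates 96 samples in 22 families (52 trios), 30 SNPs and 80
CpGs, planting 3 SNP-CpGs, 3 cis effects, one 8-CpG vSNP block and 4
family-noise CpGs. The downstream stages then report, among other lines:

```
4 heritable CpGs of 73 analyzed (2 SNP-CpGs, 2 non-SNP)
91 cis pairs tested; 8 significant at FDR < 0.05
74 ASM events from 262 testable tables across 53 samples
1 VMRs in 1 clusters; permutation FPR estimate 0.000
planted vSNP snp6 recovered: yes (8/8 block CpGs)
```

i.e. the trio regression picks up the planted SNP-CpGs, one cis effect and
one family-noise CpG (family-shared signal is heritable to MPO but
invisible to SNP-based mapping); the mQTL scan finds the cis and SNP-CpG
pairs; ASM detects the allele-specific sites in heterozygous carriers; and
the variance scan recovers the full planted vSNP block. At this desk scale
the counts are small — the point of the cohort is recovery of known truth,
not genome-wide tallies.

The same pipeline runs as one command over standard file formats
(VCF + FAM + methylation TSV, optional fragment TSV and BED):

```bash
pedmeth simulate --out-dir demo
pedmeth run-all --vcf demo/genotypes.vcf --fam demo/pedigree.fam \
    --meth demo/methylation.tsv --frags demo/fragments.tsv --out-dir out
```

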