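# panelassoc

Case-control association analysis for candidate-gene SNP panels.

`panelassoc` implements the full analysis workflow of a small-panel
case-control genetic association study — the kind of design that genotypes a
few hundred variants in a set of candidate genes on several hundred cases
and controls and asks which variants, and which two-SNP genotype
combinations, separate the groups. It covers:

* **Data model & IO** — genotype matrices coded as minor-allele dosage
  (0/1/2, explicit missing sentinel) with readers/writers for PLINK text
  `.ped`/`.map`, minimal GT-only VCF, and per-SNP genotype-count tables
  (the form in which published studies print their data).
* **Sample filtering** — duplicate/relative detection by method-of-moments
  identity-by-descent (PI_HAT = P(IBD=1)/2 + P(IBD=2), exclusion at
  PI_HAT > 0.25), and ancestry structure by classical MDS of IBS distances
  with bivariate-normal density outlier removal on a chosen component pair.
* **Variant QC** — control-sample MAF (< 0.05), call rate (< 0.94),
  Hardy–Weinberg exact test, and greedy r² > 0.994 redundancy pruning, with
  filter-by-filter accounting.
* **LD** — pairwise D′ and r² via EM haplotype-frequency estimation from
  unphased genotypes, profile-likelihood D′ confidence bounds, and
  Gabriel-style block calling with the 0.7–0.98 CI rule.
* **Single-SNP association** — dominant / recessive / genotypic / allelic
  tests (Pearson chi-square without continuity correction), odds ratios
  with Woolf confidence intervals, a max(dominant, recessive) permutation
  test, a logistic-regression cross-check, and family-wise max-T
  permutation correction.
* **Conditional two-SNP analysis** — stratify on a test SNP's three
  genotypes, run the genotypic test of a target SNP within each stratum,
  sum the stratum chi-squares and degrees of freedom, and correct the full
  (test × target) scan by min-P permutation; plus odds ratios for flagged
  genotype combinations.
* **Synthetic data** — a seeded generator producing cohorts with the
  structure the analysis assumes (HWE controls, LD blocks, penetrance-model
  effect variants with exact population odds ratios, duplicates, relative
  pairs, ancestry outliers, missingness), so the whole pipeline is testable
  without access to subject-level data.

## The statistics in brief

For a genotype-count row (hom-minor / het / hom-major in cases and
controls), the dominant model collapses to carriers-vs-noncarriers and the
recessive model to minor-homozygotes-vs-rest. The test is the uncorrected
Pearson chi-square on the collapsed 2×2 table, and the effect estimate is

    OR = ad / bc,   95% CI = exp( ln OR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) )

(Woolf). Multiple testing across a panel is controlled family-wise by
permuting phenotype labels and comparing each observed statistic to the
permutation distribution of the experiment-wide maximum (max-T). The
conditional two-SNP statistic is the sum of the three within-stratum
genotypic chi-squares with summed degrees of freedom, referred to the
chi-square upper tail.

## Worked example

The package ships a seven-row genotype-count table of top association
signals as a fixture. Count-table mode recomputes every row's test:

```bash
panelassoc table2
```

```text
snp	chrom	pos	gene	test	case_counts	control_counts	p	OR	ci_low	ci_high
rs885863	7	159028278	VIPR2	R	56/219/159	31/59/48	0.00644630	0.511350	0.313754	0.833389
rs3113275	7	70514208	AUTS2	R	30/151/249	1/54/80	0.00550747	10.0500	1.35748	74.4045
rs11764092	7	70732598	AUTS2	D	15/145/273	3/31/104	0.00782244	1.79272	1.16200	2.76578
rs135763	22	38312399	CSNK1E	D	16/103/316	4/51/82	0.00454590	0.561450	0.375821	0.838766
rs1534891	22	38299094	CSNK1E	D	12/96/327	5/45/88	0.00900075	0.581284	0.385911	0.875568
rs80136044	2	238274081	PER2	D	7/101/327	1/17/120	0.00358946	2.20183	1.28176	3.78236
rs3754729	2	238241585	PER2/HES6	D	41/202/189	12/47/78	0.00705186	1.69976	1.15321	2.50533
```

Reading the first row: under the recessive model, 56 of 434 cases but 31 of
138 controls are minor-allele homozygotes, giving chi² p = 0.0064 and
OR = 0.51 (95% CI 0.31–0.83) — minor-allele homozygosity is about half as
common in cases. A full matrix-mode run goes through
`panelassoc run-all --ped ... --map ... --out-dir ...` or the library call
`panelassoc.run_full(matrix, PipelineConfig(...))`, which emits the QC
accounting, association table, LD blocks, MDS coordinates and the
conditional scan.

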