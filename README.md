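# strainscan

Downstream whole-genome-sequencing analysis for cohorts of CRISPR/Cas9-edited
haploid yeast strains: library-quality control from per-base coverage, cohort
variant filtering and mutant-allele-frequency (MAF) classification, and
attribution (or exoneration) of private variants as Cas9 off-target edits by
windowed best-match Levenshtein scanning. A synthetic-cohort generator with
the same statistical structure makes every stage testable without sequencing
data.

## Who it is for

Groups that sequence panels of edited strains (one guide per strain, haploid
genotyping) and need to answer, per strain: did the designed edit land, which
variants are shared background versus strain-private, and do any private
variants look like Cas9 off-target activity rather than spontaneous mutation.

## The method

**Coverage QC.** For depth track $c_b$ over a genome of $L$ bases, the bias
ratio at base $b$ is $r_b = c_b / \bar c$ with $\bar c = \sum_b c_b / L$; the
bias profile reports quantiles of $r_b$ and conserves $\langle r_b\rangle=1$.
Breadth at depth $k$ is $|\{b: c_b \ge k\}|/L$ (the usual "fraction covered
≥ 8×"). A per-base GC covariate is the mean GC fraction of the 500 bp
windows (stepped by 250 bp) covering each base, correlated with depth by
Spearman's ρ over a seeded subsample of up to 100,000 positions.

**Cohort filtering and classification.** Sites are hard-filtered on caller
annotations with the standard expression
`QD < 2.0 || FS > 60.0 || MQ < 40.0 || SOR > 3.0 || MQRankSum < -12.5 || ReadPosRankSum < -8.0`
(absent annotations never trigger; inequalities are strict). Cohort filters
then mask any genotype whose depth is below 0.1× its sample's average
coverage and drop records missing in ≥ 2 samples. MAF is the fraction of
non-reference alleles among non-missing haploid genotypes; a variant is
BACKGROUND iff MAF = 1, PRIVATE iff ALT in exactly one strain, SHARED
otherwise, with ON_TARGET overriding at declared designed-edit loci.
SNP-calling TPR is correctly-called/total-truth and FPR is
miscalled/total-called against a gold-standard SNP set.

**Off-target attribution.** For each private variant, a window of
$60 + X$ bp ($X$ = variant length) centred on the variant is scanned on both
strands for the strain's 23-nt target (20-nt protospacer + 3-nt PAM). The
score is the *infix* (semi-global) Levenshtein distance — the minimum edit
distance between the full target and any substring of the window, computed
by a DP whose first row is zero. Distances are compared against those of
experimentally captured on/off-target pairs (the CIRCLE-seq regime, 0–6);
unrelated windows typically score ≥ 7, so low-distance private variants are
the plausible off-target edits.

**Synthetic cohorts.** The generator plants a 16-strain cohort with 121
background variants, 107 private variants and 14 of 16 strains edited (the
shape of the reference dataset), simulates per-base depth from a
negative-binomial model with a log-linear GC effect and dropout intervals,
and can write an off-target-like site into the genome at a requested edit
distance — verified by brute force, so the planted distance is ground truth.

## Worked example

```bash
strainscan --seed 5 --out-dir demo simulate --n-strains 4 --n-background 10 \
    --n-private 8 --n-edited 3 --chrom-length 4000 --plant-offtarget 2
strainscan --out-dir demo classify --vcf demo/cohort.vcf \
    --guides demo/guides.tsv --avg-coverage demo/avg_coverage.tsv
strainscan --out-dir demo offtarget-scan --vcf demo/cohort.vcf \
    --genome demo/genome.fa --guides demo/guides.tsv
```

`demo/class_counts.tsv` then reads:

```
class	count
BACKGROUND	10
ON_TARGET	3
PRIVATE	9
SHARED	0
```

all 10 planted background variants are recovered at MAF = 1, the 3 edited
strains are verdict `edited` in `verdicts.tsv`, and the 9 private variants
are the 8 spontaneous ones plus the planted off-target site. `scan.tsv`
shows exactly one private variant at edit distance 2 (the planted site, the
`offtarget-scan` output echoes `scanned 9 private variants`); the rest score
in the unrelated-sequence regime (≥ 7).

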