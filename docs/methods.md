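# Methods

## Scope and data model

The package consumes the *outputs* of a standard short-read pipeline — a
reference FASTA, per-base depth tracks (TSV), and a multi-sample haploid VCF
with GATK-style site annotations — and performs the downstream analysis:
coverage QC, cohort filtering and classification, and off-target
attribution. Read trimming, alignment, duplicate marking, recalibration and
variant calling are deliberately out of scope; depth is consumed as TSV so
no BAM parsing is needed.

Internally all coordinates are 0-based half-open. VCF positions are shifted
by −1 on read and +1 on write; BED is consumed as-is. Haploid GT values map
`0`→REF, non-zero→ALT, `.`→MISSING; diploid records are tolerated
(`0/0`→REF, `1/1`→ALT) but heterozygous or half-missing calls become
MISSING with a warning, since aborting a haploid cohort analysis over stray
records would be worse than masking them. Multi-allelic sites are split into
one bi-allelic record per alternate allele, duplicating site annotations to
each child (a documented approximation); in the child for alternate *k*, a
sample carrying a different alternate is MISSING — it carries neither that
record's REF nor its ALT.

## Coverage QC

* **Bias profile.** Ratio of per-base depth to the genome-wide average;
  quantiles at 1/5/25/50/75/95/99%. The mean ratio is exactly 1 by
  construction, which the tests assert to 1e-9 as a conservation check.
* **Breadth.** Fraction of bases at or above a depth threshold; monotone
  non-increasing in the threshold, 1 at threshold 0.
* **Thinning.** Down-sampling is emulated at depth level by per-base
  binomial thinning (depth *d* → Binomial(*d*, *f*)). This preserves the
  shape of metric-versus-depth curves without read-level simulation;
  thinning composes multiplicatively in distribution.
* **GC covariate.** Window GC over 500 bp windows stepped by 250 bp;
  windows start at 0, 250, 500, …, and a trailing partial window is kept iff
  it is at least one step long (a chromosome shorter than a step gets one
  whole-chromosome window — the ends were a genuinely open choice). N bases
  are excluded from window denominators; N-only windows carry no
  information, and bases covered by no informative window get NaN rather
  than a fabricated value and are excluded from correlations.
* **Correlation.** Spearman by default (robust to the depth distribution's
  tail; Pearson available), over a single seeded draw of up to 100,000
  positions without replacement.
* **Insert sizes.** From a length→count histogram: median is the smallest
  length whose cumulative count reaches half the total; mode is the
  smallest length with maximal count.

## Cohort filtering and classification

Hard filters evaluate the six standard annotation clauses with strict
inequalities exactly as written (QD = 2.0 passes; QD < 2.0 fails); absent
annotations never trigger a clause, and each failing record is labelled with
the specific violated clauses. Cohort filtering masks genotypes whose known
depth falls below 0.1× that sample's own average coverage (per-sample, not
cohort-wide; unknown depth is exempt — absence of evidence is not treated as
low depth), *then* counts missingness and drops records missing in ≥ 2
samples. Masking-first is the stricter of the two possible orders and both
steps are logged with counts so the choice is auditable.

MAF = #ALT / (#ALT + #REF) over non-missing genotypes. Classification:
ON_TARGET at declared designed-edit loci (allele-aware when alleles are
declared, position-only otherwise), else BACKGROUND iff MAF = 1, else
PRIVATE iff exactly one ALT, else SHARED. Per-strain verdicts at the
designed edit: `edited` (ALT), `wild_type_at_target` (REF), `no_call`
(missing genotype or no record at the locus). TPR/FPR identify SNPs by
(chrom, pos, ref, alt); any called SNP not exactly matching a truth SNP is
miscalled, and indels are excluded from the rates (they are still
classified). With an empty call set FPR is defined as 0 with a warning.

## Off-target attribution

The score for a private variant is the minimum Levenshtein distance between
the strain's 23-nt target (protospacer + PAM, PAM included in the distance,
no PAM-anchoring constraint) and any substring of a (60+X) bp window around
the variant, X = max(|ref|, |alt|). Using the max guarantees the window
covers the full reference footprint of deletions and scales for insertions;
the 30 bp flanks sit around the reference-allele footprint, which fixes the
even/odd placement ambiguity for indels. Scanning uses the reference
sequence (not an alt-edited haplotype) on both strands; strand ties break
toward '+', end-position ties toward the leftmost, and the achieving
substring is reported. Reverse complement maps N→N, and windows containing
N are scanned as-is (N mismatches everything) with a flag.

The infix distance is computed by a semi-global DP with a free start (first
row all zeros) rather than by enumerating fixed-length 23-mers, which would
misprice indel-containing matches. The row recurrence is vectorised in
numpy; the insertion chain, which is a prefix dependency, is resolved
exactly as a running minimum of (tentative cost − column index). An
independent brute-force formulation — one anchored DP per substring start,
reading distances to all ends — backs both the test oracle and the
verification step of the off-target planter, and edlib's infix mode is used
as a third, external cross-check in tests only.

Reference on/off-target pair distances are computed on the sequences as
provided; an optional cleaning step strips non-ACGT characters (bulge
notation) but is off by default, since the provenance of such characters
varies by dataset. The comparison output reports per-distance counts for
both collections and a separation summary (minimum observed distance,
maximum reference distance, number of observed distances within the
reference range).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not the
sequencing process:

* **Genome.** I.i.d. bases at a configurable GC fraction (default 0.38,
  yeast-like). No repeats, no chromatin structure — so passing tests show
  the *algorithms* recover planted structure, not that real genomes lack
  confounders such as repeated sequence near guide sites.
* **Cohort.** Defaults mirror the reference dataset: 16 strains, 121
  background variants (ALT in all strains), 107 private variants spread
  across strains, 14 of 16 strains edited. Positions are sampled uniformly
  without replacement at ≥ 50 bp from any guide locus; roughly half the
  variants are 1–3 bp indels (the reference cohort was ≈ 53% indels), the
  rest SNPs with a uniformly chosen alternate base. Uniform placement is a
  modelling choice — no attempt is made to reproduce a spontaneous-mutation
  spectrum. Strains that are not edited simply have no variant record at
  their target locus (an all-REF row would not appear in a real cohort
  VCF), so their verdict is `no_call`.
* **Off-target planting.** A copy of the target corrupted by *d* random
  single-character edits is written into the genome ≥ 200 bp from the true
  locus, with a private SNP at its centre. Because random edits can cancel
  or create closer spurious matches, the planter verifies the window's true
  best-match distance by brute force on both strands and redraws (up to 100
  times) until the realised distance equals the intention; the returned
  distance is therefore ground truth.
* **Coverage.** Depth at base *b* is NB with mean
  μ_b = mean_depth · exp(gc_slope · (gc_b − genome_gc)) · dropout(b) and
  variance μ + a·μ² (a = overdispersion; a = 0 is the Poisson limit).
  Dropout intervals with a multiplicative factor in [0, 1] emulate
  rDNA-like coverage loss. Defaults: mean 20 (the cohort's sequencing
  depth), overdispersion 0.1 (mild, library-like), GC slope 0 unless set.
* **Calls.** Gold-standard scoring is exercised by retaining each truth SNP
  independently with probability TPR and adding a fixed number of novel
  miscalls at positions absent from truth.

All generators are deterministic functions of (parameters, seed).

## Problem sizes and numerical choices

Tests and the acceptance script run on 20–100 kb genomes: large enough for
binomial/Poisson concentration at the asserted tolerances (e.g. mean depth
within 1% at 100 kb, GC within ±0.03 at 10 kb) and for 250 planted variants
with the required spacing, while keeping the full suite in seconds. The GC
covariate is validated exactly (array-equal, NaN-aware) against a per-base
brute-force recomputation, which works because both paths compute each
window GC as the same integer ratio and average ≤ 2 covering windows in the
same order. Stochastic recovery checks use 3-standard-deviation bands from
the exact binomial null rather than tuned tolerances.

## Known limitations

* Site annotations (QD, FS, …) are not simulated from read data; filter
  logic is tested with user-supplied constants.
* Multi-allelic splitting duplicates site annotations to all child records.
* No mappability or repeat structure in synthetic genomes; spurious
  low-distance hits among spontaneous private variants are rarer than they
  may be near real repeated sequence.
* The scanner considers only variant-centred windows, not a genome-wide
  off-target search, and applies no cleavage-activity model (no CFD/MIT
  scores) — pure edit distance.
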