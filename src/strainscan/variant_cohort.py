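"""Cohort variant filtering, MAF classification, and SNP-calling rates.

Implements the two-stage filtering used for haploid edited-strain cohorts —
per-site hard filters on caller annotations (QD, FS, MQ, SOR, MQRankSum,
ReadPosRankSum) and cohort-level filters (depth masking at 0.1× the sample's
average coverage, exclusion at ≥2 missing genotypes) — then classifies each
variant by mutant allele frequency: BACKGROUND (MAF = 1, the shared base
strain's differences from the reference), PRIVATE (ALT in exactly one
strain), SHARED otherwise, with ON_TARGET overriding at declared designed
edit loci. SNP-calling TPR/FPR are scored against a gold-standard set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from numbers import Real
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .formats_io import Genotype, VariantRecord

logger = logging.getLogger("strainscan")


@dataclass
class FilterExpression:
    """Hard-filter thresholds; a record fails iff a *present* annotation
    violates its clause (strict inequalities, exactly as printed)."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0

    def failing_clauses(self, record: VariantRecord) -> list[str]:
        clauses = (
            ("QD", "<", self.qd_min),
            ("FS", ">", self.fs_max),
            ("MQ", "<", self.mq_min),
            ("SOR", ">", self.sor_max),
            ("MQRankSum", "<", self.mq_rank_sum_min),
            ("ReadPosRankSum", "<", self.read_pos_rank_sum_min),
        )
        reasons = []
        for key, op, threshold in clauses:
            value = record.site_annotations.get(key)
            if value is None:
                continue
            if not isinstance(value, Real) or math.isnan(value):
                raise ValueError(
                    f"{record.vid}: non-numeric annotation {key}={value!r}"
                )
            if (op == "<" and value < threshold) or (op == ">" and value > threshold):
                reasons.append(f"{key}{op}{threshold:g}")
        return reasons


@dataclass
class CohortFilterConfig:
    """Cohort-level filters: genotypes at DP < depth_factor × that sample's
    average coverage are masked MISSING; records missing in ≥ max_missing
    samples are excluded."""

    depth_factor: float = 0.1
    max_missing: int = 2

    def __post_init__(self):
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be > 0")
        if self.max_missing < 1:
            raise ValueError("max_missing must be >= 1")


class VariantClass:
    BACKGROUND = "BACKGROUND"
    PRIVATE = "PRIVATE"
    SHARED = "SHARED"
    ON_TARGET = "ON_TARGET"


@dataclass
class ClassifiedVariant:
    record: VariantRecord
    maf: float
    variant_class: str

    @property
    def alt_strains(self) -> list[str]:
        return [
            s for s, g in self.record.genotypes.items() if g is Genotype.ALT
        ]


@dataclass(frozen=True)
class DesignedEdit:
    """A declared designed edit; alleles of None match any record at the locus."""

    strain: str
    chrom: str
    pos: int
    ref: str | None = None
    alt: str | None = None

    def matches(self, record: VariantRecord) -> bool:
        return (
            record.chrom == self.chrom
            and record.pos == self.pos
            and (self.ref is None or self.ref == record.ref)
            and (self.alt is None or self.alt == record.alt)
        )


@dataclass
class RatesResult:
    tpr: float
    fpr: float
    n_truth: int
    n_called: int
    n_correct: int
    n_miscalled: int


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_hard_filters(
    records: Sequence[VariantRecord],
    expression: FilterExpression | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Partition records into passing and failing (with violated clauses)."""
    expression = expression or FilterExpression()
    passing, failing = [], []
    for rec in records:
        reasons = expression.failing_clauses(rec)
        if reasons:
            failing.append((rec, reasons))
        else:
            passing.append(rec)
    logger.info("hard filters: %d pass, %d fail", len(passing), len(failing))
    return passing, failing


def apply_cohort_filters(
    records: Sequence[VariantRecord],
    sample_avg_coverage: Mapping[str, float],
    config: CohortFilterConfig | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Depth-mask genotypes, then drop records missing in too many samples.

    Masking happens first: a genotype whose known depth is below
    depth_factor × its sample's average coverage becomes MISSING (unknown
    depth is exempt). Records with MISSING count ≥ max_missing are then
    excluded. Returns the kept records (genotypes masked in place on copies)
    and the masked genotype matrix over kept records.
    """
    config = config or CohortFilterConfig()
    for rec in records:
        for s, d in rec.sample_depths.items():
            if d is not None and (
                s not in sample_avg_coverage or sample_avg_coverage[s] <= 0
            ):
                raise ValueError(
                    f"sample {s!r} has depth data but no positive average coverage"
                )
    kept: list[VariantRecord] = []
    n_masked = 0
    n_excluded = 0
    for rec in records:
        masked = rec.copy()
        for s, d in masked.sample_depths.items():
            if d is None:
                continue
            if d < config.depth_factor * sample_avg_coverage[s]:
                if masked.genotypes.get(s) is not Genotype.MISSING:
                    n_masked += 1
                masked.genotypes[s] = Genotype.MISSING
        n_missing = sum(
            1 for g in masked.genotypes.values() if g is Genotype.MISSING
        )
        if n_missing >= config.max_missing:
            n_excluded += 1
        else:
            kept.append(masked)
    logger.info(
        "cohort filters: masked %d genotypes, excluded %d of %d records",
        n_masked, n_excluded, len(records),
    )
    samples = list(records[0].genotypes) if records else []
    matrix = pd.DataFrame(
        [[rec.genotypes[s].value for s in samples] for rec in kept],
        index=[rec.vid for rec in kept],
        columns=samples,
    )
    return kept, matrix


# ---------------------------------------------------------------------------
# MAF and classification
# ---------------------------------------------------------------------------

def compute_maf(record: VariantRecord) -> float:
    """Fraction of non-reference alleles among non-missing genotypes."""
    n_alt = sum(1 for g in record.genotypes.values() if g is Genotype.ALT)
    n_ref = sum(1 for g in record.genotypes.values() if g is Genotype.REF)
    if n_alt + n_ref == 0:
        raise ValueError(f"{record.vid}: all genotypes missing")
    return n_alt / (n_alt + n_ref)


def classify_variants(
    records: Sequence[VariantRecord],
    designed_edits: Sequence[DesignedEdit] = (),
) -> tuple[list[ClassifiedVariant], dict[str, str], dict[str, int]]:
    """Classify records by MAF and privacy; verdict per strain at its edit locus.

    Returns (classified records, per-strain verdict, per-class counts).
    Verdicts: "edited" (strain is ALT at its designed edit), "wild_type_at_target"
    (record present, strain REF), "no_call" (no record at the locus, or the
    strain's genotype there is missing).
    """
    classified: list[ClassifiedVariant] = []
    for rec in records:
        maf = compute_maf(rec)
        n_alt = sum(1 for g in rec.genotypes.values() if g is Genotype.ALT)
        if any(e.matches(rec) for e in designed_edits):
            vclass = VariantClass.ON_TARGET
        elif maf == 1.0:
            vclass = VariantClass.BACKGROUND
        elif n_alt == 1:
            vclass = VariantClass.PRIVATE
        else:
            vclass = VariantClass.SHARED
        classified.append(ClassifiedVariant(record=rec, maf=maf, variant_class=vclass))

    verdicts: dict[str, str] = {}
    for edit in designed_edits:
        matching = [r for r in records if edit.matches(r)]
        if not matching:
            verdicts[edit.strain] = "no_call"
            continue
        gt = matching[0].genotypes.get(edit.strain, Genotype.MISSING)
        if gt is Genotype.ALT:
            verdicts[edit.strain] = "edited"
        elif gt is Genotype.REF:
            verdicts[edit.strain] = "wild_type_at_target"
        else:
            verdicts[edit.strain] = "no_call"

    counts = {c: 0 for c in (
        VariantClass.ON_TARGET, VariantClass.BACKGROUND,
        VariantClass.PRIVATE, VariantClass.SHARED,
    )}
    for cv in classified:
        counts[cv.variant_class] += 1
    logger.info("classification: %s; verdicts: %s", counts, verdicts)
    return classified, verdicts, counts


# ---------------------------------------------------------------------------
# SNP-calling rates
# ---------------------------------------------------------------------------

def _snp_keys(
    variants: Iterable[VariantRecord | tuple[str, int, str, str]]
) -> set[tuple[str, int, str, str]]:
    keys = set()
    for v in variants:
        key = v.key if isinstance(v, VariantRecord) else tuple(v)
        chrom, pos, ref, alt = key
        if len(ref) == 1 and len(alt) == 1 and ref != alt:
            keys.add((chrom, int(pos), ref, alt))
    return keys


def snp_calling_rates(
    called: Iterable[VariantRecord | tuple[str, int, str, str]],
    truth: Iterable[VariantRecord | tuple[str, int, str, str]],
) -> RatesResult:
    """TPR = correctly called / total true SNPs; FPR = miscalled / total called.

    SNPs are identified by (chrom, pos, ref, alt); indels are ignored. A call
    is miscalled when no truth SNP matches it exactly. With nothing called,
    FPR is defined as 0 with a warning.
    """
    truth_keys = _snp_keys(truth)
    if not truth_keys:
        raise ValueError("truth SNP set is empty")
    called_keys = _snp_keys(called)
    correct = called_keys & truth_keys
    miscalled = called_keys - truth_keys
    tpr = len(correct) / len(truth_keys)
    if called_keys:
        fpr = len(miscalled) / len(called_keys)
    else:
        logger.warning("snp_calling_rates: empty called set, FPR defined as 0")
        fpr = 0.0
    return RatesResult(
        tpr=tpr,
        fpr=fpr,
        n_truth=len(truth_keys),
        n_called=len(called_keys),
        n_correct=len(correct),
        n_miscalled=len(miscalled),
    )
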