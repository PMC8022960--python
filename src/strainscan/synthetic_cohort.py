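"""Synthetic strain cohorts with the statistical structure the analysis assumes.

Emulates a haploid yeast cohort of CRISPR-edited strains derived from a
common base strain: shared background variants (present in every strain,
MAF = 1), one designed on-target edit per strain at its guide locus,
strain-private spontaneous variants, and optional planted off-target-like
sites whose window carries a corrupted copy of a guide target at a
brute-force-verified edit distance. Coverage tracks are drawn from a
negative-binomial model with a log-linear GC effect, multiplicative dropout
intervals (rDNA-like), and controllable overdispersion.

All generators are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage_qc import gc_profile, genome_gc_fraction
from .formats_io import Genotype, VariantRecord
from .offtarget import (
    GuideTarget,
    brute_force_infix_distance,
    extract_window,
    reverse_complement,
)

logger = logging.getLogger("strainscan")

BASES = np.array(list("ACGT"))

#: Background/private variants keep this distance (bp) from any guide locus.
GUIDE_SPACING = 50
#: Planted off-target sites keep this distance (bp) from the true guide locus.
OFFTARGET_SPACING = 200


@dataclass
class CohortTruth:
    """Ground truth for a planted cohort, keyed the way the classifier reports."""

    strains: list[str]
    background_variants: list[VariantRecord]
    designed_edits: dict[str, VariantRecord]  # edited strains only
    private_variants: dict[str, list[VariantRecord]]
    planted_offtargets: list[tuple[str, VariantRecord, int]] = field(
        default_factory=list
    )
    guides: list[GuideTarget] = field(default_factory=list)

    def all_records(self) -> list[VariantRecord]:
        records = list(self.background_variants)
        records.extend(self.designed_edits.values())
        for recs in self.private_variants.values():
            records.extend(recs)
        records.extend(rec for _, rec, _ in self.planted_offtargets)
        return sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))

    def n_private(self) -> int:
        return sum(len(v) for v in self.private_variants.values()) + len(
            self.planted_offtargets
        )


@dataclass
class CoverageModel:
    """Per-base depth model: NB(mean × exp(gc_slope·(gc_b − genome_gc)) × dropout).

    ``overdispersion`` is the NB dispersion a in Var = μ + a·μ²; 0 gives the
    Poisson limit. ``dropout`` entries are (chrom, start, end, factor) with
    factor in [0, 1], multiplying expected depth inside the interval.
    """

    mean_depth: float
    gc_slope: float = 0.0
    dropout: Sequence[tuple[str, int, int, float]] = ()
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth < 0 or self.overdispersion < 0:
            raise ValueError("mean_depth and overdispersion must be non-negative")
        for chrom, start, end, factor in self.dropout:
            if not 0 <= factor <= 1:
                raise ValueError("dropout factor must be in [0, 1]")
            if end <= start:
                raise ValueError(f"dropout interval {chrom}:{start}-{end} is empty")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(
    n_chroms: int,
    lengths: Sequence[int] | int,
    gc_content: float = 0.38,
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. random genome with P(G)+P(C) = gc_content, split equally."""
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    if isinstance(lengths, int):
        lengths = [lengths] * n_chroms
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    if any(l < 1000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    return {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=length, p=p))
        for i, length in enumerate(lengths)
    }


# ---------------------------------------------------------------------------
# Cohort planting
# ---------------------------------------------------------------------------

def design_guides(
    genome: Mapping[str, str], strains: Sequence[str], seed: int = 0
) -> list[GuideTarget]:
    """One guide per strain at a random locus, 23-mer taken from the genome.

    Loci are spaced at least 2×GUIDE_SPACING apart and kept away from
    chromosome ends so scan windows are never truncated.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    guides: list[GuideTarget] = []
    taken: list[tuple[str, int]] = []
    margin = 60
    for strain in strains:
        for _ in range(1000):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(margin, len(genome[chrom]) - margin - 23))
            if any(c == chrom and abs(p - pos) < 2 * GUIDE_SPACING for c, p in taken):
                continue
            site = genome[chrom][pos : pos + 23]
            if "N" in site:
                continue
            taken.append((chrom, pos))
            guides.append(
                GuideTarget(
                    strain=strain,
                    protospacer=site[:20],
                    pam=site[20:],
                    chrom=chrom,
                    pos=pos,
                )
            )
            break
        else:
            raise ValueError("could not place guides; genome too small")
    return guides


def _random_variant(
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    rng: np.random.Generator,
    indel: bool,
    max_indel: int = 3,
) -> tuple[str, str]:
    """(ref, alt) alleles for a SNP or a 1–3 bp indel anchored at pos."""
    base = genome[chrom][pos]
    if not indel:
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        return base, alt
    k = int(rng.integers(1, max_indel + 1))
    if rng.random() < 0.5 and pos + 1 + k <= len(genome[chrom]):
        return genome[chrom][pos : pos + 1 + k], base  # deletion
    ins = "".join(rng.choice(BASES, size=k))
    return base, base + ins  # insertion


def _make_record(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    strains: Sequence[str],
    alt_strains: set[str],
    depth: int | None,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={
            s: (Genotype.ALT if s in alt_strains else Genotype.REF) for s in strains
        },
        sample_depths={s: depth for s in strains},
    )


def plant_cohort(
    genome: Mapping[str, str],
    n_strains: int = 16,
    n_background: int = 121,
    n_private_per_strain: Sequence[int] | int | None = None,
    guides: Sequence[GuideTarget] | None = None,
    seed: int = 0,
    indel_fraction: float = 0.5,
    n_edited: int | None = None,
    default_depth: int | None = 20,
) -> CohortTruth:
    """Plant a cohort: shared background, designed edits, private variants.

    Defaults mirror the reference cohort shape: 16 strains, 121 background
    variants (ALT in every strain), 107 private variants spread over strains,
    14 of 16 strains carrying their designed edit. Variant positions are
    sampled without replacement at least GUIDE_SPACING bp from any guide
    locus; about ``indel_fraction`` of the non-designed variants are 1–3 bp
    indels, the rest SNPs.
    """
    strains = [f"strain{i + 1:02d}" for i in range(n_strains)]
    if n_private_per_strain is None:
        total = 107
        base, extra = divmod(total, n_strains)
        n_private = [base + (1 if i < extra else 0) for i in range(n_strains)]
    elif isinstance(n_private_per_strain, int):
        n_private = [n_private_per_strain] * n_strains
    else:
        n_private = list(n_private_per_strain)
        if len(n_private) != n_strains:
            raise ValueError("need one private-variant count per strain")
    if n_edited is None:
        n_edited = min(14, n_strains)
    if n_edited > n_strains:
        raise ValueError("n_edited cannot exceed n_strains")

    rng = np.random.default_rng(seed)
    if guides is None:
        guides = design_guides(genome, strains, seed=int(rng.integers(2**31)))
    if len(guides) != n_strains:
        raise ValueError("need one guide per strain")
    loci = [(g.chrom, g.pos) for g in guides]
    if len(set(loci)) != len(loci):
        raise ValueError("two guides at the same locus")

    # candidate positions: away from guide loci and chromosome edges
    margin = 35  # scan windows of SNPs/indels stay in bounds
    candidates = []
    for chrom, seq in genome.items():
        near_guide = np.zeros(len(seq), dtype=bool)
        for gc_, gp in loci:
            if gc_ == chrom:
                near_guide[max(0, gp - GUIDE_SPACING) : gp + GUIDE_SPACING + 23] = True
        ok = ~near_guide
        ok[:margin] = False
        ok[-margin:] = False
        for p in np.flatnonzero(ok):
            candidates.append((chrom, int(p)))
    n_needed = n_background + sum(n_private)
    if n_needed > len(candidates):
        raise ValueError(
            f"cannot place {n_needed} variants without collisions; "
            "use a larger genome"
        )
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    positions = [candidates[i] for i in chosen]

    def new_record(chrom: str, pos: int, alt_strains: set[str]) -> VariantRecord:
        indel = bool(rng.random() < indel_fraction)
        ref, alt = _random_variant(genome, chrom, pos, rng, indel)
        return _make_record(chrom, pos, ref, alt, strains, alt_strains, default_depth)

    background = [
        new_record(c, p, set(strains)) for c, p in positions[:n_background]
    ]
    private: dict[str, list[VariantRecord]] = {s: [] for s in strains}
    cursor = n_background
    for strain, count in zip(strains, n_private):
        for c, p in positions[cursor : cursor + count]:
            private[strain].append(new_record(c, p, {strain}))
        cursor += count

    edited = list(strains[:n_edited])
    designed: dict[str, VariantRecord] = {}
    guide_by_strain = {g.strain: g for g in guides}
    for strain in edited:
        g = guide_by_strain[strain]
        ref, alt = _random_variant(genome, g.chrom, g.pos, rng, indel=False)
        designed[strain] = _make_record(
            g.chrom, g.pos, ref, alt, strains, {strain}, default_depth
        )

    logger.info(
        "plant_cohort: %d strains, %d background, %d private, %d edited (seed %d)",
        n_strains, n_background, sum(n_private), n_edited, seed,
    )
    return CohortTruth(
        strains=strains,
        background_variants=background,
        designed_edits=designed,
        private_variants=private,
        guides=list(guides),
    )


# ---------------------------------------------------------------------------
# Off-target planting
# ---------------------------------------------------------------------------

def _corrupt(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply n random single-character edits (sub/ins/del) to seq."""
    s = list(seq)
    for _ in range(n_edits):
        op = rng.integers(3)
        if op == 0 and s:  # substitution
            i = int(rng.integers(len(s)))
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
        elif op == 1:  # insertion
            i = int(rng.integers(len(s) + 1))
            s.insert(i, str(rng.choice(BASES)))
        elif s:  # deletion
            i = int(rng.integers(len(s)))
            del s[i]
    return "".join(s)


def _window_best_distance(genome: Mapping[str, str], variant, target: str) -> int:
    """Brute-force both-strand best-match distance of the variant's window."""
    window = extract_window(genome, variant)
    return min(
        brute_force_infix_distance(target, window.sequence),
        brute_force_infix_distance(target, reverse_complement(window.sequence)),
    )


def plant_offtarget_site(
    genome: Mapping[str, str],
    guide: GuideTarget,
    intended_distance: int,
    seed: int = 0,
    strains: Sequence[str] | None = None,
    max_redraws: int = 100,
) -> tuple[dict[str, str], VariantRecord, int]:
    """Write an off-target-like site into the genome and centre a private SNP on it.

    A corrupted copy of the guide's 23-nt target (``intended_distance`` random
    edits) replaces genome sequence at a random location ≥ 200 bp from the
    true guide locus; a private SNP is placed at its centre. The placement is
    VERIFIED by brute force: the scan window's true best-match distance (both
    strands) must equal the intended distance, redrawing up to ``max_redraws``
    times otherwise. The returned distance is the verified value, a ground
    truth rather than an intention.
    """
    if not 0 <= intended_distance <= 10:
        raise ValueError("intended_distance must be in 0..10")
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    target = guide.target23
    for _ in range(max_redraws):
        planted = _corrupt(target, intended_distance, rng)
        if not planted:
            continue
        chrom = chroms[rng.integers(len(chroms))]
        margin = 40
        lo, hi = margin, len(genome[chrom]) - margin - len(planted)
        if hi <= lo:
            continue
        loc = int(rng.integers(lo, hi))
        if chrom == guide.chrom and abs(loc - guide.pos) < OFFTARGET_SPACING:
            continue
        seq = genome[chrom]
        mutated = dict(genome)
        mutated[chrom] = seq[:loc] + planted + seq[loc + len(planted):]
        pos_v = loc + len(planted) // 2
        ref = mutated[chrom][pos_v]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        alt_strains = {guide.strain}
        record = _make_record(
            chrom, pos_v, ref, alt,
            strains if strains is not None else [guide.strain],
            alt_strains, 20,
        )
        realized = _window_best_distance(mutated, record, target)
        if realized == intended_distance:
            return mutated, record, realized
    raise ValueError(
        f"could not realise edit distance {intended_distance} in "
        f"{max_redraws} draws; genome too small or distance too large"
    )


# ---------------------------------------------------------------------------
# Coverage and call simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    genome: Mapping[str, str], model: CoverageModel
) -> dict[str, np.ndarray]:
    """Draw per-base depth tracks from the coverage model."""
    if model.mean_depth == 0:
        return {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.items()}
    rng = np.random.default_rng(model.seed)
    gc = gc_profile(genome)
    overall = genome_gc_fraction(genome)
    tracks: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        g = np.where(np.isnan(gc[chrom]), overall, gc[chrom])
        mu = model.mean_depth * np.exp(model.gc_slope * (g - overall))
        for dchrom, start, end, factor in model.dropout:
            if dchrom == chrom:
                mu[start:end] *= factor
        if model.overdispersion == 0:
            tracks[chrom] = rng.poisson(mu).astype(np.int64)
        else:
            n = 1.0 / model.overdispersion
            p = n / (n + mu)
            tracks[chrom] = rng.negative_binomial(n, p).astype(np.int64)
    return tracks


def simulate_calls(
    truth_snps: Sequence[tuple[str, int, str, str]],
    tpr: float,
    fpr_count: int,
    seed: int = 0,
    genome: Mapping[str, str] | None = None,
) -> set[tuple[str, int, str, str]]:
    """Retain each true SNP with probability tpr; add novel miscalled SNPs.

    Novel calls are placed at positions absent from the truth set and need a
    genome to sample from (required when ``fpr_count > 0``).
    """
    if not 0 <= tpr <= 1:
        raise ValueError("tpr must be in [0, 1]")
    if fpr_count < 0:
        raise ValueError("fpr_count must be >= 0")
    rng = np.random.default_rng(seed)
    truth = [tuple(t) for t in truth_snps]
    keep = rng.random(len(truth)) < tpr
    called = {t for t, k in zip(truth, keep) if k}
    if fpr_count:
        if genome is None:
            raise ValueError("a genome is required to place miscalled SNPs")
        truth_pos = {(c, p) for c, p, _, _ in truth}
        chroms = list(genome)
        added = 0
        while added < fpr_count:
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(len(genome[chrom])))
            if (chrom, pos) in truth_pos:
                continue
            ref = genome[chrom][pos]
            if ref not in "ACGT":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            if (chrom, pos, ref, alt) in called:
                continue
            called.add((chrom, pos, ref, alt))
            truth_pos.add((chrom, pos))
            added += 1
    return called
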