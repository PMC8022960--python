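"""File formats and domain containers shared across the pipeline.

Internal coordinate convention: 0-based, half-open everywhere. VCF positions
are converted on read (−1) and on write (+1); BED intervals are consumed
as-is. Genomes are plain ``{chrom: sequence}`` mappings with uppercase
sequences over ``{A, C, G, T, N}``; coverage tracks are ``{chrom: int array}``
mappings aligned base-for-base with the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

logger = logging.getLogger("strainscan")

#: INFO annotations consumed by the hard-filter expression.
ANNOTATION_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")

VALID_BASES = frozenset("ACGTN")


def configure_logging(level: str = "INFO") -> None:
    """Configure the package logger once, with a plain stderr handler."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class Genotype(Enum):
    """Haploid genotype call for one sample at one site."""

    REF = "REF"
    ALT = "ALT"
    MISSING = "MISSING"


@dataclass
class VariantRecord:
    """One bi-allelic variant call across a haploid cohort.

    ``pos`` is the 0-based position of the first reference base.
    ``sample_depths`` entries of ``None`` mean depth unknown (exempt from
    depth-based masking). Records from multi-allelic sites are split, one per
    alternate allele, sharing position and site annotations.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_annotations: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    sample_depths: dict[str, int | None] = field(default_factory=dict)

    @property
    def variant_type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1 and self.ref != self.alt:
            return "SNP"
        return "INDEL"

    @property
    def variant_length(self) -> int:
        """X, the variant length: max of the two allele lengths (≥ 1)."""
        return max(len(self.ref), len(self.alt))

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def copy(self) -> "VariantRecord":
        return replace(
            self,
            site_annotations=dict(self.site_annotations),
            genotypes=dict(self.genotypes),
            sample_depths=dict(self.sample_depths),
        )


@dataclass
class AnnotationIntervals:
    """A named category of genomic intervals (0-based half-open)."""

    category_name: str
    intervals: list[tuple[str, int, int]]

    def validate(self, genome: Mapping[str, str]) -> None:
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(
                    f"interval {chrom}:{start}-{end} in category "
                    f"{self.category_name!r} has end <= start"
                )
            if chrom not in genome or end > len(genome[chrom]):
                raise ValueError(
                    f"interval {chrom}:{start}-{end} outside genome bounds"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into ``{chrom: uppercase sequence}``.

    Characters outside {A,C,G,T,N} are replaced by N with a logged warning;
    duplicate chromosome names and empty files are hard errors.
    """
    genome: dict[str, str] = {}
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for chromosome {rec.id!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            for ch in bad:
                n_replaced += seq.count(ch)
                seq = seq.replace(ch, "N")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no sequences found in FASTA {path}")
    if n_replaced:
        logger.warning(
            "read_fasta: replaced %d non-ACGTN characters with N", n_replaced
        )
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_from_alleles(
    alleles: Sequence[int], alt_index: int, record_id: str
) -> tuple[Genotype, bool]:
    """Map cyvcf2 allele indices to a haploid genotype for one split record.

    Returns (genotype, warned). In the child record for alternate allele
    ``alt_index`` (1-based), allele 0 maps to REF, allele ``alt_index`` to
    ALT, any other non-missing allele to MISSING (the sample carries a
    different alternate). Heterozygous diploid calls map to MISSING with a
    warning, as the cohort model is haploid.
    """
    alleles = [a for a in alleles]
    if len(alleles) == 1:
        a = alleles[0]
        if a < 0:
            return Genotype.MISSING, False
    elif len(alleles) == 2:
        a1, a2 = alleles
        if a1 < 0 and a2 < 0:
            logger.warning("%s: missing diploid genotype ./., set MISSING", record_id)
            return Genotype.MISSING, True
        if a1 != a2:
            logger.warning(
                "%s: heterozygous genotype %s/%s in haploid cohort, set MISSING",
                record_id, a1, a2,
            )
            return Genotype.MISSING, True
        a = a1
    else:
        raise ValueError(f"{record_id}: malformed genotype with ploidy {len(alleles)}")
    if a == 0:
        return Genotype.REF, False
    if a == alt_index:
        return Genotype.ALT, False
    return Genotype.MISSING, False


def read_vcf_cohort(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample haploid VCF into split bi-allelic records.

    Multi-allelic sites yield one record per alternate allele, duplicating
    site annotations. Per-sample DP, when absent, is stored as ``None`` and
    treated as unknown downstream.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for rec in vcf:
        annotations = {}
        for key in ANNOTATION_KEYS:
            value = rec.INFO.get(key)
            if value is not None:
                annotations[key] = float(value)
        dp = rec.format("DP")
        depths: list[int | None]
        if dp is None:
            depths = [None] * len(samples)
        else:
            depths = [
                None if int(d) < 0 else int(d) for d in np.asarray(dp).reshape(-1)
            ]
        genotypes = rec.genotypes
        if genotypes is None or len(genotypes) != len(samples):
            raise ValueError(f"{rec.CHROM}:{rec.POS}: malformed or absent GT field")
        for alt_index, alt in enumerate(rec.ALT, start=1):
            record_id = f"{rec.CHROM}:{rec.POS}:{rec.REF}>{alt}"
            gts: dict[str, Genotype] = {}
            for sample, g in zip(samples, genotypes):
                gt, _ = _genotype_from_alleles(g[:-1], alt_index, record_id)
                gts[sample] = gt
            records.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS - 1,
                    ref=rec.REF,
                    alt=str(alt),
                    site_annotations=dict(annotations),
                    genotypes=gts,
                    sample_depths={s: d for s, d in zip(samples, depths)},
                )
            )
    logger.info("read_vcf_cohort: %d records, %d samples from %s",
                len(records), len(samples), path)
    return records, samples


def write_vcf_cohort(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write split bi-allelic records as a VCF v4.2 text file.

    Haploid GT encoding: REF→``0``, ALT→``1``, MISSING→``.``; DP ``.`` when
    unknown. Records are sorted by (chrom, pos, alt).
    """
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    for key in ANNOTATION_KEYS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    gt_code = {Genotype.REF: "0", Genotype.ALT: "1", Genotype.MISSING: "."}
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        if rec.site_annotations:
            info = ";".join(
                f"{k}={rec.site_annotations[k]:g}"
                for k in ANNOTATION_KEYS
                if k in rec.site_annotations
            )
        else:
            info = "."
        cells = []
        for s in samples:
            d = rec.sample_depths.get(s)
            cells.append(
                f"{gt_code[rec.genotypes.get(s, Genotype.MISSING)]}:"
                f"{'.' if d is None else d}"
            )
        lines.append(
            f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}"
            f"\tGT:DP\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Depth tracks (TSV: chrom, 1-based pos, depth)
# ---------------------------------------------------------------------------

def read_depth_tsv(
    path: str | Path, genome: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Read a sparse per-base depth TSV into dense tracks over the genome.

    Unlisted positions get depth 0. Positions beyond chromosome length and
    negative depths are hard errors; an empty file yields all-zero tracks
    with a warning.
    """
    tracks = {name: np.zeros(len(seq), dtype=np.int64) for name, seq in genome.items()}
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "pos", "depth"])
    if df.empty:
        logger.warning("read_depth_tsv: empty file %s, all-zero tracks", path)
        return tracks
    if (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise ValueError(
            f"negative depth {bad.depth} at {bad.chrom}:{bad.pos} in {path}"
        )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in tracks:
            raise ValueError(f"unknown chromosome {chrom!r} in depth TSV {path}")
        idx = sub["pos"].to_numpy() - 1
        if (idx < 0).any() or (idx >= len(tracks[chrom])).any():
            raise ValueError(
                f"position out of bounds for chromosome {chrom!r} "
                f"(length {len(tracks[chrom])}) in {path}"
            )
        tracks[chrom][idx] = sub["depth"].to_numpy()
    return tracks


def write_depth_tsv(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write depth tracks sparsely (non-zero positions only, 1-based)."""
    with open(path, "w") as fh:
        for chrom in tracks:
            depth = np.asarray(tracks[chrom])
            (nz,) = np.nonzero(depth)
            for i in nz:
                fh.write(f"{chrom}\t{i + 1}\t{depth[i]}\n")


# ---------------------------------------------------------------------------
# BED, guides, insert sizes, sequence pairs
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[AnnotationIntervals]:
    """Read BED3+name into per-category interval sets (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
    )
    out = []
    for name, sub in df.groupby("name", sort=False):
        out.append(
            AnnotationIntervals(
                category_name=str(name),
                intervals=[
                    (r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()
                ],
            )
        )
    return out


def write_bed(categories: Sequence[AnnotationIntervals], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cat in categories:
            for chrom, start, end in cat.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{cat.category_name}\n")


def read_guide_tsv(path: str | Path):
    """Read guide targets (strain, protospacer, pam, chrom, pos, strand).

    ``pos`` in the file is 1-based; returned loci are 0-based.
    """
    from .offtarget import GuideTarget

    df = pd.read_csv(
        path, sep="\t", header=0,
        dtype={"strain": str, "protospacer": str, "pam": str,
               "chrom": str, "pos": np.int64, "strand": str},
    )
    return [
        GuideTarget(
            strain=r.strain,
            protospacer=r.protospacer.upper(),
            pam=r.pam.upper(),
            chrom=r.chrom,
            pos=int(r.pos) - 1,
            strand=r.strand,
        )
        for r in df.itertuples()
    ]


def write_guide_tsv(guides, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tprotospacer\tpam\tchrom\tpos\tstrand\n")
        for g in guides:
            fh.write(
                f"{g.strain}\t{g.protospacer}\t{g.pam}\t{g.chrom}\t{g.pos + 1}\t{g.strand}\n"
            )


def read_insert_size_tsv(path: str | Path) -> dict[int, int]:
    """Read an insert-size histogram TSV (length, count)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["length", "count"],
        dtype={"length": np.int64, "count": np.int64},
    )
    if (df["length"] <= 0).any() or (df["count"] < 0).any():
        raise ValueError(f"invalid insert-size histogram in {path}")
    return dict(zip(df["length"].tolist(), df["count"].tolist()))


def read_pairs_tsv(path: str | Path):
    """Read on/off-target sequence pairs (on_seq, off_seq[, read_count])."""
    from .offtarget import TargetPair

    df = pd.read_csv(path, sep="\t", header=0)
    if "on_seq" not in df.columns or "off_seq" not in df.columns:
        raise ValueError(f"pair TSV {path} must have columns on_seq, off_seq")
    pairs = []
    for r in df.itertuples():
        count = getattr(r, "read_count", None)
        pairs.append(
            TargetPair(
                on_sequence=str(r.on_seq).upper(),
                off_sequence=str(r.off_seq).upper(),
                read_count=None if count is None or pd.isna(count) else float(count),
            )
        )
    return pairs
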