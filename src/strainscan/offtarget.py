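"""Off-target attribution by windowed best-match Levenshtein scanning.

A Cas9 off-target edit should sit in sequence similar to the guide's target.
For each private variant we take a (60+X) bp window around it (X = variant
length), compute the minimum Levenshtein distance between the 23-nt target
(20-nt protospacer + 3-nt PAM) and *any substring* of the window on either
strand, and compare the resulting distances with those of experimentally
captured on/off-target sequence pairs. Genuine off-target sites fall in the
low-distance regime (0–6 for CIRCLE-seq pairs); unrelated sequence typically
scores 7 or higher against a 23-nt pattern in a ~61 bp window.

The best-match ("infix" / semi-global) distance is computed by a dynamic
program whose first row is all zeros, so an alignment may start at any text
position for free; the answer is the minimum of the final row, i.e. over all
substring end positions. Row updates are vectorised: the insertion chain
``new[j] = min(new[j-1]+1, t[j])`` is resolved as a prefix minimum of
``t[j]-j`` (each step right costs exactly 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import VariantRecord

logger = logging.getLogger("strainscan")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Flank width on each side of the variant footprint; window length = 2*FLANK + X.
FLANK = 30


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _dp_final_row(pattern: str, text: str, free_start: bool) -> np.ndarray:
    """Final row of the edit-distance DP of ``pattern`` (rows) vs ``text``.

    With ``free_start`` the first row is all zeros (alignment may begin at any
    text position); otherwise it is 0..len(text) (global-in-text prefix
    distances). Entry j of the result is the minimum edit distance between
    the full pattern and a substring of ``text`` ending at j (free start) or
    the prefix ``text[:j]`` (anchored start).
    """
    p = _as_codes(pattern)
    t = _as_codes(text)
    m, n = len(p), len(t)
    steps = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int64) if free_start else steps.copy()
    for i in range(1, m + 1):
        sub = prev[:-1] + (t != p[i - 1])
        tent = np.empty(n + 1, dtype=np.int64)
        tent[0] = i
        tent[1:] = np.minimum(prev[1:] + 1, sub)
        prev = np.minimum.accumulate(tent - steps) + steps
    return prev


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits transforming a into b."""
    if not a:
        return len(b)
    return int(_dp_final_row(a, b, free_start=False)[-1])


def infix_best_match(pattern: str, text: str) -> tuple[int, list[int]]:
    """Minimum Levenshtein distance of ``pattern`` to any substring of ``text``.

    Returns ``(distance, end_positions)`` where each end position j (0-based,
    exclusive) admits a substring ending at j that achieves the distance.
    Empty text yields ``(len(pattern), [0])`` — the only substring is empty.
    """
    if not pattern:
        raise ValueError("infix_best_match requires a non-empty pattern")
    if not text:
        return len(pattern), [0]
    row = _dp_final_row(pattern, text, free_start=True)
    best = int(row.min())
    ends = np.flatnonzero(row == best).tolist()
    return best, ends


def brute_force_infix_distance(pattern: str, text: str) -> int:
    """Exhaustive substring minimum, used as an independent check.

    For every start s, one anchored DP of pattern vs ``text[s:]`` yields the
    distances to all substrings starting at s; the result is the minimum over
    every (start, end) pair. Enumerates all O(n^2) substrings without using
    the free-start recurrence of :func:`infix_best_match`.
    """
    if not text:
        return len(pattern)
    best = len(pattern)
    for s in range(len(text)):
        row = _dp_final_row(pattern, text[s:], free_start=False)
        best = min(best, int(row.min()))
    return best


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideTarget:
    """A strain's CRISPR target: 20-nt protospacer + 3-nt PAM at a locus."""

    strain: str
    protospacer: str
    pam: str
    chrom: str
    pos: int  # 0-based position of the designed edit locus
    strand: str = "+"

    def __post_init__(self):
        if len(self.protospacer) != 20 or len(self.pam) != 3:
            raise ValueError(
                f"guide for {self.strain}: need 20-nt protospacer and 3-nt PAM, "
                f"got {len(self.protospacer)}/{len(self.pam)}"
            )
        if set(self.protospacer + self.pam) - set("ACGT"):
            raise ValueError(f"guide for {self.strain}: non-ACGT characters")

    @property
    def target23(self) -> str:
        return self.protospacer + self.pam


@dataclass
class ScanWindow:
    variant_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    truncated: bool = False


@dataclass
class ScanResult:
    variant_id: str
    best_distance: int
    strand: str
    match_start: int  # window-local coordinates of the achieving substring
    match_end: int
    best_match_sequence: str
    truncated: bool = False


@dataclass(frozen=True)
class TargetPair:
    """An on-target / captured off-target sequence pair."""

    on_sequence: str
    off_sequence: str
    read_count: float | None = None

    def __post_init__(self):
        if not self.on_sequence or not self.off_sequence:
            raise ValueError("pair sequences must be non-empty")


# ---------------------------------------------------------------------------
# Window extraction and scanning
# ---------------------------------------------------------------------------

def extract_window(genome: Mapping[str, str], variant: VariantRecord) -> ScanWindow:
    """The (60+X) bp scan window centred on a variant.

    X = max(|ref|, |alt|); the window spans the X reference bases starting at
    the variant position plus 30 bp flanks on each side, truncated (and
    flagged) at chromosome ends.
    """
    if variant.chrom not in genome:
        raise ValueError(f"{variant.vid}: unknown chromosome")
    chrom_len = len(genome[variant.chrom])
    if not (0 <= variant.pos < chrom_len):
        raise ValueError(f"{variant.vid}: position outside chromosome")
    x = variant.variant_length
    start = variant.pos - FLANK
    end = variant.pos + x + FLANK
    truncated = start < 0 or end > chrom_len
    start_c, end_c = max(0, start), min(chrom_len, end)
    if truncated:
        logger.info("%s: window truncated to %d bp at chromosome end",
                    variant.vid, end_c - start_c)
    return ScanWindow(
        variant_id=variant.vid,
        sequence=genome[variant.chrom][start_c:end_c],
        chrom=variant.chrom,
        start=start_c,
        end=end_c,
        truncated=truncated,
    )


def _leftmost_match_start(pattern: str, text: str, end: int, distance: int) -> int:
    """Smallest start s with levenshtein(pattern, text[s:end]) == distance.

    A substring achieving distance d has length within d of the pattern's,
    so only starts in that band need checking.
    """
    lo = max(0, end - len(pattern) - distance)
    hi = max(0, end - len(pattern) + distance)
    for s in range(lo, min(hi, end) + 1):
        if levenshtein(pattern, text[s:end]) == distance:
            return s
    raise AssertionError("no substring achieves the reported distance")


def scan(
    variant: VariantRecord, guide: GuideTarget, genome: Mapping[str, str]
) -> ScanResult:
    """Best-match distance of the guide target within the variant's window.

    Both strands are scanned; ties between strands break toward '+', ties
    among end positions toward the leftmost. The match span is reported in
    window-local '+' coordinates; for '-' matches, ``best_match_sequence`` is
    the minus-strand sequence that was matched.
    """
    window = extract_window(genome, variant)
    target = guide.target23
    fwd_d, fwd_ends = infix_best_match(target, window.sequence)
    rc = reverse_complement(window.sequence)
    rev_d, rev_ends = infix_best_match(target, rc)
    if fwd_d <= rev_d:
        strand, dist, text, ends = "+", fwd_d, window.sequence, fwd_ends
    else:
        strand, dist, text, ends = "-", rev_d, rc, rev_ends
    end = min(ends)
    start = _leftmost_match_start(target, text, end, dist)
    if strand == "+":
        span = (start, end)
    else:
        span = (len(text) - end, len(text) - start)
    return ScanResult(
        variant_id=variant.vid,
        best_distance=dist,
        strand=strand,
        match_start=span[0],
        match_end=span[1],
        best_match_sequence=text[start:end],
        truncated=window.truncated,
    )


def scan_private_variants(
    variants: Iterable[VariantRecord],
    guides_by_strain: Mapping[str, GuideTarget],
    strain_of_variant: Mapping[str, str],
    genome: Mapping[str, str],
) -> list[ScanResult]:
    """Scan each private variant against its own strain's guide."""
    results = []
    for v in variants:
        strain = strain_of_variant[v.vid]
        results.append(scan(v, guides_by_strain[strain], genome))
    return results


# ---------------------------------------------------------------------------
# Reference pair distances and distribution comparison
# ---------------------------------------------------------------------------

def pair_distances(
    pairs: Sequence[TargetPair], clean: bool = False
) -> tuple[list[int], dict[int, int]]:
    """Levenshtein distance of each on/off-target pair, plus a histogram.

    With ``clean=True`` characters outside ACGT (e.g. bulge notation) are
    stripped before the distance is computed; default is off — distances are
    taken on the sequences as provided.
    """
    distances = []
    for p in pairs:
        on, off = p.on_sequence, p.off_sequence
        if clean:
            on = "".join(c for c in on if c in "ACGT")
            off = "".join(c for c in off if c in "ACGT")
        distances.append(levenshtein(on, off))
    hist: dict[int, int] = {}
    for d in distances:
        hist[d] = hist.get(d, 0) + 1
    return distances, dict(sorted(hist.items()))


def compare_distributions(
    observed: Sequence[int], reference: Sequence[int]
) -> dict:
    """Side-by-side histograms plus a separation summary.

    The summary reports the minimum observed distance, the maximum reference
    distance, and how many observed distances fall at or below that maximum —
    the count of private variants that look like plausible off-target edits.
    """
    if not observed or not reference:
        raise ValueError("both distance collections must be non-empty")
    max_d = max(max(observed), max(reference))
    table = {
        d: {
            "observed": sum(1 for x in observed if x == d),
            "reference": sum(1 for x in reference if x == d),
        }
        for d in range(0, max_d + 1)
    }
    max_ref = max(reference)
    summary = {
        "min_observed": min(observed),
        "max_reference": max_ref,
        "n_observed_within_reference": sum(1 for x in observed if x <= max_ref),
    }
    return {"histogram": table, "separation": summary}
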