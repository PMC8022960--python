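"""Edit distance, infix best-match, window extraction and scanning."""

import random

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainscan import (
    GuideTarget,
    TargetPair,
    brute_force_infix_distance,
    compare_distributions,
    extract_window,
    infix_best_match,
    levenshtein,
    pair_distances,
    reverse_complement,
    scan,
)
from strainscan.formats_io import Genotype

from conftest import make_record

dna = st.text(alphabet="ACGT", max_size=12)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("GATTACA", "GATTACA", 0),
        ("AC", "", 2),
        ("", "AC", 2),
        ("kitten", "sitting", 3),
        ("ACGT", "AGT", 1),
    ],
)
def test_levenshtein_examples(a, b, expected):
    assert levenshtein(a, b) == expected


@settings(derandomize=True, max_examples=200)
@given(dna, dna, dna)
def test_levenshtein_is_a_metric(a, b, c):
    assert levenshtein(a, a) == 0
    assert levenshtein(a, b) == levenshtein(b, a)
    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)
    if a != b:
        assert levenshtein(a, b) >= 1


@settings(derandomize=True, max_examples=200)
@given(dna.filter(bool), dna.filter(bool))
def test_levenshtein_agrees_with_edlib(a, b):
    assert levenshtein(a, b) == edlib.align(a, b, mode="NW")["editDistance"]


@pytest.mark.parametrize(
    "pattern,text,distance",
    [
        ("ACG", "TTACGTT", 0),
        ("ACG", "", 3),
        ("ACG", "C", 2),
        ("AAAA", "TTTT", 4),
    ],
)
def test_infix_examples(pattern, text, distance):
    d, ends = infix_best_match(pattern, text)
    assert d == distance
    assert ends  # at least one achieving end position


def test_infix_exact_containment_reports_end():
    d, ends = infix_best_match("ACG", "TTACGTT")
    assert d == 0 and 5 in ends


def test_infix_rejects_empty_pattern():
    with pytest.raises(ValueError):
        infix_best_match("", "ACGT")


def test_infix_matches_brute_force_and_edlib():
    rnd = random.Random(7)
    for _ in range(500):
        pattern = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 8)))
        text = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(0, 30)))
        d, ends = infix_best_match(pattern, text)
        assert d == brute_force_infix_distance(pattern, text)
        if text:
            assert d == edlib.align(pattern, text, mode="HW")["editDistance"]
        # every reported end admits a substring achieving the distance
        for e in ends:
            assert min(
                levenshtein(pattern, text[s:e]) for s in range(e + 1)
            ) == d


def test_infix_monotone_under_window_extension():
    rnd = random.Random(11)
    pattern = "".join(rnd.choice("ACGT") for _ in range(10))
    text = "".join(rnd.choice("ACGT") for _ in range(80))
    prev = len(pattern)
    for end in range(0, len(text) + 1, 5):
        d, _ = infix_best_match(pattern, text[:end])
        assert d <= prev
        prev = d


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def test_extract_window_snp(small_genome):
    win = extract_window(small_genome, make_record(chrom="chrA", pos=100))
    assert (win.start, win.end) == (70, 131)
    assert len(win.sequence) == 61
    assert not win.truncated


def test_extract_window_deletion_length(small_genome):
    ref = small_genome["chrA"][200:203]
    rec = make_record(chrom="chrA", pos=200, ref=ref, alt=ref[0])
    win = extract_window(small_genome, rec)
    assert len(win.sequence) == 63  # 60 + X with X = 3


def test_extract_window_truncated_at_start(small_genome):
    win = extract_window(small_genome, make_record(chrom="chrA", pos=10))
    assert win.truncated
    assert len(win.sequence) == 41
    assert win.start == 0


def test_extract_window_out_of_bounds(small_genome):
    with pytest.raises(ValueError):
        extract_window(small_genome, make_record(chrom="chrA", pos=10_000))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _guide_for(seq23, strain="s1", chrom="chrA", pos=500):
    return GuideTarget(
        strain=strain, protospacer=seq23[:20], pam=seq23[20:], chrom=chrom, pos=pos
    )


def test_scan_finds_minus_strand_target(small_genome):
    target = "ACGTACGTACGTACGTACGTTGG"
    genome = dict(small_genome)
    seq = genome["chrA"]
    # plant the reverse complement so only the minus strand matches exactly
    rc = reverse_complement(target)
    genome["chrA"] = seq[:400] + rc + seq[400 + 23:]
    rec = make_record(chrom="chrA", pos=411)
    res = scan(rec, _guide_for(target), genome)
    assert res.best_distance == 0
    assert res.strand == "-"
    assert res.best_match_sequence == target


def test_scan_strand_symmetry(small_genome):
    """Scanning the reverse-complemented genome at the mirrored position
    yields the same best distance."""
    target = "".join(np.random.default_rng(3).choice(list("ACGT"), size=23))
    guide = _guide_for(target)
    rec = make_record(chrom="chrA", pos=1500)
    res_fwd = scan(rec, guide, small_genome)
    mirrored = {
        "chrA": reverse_complement(small_genome["chrA"]),
        "chrB": small_genome["chrB"],
    }
    rec_rc = make_record(chrom="chrA", pos=len(small_genome["chrA"]) - 1 - 1500)
    res_rev = scan(rec_rc, guide, mirrored)
    assert res_fwd.best_distance == res_rev.best_distance
    assert {res_fwd.strand, res_rev.strand} in ({"+", "-"}, {"+"}, {"-"})


def test_scan_reports_achieving_substring(small_genome):
    target = "".join(np.random.default_rng(5).choice(list("ACGT"), size=23))
    rec = make_record(chrom="chrB", pos=800)
    res = scan(rec, _guide_for(target), small_genome)
    assert levenshtein(target, res.best_match_sequence) == res.best_distance


def test_random_window_distance_regime(small_genome):
    """Unrelated 23-nt targets against random 61 bp windows are rarely
    within the off-target regime: distances concentrate at >= 7."""
    rng = np.random.default_rng(17)
    distances = []
    for i in range(30):
        target = "".join(rng.choice(list("ACGT"), size=23))
        rec = make_record(chrom="chrA", pos=int(rng.integers(40, 2900)))
        res = scan(rec, _guide_for(target), small_genome)
        distances.append(res.best_distance)
    assert np.median(distances) >= 7
    assert min(distances) >= 5


# ---------------------------------------------------------------------------
# Pair distances and comparison
# ---------------------------------------------------------------------------

def test_pair_distances():
    on = "ACGTACGTACGTACGTACGTTGG"
    off2 = "ACGAACGTACGTACGTACGATGG"  # two substitutions
    pairs = [
        TargetPair(on, on),
        TargetPair(on, off2),
        TargetPair(on, off2, read_count=10),
    ]
    distances, hist = pair_distances(pairs)
    assert distances == [0, 2, 2]
    assert hist == {0: 1, 2: 2}


def test_pair_distances_clean_strips_bulge_notation():
    pairs = [TargetPair("AC-GT", "ACGT")]
    assert pair_distances(pairs)[0] == [1]
    assert pair_distances(pairs, clean=True)[0] == [0]


@pytest.mark.parametrize(
    "observed,reference,expected_overlap",
    [([7, 8, 9], list(range(7)), 0), ([3], list(range(7)), 1)],
)
def test_compare_distributions_separation(observed, reference, expected_overlap):
    out = compare_distributions(observed, reference)
    sep = out["separation"]
    assert sep["max_reference"] == 6
    assert sep["n_observed_within_reference"] == expected_overlap
    assert sep["min_observed"] == min(observed)


def test_compare_distributions_requires_data():
    with pytest.raises(ValueError):
        compare_distributions([], [1])


# ---------------------------------------------------------------------------
# End-to-end attribution
# ---------------------------------------------------------------------------

def test_end_to_end_attribution_over_seeds():
    """On cohorts with planted off-target sites at distances 0..4 and >= 50
    spontaneous private variants, the planted variants are recovered at
    exactly their realised distances; spurious sub-5 hits among spontaneous
    privates occur at most at the rate of the random-sequence null."""
    from strainscan import classify_variants, plant_cohort, plant_offtarget_site
    from strainscan import generate_genome
    from strainscan.variant_cohort import VariantClass

    spurious = 0
    for seed in range(20):
        genome = generate_genome(2, 15_000, seed=seed)
        truth = plant_cohort(
            genome, n_strains=4, n_background=0, n_private_per_strain=14,
            n_edited=0, seed=seed + 500,
        )
        guide_by_strain = {g.strain: g for g in truth.guides}
        realized = {}
        for d in range(5):
            strain = truth.strains[d % 4]
            genome, rec, rd = plant_offtarget_site(
                genome, guide_by_strain[strain], d, seed=seed * 100 + d,
                strains=truth.strains,
            )
            truth.planted_offtargets.append((strain, rec, rd))
            realized[rec.vid] = rd
        classified, _, _ = classify_variants(truth.all_records(), [])
        for cv in classified:
            assert cv.variant_class == VariantClass.PRIVATE
            res = scan(cv.record, guide_by_strain[cv.alt_strains[0]], genome)
            if res.variant_id in realized:
                assert res.best_distance == realized[res.variant_id]
            elif res.best_distance <= 4:
                spurious += 1
    # 20 x 56 spontaneous windows; the random-sequence null predicts at most
    # about one sub-5 hit at these sizes
    assert spurious <= 3
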