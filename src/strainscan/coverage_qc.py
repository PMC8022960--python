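"""Library-quality metrics from per-base coverage tracks.

Covers coverage-bias profiles (per-base depth over genome-wide average),
breadth of coverage at a depth threshold, binomial depth thinning for
metric-vs-depth curves, a sliding-window per-base GC covariate, seeded
subsampled coverage–covariate correlation, per-annotation-category coverage
summaries, and insert-size median/mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import AnnotationIntervals

logger = logging.getLogger("strainscan")

QUANTILES = (1, 5, 25, 50, 75, 95, 99)

#: Default GC sliding-window scheme: 500 bp windows stepped by 250 bp.
GC_WINDOW = 500
GC_STEP = 250


@dataclass
class BiasProfile:
    """Per-base coverage-bias ratios (depth / genome-wide mean depth)."""

    ratios: dict[str, np.ndarray]
    average_coverage: float
    quantiles: dict[int, float]

    def all_ratios(self) -> np.ndarray:
        return np.concatenate([self.ratios[c] for c in self.ratios])


def _total_depth_and_length(tracks: Mapping[str, np.ndarray]) -> tuple[float, int]:
    total = sum(int(np.asarray(t).sum()) for t in tracks.values())
    length = sum(len(t) for t in tracks.values())
    return float(total), length


def bias_profile(tracks: Mapping[str, np.ndarray]) -> BiasProfile:
    """Coverage bias: per-base ratio of depth to genome-wide average depth."""
    total, length = _total_depth_and_length(tracks)
    if length == 0:
        raise ValueError("empty track collection")
    avg = total / length
    if avg == 0:
        raise ValueError("average coverage is zero")
    ratios = {c: np.asarray(t, dtype=float) / avg for c, t in tracks.items()}
    pooled = np.concatenate(list(ratios.values()))
    quantiles = {q: float(np.percentile(pooled, q)) for q in QUANTILES}
    return BiasProfile(ratios=ratios, average_coverage=avg, quantiles=quantiles)


def breadth_at_depth(tracks: Mapping[str, np.ndarray], min_depth: int) -> float:
    """Fraction of genome bases covered at least ``min_depth``-fold."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    covered = sum(int((np.asarray(t) >= min_depth).sum()) for t in tracks.values())
    _, length = _total_depth_and_length(tracks)
    return covered / length


def breadth_curve(
    tracks: Mapping[str, np.ndarray], min_depths: Sequence[int]
) -> dict[int, float]:
    return {int(d): breadth_at_depth(tracks, int(d)) for d in min_depths}


def thin_coverage(
    tracks: Mapping[str, np.ndarray], fraction: float, seed: int
) -> dict[str, np.ndarray]:
    """Binomially thin each base's depth to emulate read down-sampling.

    Each depth d is replaced by Binomial(d, fraction); thinning by f1 then f2
    is distributionally identical to thinning once by f1*f2.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return {
        c: rng.binomial(np.asarray(t, dtype=np.int64), fraction)
        for c, t in tracks.items()
    }


def gc_profile(
    genome: Mapping[str, str], window: int = GC_WINDOW, step: int = GC_STEP
) -> dict[str, np.ndarray]:
    """Per-base GC covariate from overlapping sliding windows.

    Windows start at 0, step, 2*step, ...; a trailing partial window is kept
    iff its length is at least ``step`` (a chromosome shorter than ``step``
    gets a single whole-chromosome window). Window GC is (G+C) over the
    non-N window length; N-only windows are excluded. Each base's value is
    the mean GC of the kept windows covering it; bases covered by no kept
    window are NaN (undefined).
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    out: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        n = len(seq)
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (codes == ord("G")) | (codes == ord("C"))
        is_n = codes == ord("N")
        gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
        n_cum = np.concatenate([[0], np.cumsum(is_n)])
        spans = []
        for start in range(0, n, step):
            end = min(start + window, n)
            if end - start == window or end - start >= step:
                spans.append((start, end))
        if not spans:
            spans = [(0, n)]
        val_sum = np.zeros(n)
        val_cnt = np.zeros(n)
        for start, end in spans:
            denom = (end - start) - (n_cum[end] - n_cum[start])
            if denom == 0:
                continue  # N-only window carries no information
            gc = (gc_cum[end] - gc_cum[start]) / denom
            val_sum[start:end] += gc
            val_cnt[start:end] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            out[chrom] = np.where(val_cnt > 0, val_sum / np.maximum(val_cnt, 1), np.nan)
    return out


def genome_gc_fraction(genome: Mapping[str, str]) -> float:
    """Overall (G+C) / (non-N length) of the genome."""
    gc = sum(s.count("G") + s.count("C") for s in genome.values())
    acgt = sum(len(s) - s.count("N") for s in genome.values())
    if acgt == 0:
        raise ValueError("genome contains no ACGT bases")
    return gc / acgt


def correlate_coverage_covariate(
    tracks: Mapping[str, np.ndarray],
    covariate: Mapping[str, np.ndarray],
    n_subsample: int = 100_000,
    method: str = "spearman",
    seed: int = 0,
) -> tuple[float, int]:
    """Coverage–covariate correlation on a seeded position subsample.

    Positions with an undefined (NaN) covariate are excluded; up to
    ``n_subsample`` of the remainder are drawn uniformly without replacement
    (all of them if fewer). Returns (coefficient, n_used).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    depth = np.concatenate([np.asarray(tracks[c], dtype=float) for c in tracks])
    cov = np.concatenate([np.asarray(covariate[c], dtype=float) for c in tracks])
    if len(depth) != len(cov):
        raise ValueError("covariate and tracks cover different coordinates")
    usable = np.flatnonzero(~np.isnan(cov))
    if len(usable) < 10:
        raise ValueError("fewer than 10 usable positions")
    if len(usable) > n_subsample:
        rng = np.random.default_rng(seed)
        usable = rng.choice(usable, size=n_subsample, replace=False)
    x, y = depth[usable], cov[usable]
    if np.all(y == y[0]) or np.all(x == x[0]):
        raise ValueError("degenerate input: constant covariate or coverage")
    if method == "spearman":
        coeff = stats.spearmanr(x, y).statistic
    else:
        coeff = stats.pearsonr(x, y).statistic
    logger.info("correlation (%s): %.4f over %d positions (seed %d)",
                method, coeff, len(usable), seed)
    return float(coeff), int(len(usable))


def stratified_coverage(
    tracks: Mapping[str, np.ndarray],
    categories: Sequence[AnnotationIntervals],
) -> dict[str, dict]:
    """Coverage-bias summaries per annotation category.

    Bases may belong to several categories (counted in each); bases in none
    are summarised under "unannotated". Empty categories are reported with
    n=0 and no summary statistics.
    """
    profile = bias_profile(tracks)
    out: dict[str, dict] = {}
    in_any = {c: np.zeros(len(t), dtype=bool) for c, t in tracks.items()}
    for cat in categories:
        vals = []
        for chrom, start, end in cat.intervals:
            if chrom not in tracks or end > len(tracks[chrom]) or start < 0:
                raise ValueError(
                    f"interval {chrom}:{start}-{end} outside track bounds"
                )
            vals.append(profile.ratios[chrom][start:end])
            in_any[chrom][start:end] = True
        pooled = np.concatenate(vals) if vals else np.array([])
        out[cat.category_name] = _ratio_summary(pooled)
    unann = np.concatenate(
        [profile.ratios[c][~in_any[c]] for c in tracks]
    )
    out["unannotated"] = _ratio_summary(unann)
    return out


def _ratio_summary(vals: np.ndarray) -> dict:
    if len(vals) == 0:
        return {"n": 0}
    return {
        "n": int(len(vals)),
        "mean_ratio": float(vals.mean()),
        "quantiles": {q: float(np.percentile(vals, q)) for q in QUANTILES},
    }


def insert_size_summary(histogram: Mapping[int, int]) -> tuple[int, int]:
    """(median, mode) of an insert-size histogram.

    Median is the smallest length whose cumulative count reaches half the
    total; mode is the length with the maximal count, smallest on ties.
    """
    items = sorted((int(l), int(c)) for l, c in histogram.items() if c > 0)
    if not items:
        raise ValueError("empty insert-size histogram")
    total = sum(c for _, c in items)
    half = total / 2
    cum = 0
    median = items[-1][0]
    for length, count in items:
        cum += count
        if cum >= half:
            median = length
            break
    mode = max(items, key=lambda lc: (lc[1], -lc[0]))[0]
    return median, mode
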