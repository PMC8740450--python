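"""Automatic selection of the high-quality read region.

Per-position median Phred scores are computed over all reads covering each
position, smoothed with a centered 5-position moving average to damp
single-position dips, and the longest run of positions whose smoothed score
strictly exceeds the cutoff (default Q30) is selected — provided it spans
strictly more than half the profile length.  The resulting 1-based inclusive
coordinates are what a denoiser consumes as trim positions.

The moving average matters: a single aberrant low-quality position in an
otherwise clean stretch would truncate the region prematurely if raw medians
were screened directly, but its smoothed value typically stays above the
cutoff, preserving the surrounding high-quality bases.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .errors import NoRegionError
from .types import MAX_PHRED, FastqRecord, HQRegion, QualityProfile


def compute_quality_profile(
    reads: Iterable[FastqRecord],
    window: int = 5,
    sample_n: int | None = None,
) -> QualityProfile:
    """Per-position median Phred profile with its moving average.

    Position ``p`` (1-based) aggregates every read of length >= p; the
    median of an even-sized set is the mean of the two central values.
    ``sample_n`` restricts the computation to the first N reads (profiles on
    very deep runs stabilize long before all reads are seen).

    Internally qualities are accumulated as per-position histograms over the
    Phred range, so memory is O(L * 94) regardless of read count.
    """
    hist = np.zeros((0, MAX_PHRED + 1), dtype=np.int64)
    n_reads = 0
    for rec in reads:
        if sample_n is not None and n_reads >= sample_n:
            break
        n_reads += 1
        if len(rec) > hist.shape[0]:
            grown = np.zeros((len(rec), MAX_PHRED + 1), dtype=np.int64)
            grown[: hist.shape[0]] = hist
            hist = grown
        if len(rec):
            hist[np.arange(len(rec)), np.asarray(rec.quals)] += 1
    if n_reads == 0:
        raise ValueError("cannot compute a quality profile from zero reads")
    coverage = hist.sum(axis=1)
    medians = np.array(
        [_median_from_histogram(hist[p], coverage[p]) for p in range(hist.shape[0])]
    )
    smoothed = moving_average(medians, window)
    return QualityProfile(
        tuple(float(m) for m in medians),
        tuple(float(s) for s in smoothed),
        tuple(int(c) for c in coverage),
    )


def _median_from_histogram(counts: np.ndarray, n: int) -> float:
    """Median of n values summarized as a histogram over 0..MAX_PHRED."""
    cum = np.cumsum(counts)
    if n % 2:
        return float(np.searchsorted(cum, n // 2 + 1))
    lo = np.searchsorted(cum, n // 2)
    hi = np.searchsorted(cum, n // 2 + 1)
    return (float(lo) + float(hi)) / 2.0


def moving_average(values, n: int = 5) -> np.ndarray:
    """Centered moving average of odd window size with edge truncation.

    Each output position averages the input positions within radius
    (n-1)/2 that actually fall inside the sequence, so the ends are averaged
    over shorter windows and the output length equals the input length.
    A constant input is a fixed point; n=1 is the identity.
    """
    if n <= 0:
        raise ValueError(f"window size must be positive, got {n}")
    if n % 2 == 0:
        raise ValueError(f"window size must be odd for a centered window, got {n}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values
    radius = (n - 1) // 2
    # cumulative-sum trick with per-position effective window lengths
    padded = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(values.size)
    lo = np.maximum(idx - radius, 0)
    hi = np.minimum(idx + radius, values.size - 1)
    return (padded[hi + 1] - padded[lo]) / (hi - lo + 1)


def select_hq_region(
    smoothed,
    cutoff: float = 30.0,
    min_span_frac: float = 0.5,
) -> HQRegion:
    """Pick the longest run of smoothed scores strictly above ``cutoff``.

    The winning run must span strictly more than ``min_span_frac`` of the
    profile length; ties between equally long runs go to the earliest.
    Raises :class:`NoRegionError` (naming the best run found) when no run
    qualifies.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size == 0:
        raise ValueError("empty quality profile")
    L = smoothed.size
    best: HQRegion | None = None
    run_start: int | None = None
    for pos in range(L + 1):
        above = pos < L and smoothed[pos] > cutoff
        if above and run_start is None:
            run_start = pos
        elif not above and run_start is not None:
            candidate = HQRegion(run_start + 1, pos)  # 1-based inclusive
            if best is None or candidate.length > best.length:
                best = candidate
            run_start = None
    if best is None:
        raise NoRegionError(
            f"no position has smoothed quality > {cutoff}; best run: none"
        )
    if not best.length > min_span_frac * L:
        raise NoRegionError(
            f"longest run above Q{cutoff:g} is ({best.start}, {best.end}), "
            f"length {best.length}, which does not exceed "
            f"{min_span_frac:.0%} of the profile length {L}",
            best_run=best,
        )
    return best
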