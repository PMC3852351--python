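"""Sliding-window peak calling with local Poisson nulls.

A candidate window of width ``w`` slides along each strand of each
chromosome in steps of ``w/2``. Candidates with at least ``min_reads``
read starts are tested against two Poisson nulls whose rates are the
left and right flanking-window counts scaled to the candidate width.
Significant windows are trimmed to their nonzero span and windows closer
than ``merge_gap`` are merged into single peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import special, stats

from cagetss.genomic_io import STRANDS, GenomicInterval, ReadStartProfile


@dataclass
class PeakCallingParams:
    """Parameters of the sliding-window caller; defaults are the method defaults."""

    w: int = 50
    step: int | None = None  # defaults to w // 2
    flank_width: int = 200
    min_reads: int = 10
    p_threshold: float = 1e-20
    merge_gap: int = 30
    mapq_min: int = 20
    require_both: bool = False  # require BOTH flank tests to reject, not either

    def __post_init__(self) -> None:
        if self.step is None:
            self.step = self.w // 2
        if self.w <= 0 or self.step <= 0 or self.flank_width <= 0:
            raise ValueError("w, step and flank_width must be positive")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")

    @property
    def log_p_threshold(self) -> float:
        return math.log(self.p_threshold)


@dataclass
class CandidateWindow:
    interval: GenomicInterval
    count: int
    left_flank_count: int
    right_flank_count: int
    lambda_left: int
    lambda_right: int


@dataclass
class Peak:
    """A called peak: trimmed interval, total read-start count and summit."""

    interval: GenomicInterval
    total_count: int
    summit: int

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit must lie within the peak interval")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (inputs are >= 0 here)."""
    return int(math.floor(x + 0.5))


def poisson_upper_tail(x: int, lam: float) -> float:
    """P(X >= x) for X ~ Poisson(lam).

    The degenerate lam = 0 case gives 1 for x = 0 and 0 otherwise.
    """
    if x < 0 or lam < 0:
        raise ValueError("x and lam must be non-negative")
    if x == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(x - 1, lam))


def poisson_log_upper_tail(x: int, lam: float) -> float:
    """log P(X >= x) for X ~ Poisson(lam); -inf for the degenerate zero tail.

    Stable far below the underflow limit of the plain probability, so
    thresholds like 1e-20 (and tails down past 1e-300) compare exactly.
    """
    if x < 0 or lam < 0:
        raise ValueError("x and lam must be non-negative")
    if x == 0:
        return 0.0
    if lam == 0:
        return -math.inf
    value = float(stats.poisson.logsf(x - 1, lam))
    if math.isinf(value):
        # linear-space tail underflowed; sum the dominant pmf terms in log space
        k = np.arange(x, x + 256)
        log_pmf = k * math.log(lam) - lam - special.gammaln(k + 1)
        value = float(special.logsumexp(log_pmf))
    return value


def _scaled_flank(
    raw_count: int, flank_width: int, candidate_width: int
) -> int:
    """Scale a flank count to the candidate window width; zero-width flank -> 0."""
    if flank_width <= 0:
        return 0
    return _round_half_away(raw_count * candidate_width / flank_width)


def _scan_chrom(
    profile: ReadStartProfile,
    chrom: str,
    strand: str,
    params: PeakCallingParams,
) -> Iterator[CandidateWindow]:
    length = profile.chrom_lengths[chrom]
    pos, _, cum = profile.arrays(chrom, strand)
    if pos.size == 0:
        return
    starts = np.arange(0, length, params.step, dtype=np.int64)
    ends = np.minimum(starts + params.w, length)

    def mass(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(pos, a, side="left")
        hi = np.searchsorted(pos, b, side="left")
        left = np.where(lo > 0, cum[np.maximum(lo - 1, 0)], 0)
        right = np.where(hi > 0, cum[np.maximum(hi - 1, 0)], 0)
        return right - left

    counts = mass(starts, ends)
    keep = counts >= params.min_reads
    for s, e, c in zip(starts[keep], ends[keep], counts[keep]):
        s, e, c = int(s), int(e), int(c)
        lf_start, lf_end = max(0, s - params.flank_width), s
        rf_start, rf_end = e, min(length, e + params.flank_width)
        left_raw = profile.count_in(chrom, strand, lf_start, lf_end)
        right_raw = profile.count_in(chrom, strand, rf_start, rf_end)
        width = e - s
        yield CandidateWindow(
            interval=GenomicInterval(chrom, s, e, strand),
            count=c,
            left_flank_count=left_raw,
            right_flank_count=right_raw,
            lambda_left=_scaled_flank(left_raw, lf_end - lf_start, width),
            lambda_right=_scaled_flank(right_raw, rf_end - rf_start, width),
        )


def scan_candidates(
    profile: ReadStartProfile, params: PeakCallingParams
) -> Iterator[CandidateWindow]:
    """All candidate windows with count >= min_reads, over every chrom and strand."""
    for chrom in sorted(profile.chrom_lengths):
        for strand in STRANDS:
            yield from _scan_chrom(profile, chrom, strand, params)


def test_window(cand: CandidateWindow, params: PeakCallingParams) -> bool:
    """Significance test against the two flank-scaled Poisson nulls.

    By default a candidate passes when either flank null rejects below
    the threshold; ``require_both`` demands both.
    """
    threshold = params.log_p_threshold
    left = poisson_log_upper_tail(cand.count, cand.lambda_left) < threshold
    right = poisson_log_upper_tail(cand.count, cand.lambda_right) < threshold
    return (left and right) if params.require_both else (left or right)


def trim_window(
    interval: GenomicInterval, profile: ReadStartProfile
) -> GenomicInterval | None:
    """Trim outermost zero-count positions; None when the window is empty."""
    pos, _ = profile.positions_in(
        interval.chrom, interval.strand, interval.start, interval.end
    )
    if pos.size == 0:
        return None
    return GenomicInterval(
        interval.chrom, int(pos[0]), int(pos[-1]) + 1, interval.strand
    )


def merge_windows(
    intervals: list[GenomicInterval], merge_gap: int
) -> list[GenomicInterval]:
    """Merge intervals separated by less than ``merge_gap`` bases (transitively)."""
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("merge_windows requires a single chromosome and strand")
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.start, v.end)):
        if merged and iv.start - merged[-1].end < merge_gap:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end), prev.strand
            )
        else:
            merged.append(iv)
    return merged


def peak_from_interval(
    interval: GenomicInterval, profile: ReadStartProfile
) -> Peak:
    """Build a Peak (total count + summit) for an interval from the profile.

    Summit ties break toward the 5'-most position on the peak's strand.
    """
    pos, cnt = profile.positions_in(
        interval.chrom, interval.strand, interval.start, interval.end
    )
    if pos.size == 0:
        raise ValueError(f"interval {interval} has no read starts")
    best = cnt.max()
    tied = pos[cnt == best]
    summit = int(tied.min() if interval.strand == "+" else tied.max())
    return Peak(interval=interval, total_count=int(cnt.sum()), summit=summit)


def peak_base_counts(peak: Peak, profile: ReadStartProfile) -> np.ndarray:
    """Dense per-base read-start counts across the peak interval."""
    iv = peak.interval
    counts = np.zeros(iv.width, dtype=np.int64)
    pos, cnt = profile.positions_in(iv.chrom, iv.strand, iv.start, iv.end)
    counts[pos - iv.start] = cnt
    return counts


def call_peaks(
    profile: ReadStartProfile, params: PeakCallingParams | None = None
) -> list[Peak]:
    """Full caller: scan -> test -> trim -> merge -> re-trim -> summarize.

    Output is deterministic, sorted by (chrom, start, strand); peaks on one
    strand are pairwise separated by at least ``merge_gap``.
    """
    if params is None:
        params = PeakCallingParams()
    peaks: list[Peak] = []
    for chrom in sorted(profile.chrom_lengths):
        for strand in STRANDS:
            trimmed: list[GenomicInterval] = []
            for cand in _scan_chrom(profile, chrom, strand, params):
                if not test_window(cand, params):
                    continue
                tiv = trim_window(cand.interval, profile)
                if tiv is not None:
                    trimmed.append(tiv)
            for merged in merge_windows(trimmed, params.merge_gap):
                final = trim_window(merged, profile)  # structural no-op guard
                if final is not None:
                    peaks.append(peak_from_interval(final, profile))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.strand))
    return peaks
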