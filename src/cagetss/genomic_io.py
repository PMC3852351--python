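"""Readers/writers for the genomic formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversions to and from
1-based conventions (GTF) happen only inside the loaders in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: columns of a DataFrame that are metadata, not features
META_COLUMNS = ("cell_line", "label", "peak_id")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-specific genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptStart:
    """Strand-aware 5' end of an annotated transcript (0-based)."""

    chrom: str
    position: int
    strand: str


class ReadStartProfile:
    """Sparse per-(chrom, strand) counts of read 5'-start positions.

    Zero counts are never stored. Sorted position/count arrays are cached
    per (chrom, strand) and invalidated on mutation.
    """

    def __init__(self, chrom_lengths: dict[str, int] | None = None) -> None:
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths or {})
        self._counts: dict[tuple[str, str], dict[int, int]] = {}
        self._cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def add(self, chrom: str, strand: str, position: int, count: int = 1) -> None:
        if strand not in STRANDS:
            raise ValueError(f"bad strand {strand!r}")
        if count < 1:
            raise ValueError("count must be >= 1")
        length = self.chrom_lengths.get(chrom)
        if length is not None and not (0 <= position < length):
            raise ValueError(
                f"position {position} outside [0, {length}) on {chrom}"
            )
        if length is None:
            # grow an inferred length; callers with real headers set it up front
            self.chrom_lengths[chrom] = max(self.chrom_lengths.get(chrom, 0), position + 1)
        key = (chrom, strand)
        bucket = self._counts.setdefault(key, {})
        bucket[position] = bucket.get(position, 0) + count
        self._cache.pop(key, None)

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._counts)

    def total_mass(self) -> int:
        return sum(sum(b.values()) for b in self._counts.values())

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sorted positions, matching counts, and the counts' cumulative sum."""
        key = (chrom, strand)
        cached = self._cache.get(key)
        if cached is None:
            bucket = self._counts.get(key, {})
            pos = np.array(sorted(bucket), dtype=np.int64)
            cnt = np.array([bucket[p] for p in pos], dtype=np.int64)
            cached = (pos, cnt, np.cumsum(cnt))
            self._cache[key] = cached
        return cached

    def count_in(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Total read starts at positions in [start, end)."""
        pos, _, cum = self.arrays(chrom, strand)
        if pos.size == 0 or end <= start:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        if hi == lo:
            return 0
        return int(cum[hi - 1] - (cum[lo - 1] if lo > 0 else 0))

    def positions_in(
        self, chrom: str, strand: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Positions and counts within [start, end)."""
        pos, cnt, _ = self.arrays(chrom, strand)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], cnt[lo:hi]


class ScoreTrack:
    """Unstranded scored intervals supporting max / per-base-mean queries.

    Overlapping intervals are permitted; a base covered by several
    intervals takes the mean of their scores for per-base queries.
    """

    def __init__(self) -> None:
        self._records: dict[str, list[tuple[int, int, float]]] = {}
        self._frozen: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def add(self, chrom: str, start: int, end: int, score: float) -> None:
        if not 0 <= start < end:
            raise ValueError(f"bad interval [{start}, {end})")
        self._records.setdefault(chrom, []).append((start, end, float(score)))
        self._frozen.pop(chrom, None)

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())

    def _arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        arrs = self._frozen.get(chrom)
        if arrs is None:
            recs = sorted(self._records.get(chrom, []))
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            scores = np.array([r[2] for r in recs], dtype=float)
            arrs = (starts, ends, scores)
            self._frozen[chrom] = arrs
        return arrs

    def _overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        starts, ends, _ = self._arrays(chrom)
        if starts.size == 0:
            return np.zeros(0, dtype=bool)
        return (starts < end) & (ends > start)

    def max_over(self, chrom: str, start: int, end: int) -> float | None:
        """Maximum score of intervals overlapping [start, end); None if no overlap."""
        mask = self._overlapping(chrom, start, end)
        if not mask.any():
            return None
        return float(self._arrays(chrom)[2][mask].max())

    def per_base_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base score over covered bases of [start, end); NaN if none covered."""
        mask = self._overlapping(chrom, start, end)
        if not mask.any():
            return float("nan")
        starts, ends, scores = self._arrays(chrom)
        width = end - start
        total = np.zeros(width)
        cover = np.zeros(width, dtype=np.int64)
        for s, e, v in zip(starts[mask], ends[mask], scores[mask]):
            lo = max(s, start) - start
            hi = min(e, end) - start
            total[lo:hi] += v
            cover[lo:hi] += 1
        covered = cover > 0
        return float(np.mean(total[covered] / cover[covered]))


def load_read_starts(alignment_file: str, mapq_min: int = 20) -> ReadStartProfile:
    """Extract strand-specific read 5'-start counts from a SAM/BAM file.

    Each retained primary alignment contributes 1 at its cap-proximal end:
    the leftmost aligned base for forward reads, the rightmost aligned base
    for reverse reads. Unmapped, secondary and supplementary records, and
    records with mapping quality below ``mapq_min`` are discarded.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    try:
        af = pysam.AlignmentFile(str(alignment_file))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignment file {alignment_file}: {exc}") from exc
    with af:
        lengths = dict(zip(af.references, af.lengths))
        profile = ReadStartProfile(lengths)
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            chrom = read.reference_name
            if read.is_reverse:
                strand, pos = "-", read.reference_end - 1
            else:
                strand, pos = "+", read.reference_start
            length = lengths.get(chrom)
            if length is not None and not (0 <= pos < length):
                logger.warning(
                    "read %s maps at %s:%d beyond declared length %d; rejected",
                    read.query_name, chrom, pos, length,
                )
                continue
            profile.add(chrom, strand, pos)
    return profile


def load_transcript_starts(annotation_file: str) -> list[TranscriptStart]:
    """Strand-aware transcript 5' ends from a GTF/GFF file (0-based output)."""
    starts: list[TranscriptStart] = []
    with open(annotation_file) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{annotation_file}:{lineno}: expected >= 8 tab-separated fields"
                )
            feature = fields[2]
            if feature not in ("transcript", "mRNA"):
                continue
            strand = fields[6]
            if strand not in STRANDS:
                logger.warning(
                    "%s:%d: transcript without strand; rejected",
                    annotation_file, lineno,
                )
                continue
            start1, end1 = int(fields[3]), int(fields[4])
            # GTF is 1-based inclusive; 5' end is strand dependent
            position = start1 - 1 if strand == "+" else end1 - 1
            starts.append(TranscriptStart(fields[0], position, strand))
    return starts


def load_score_track(track_file: str) -> ScoreTrack:
    """Load a bedGraph / scored-BED file of (chrom, start, end, score) records."""
    track = ScoreTrack()
    with open(track_file) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if (
                not stripped
                or stripped.startswith("#")
                or stripped.startswith(("track", "browser"))
            ):
                continue
            fields = stripped.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{track_file}:{lineno}: expected >= 4 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{track_file}:{lineno}: non-integer coordinates"
                ) from exc
            # bedGraph puts the score in column 4; BED5+ in column 5
            try:
                score = float(fields[3])
            except ValueError:
                if len(fields) >= 5:
                    try:
                        score = float(fields[4])
                    except ValueError as exc:
                        raise ValueError(
                            f"{track_file}:{lineno}: non-numeric score"
                        ) from exc
                else:
                    raise ValueError(f"{track_file}:{lineno}: non-numeric score")
            track.add(chrom, start, end, score)
    return track


def write_peaks_bed(peaks, path: str) -> None:
    """Write peaks as BED6; the score column carries total read count capped at 1000."""
    try:
        with open(path, "w") as handle:
            for i, peak in enumerate(peaks, start=1):
                iv = peak.interval
                score = min(int(peak.total_count), 1000)
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{score}\t{iv.strand}\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write BED file {path}: {exc}") from exc


def read_bed_intervals(path: str) -> list[GenomicInterval]:
    """Read a BED6 file back into strand-specific intervals."""
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6")
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            )
    return intervals


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif name is not None:
                parts.append(line.strip())
    if name is not None:
        sequences[name] = "".join(parts)
    return sequences
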