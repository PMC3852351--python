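"""Peak feature construction.

Eight feature families: kurtosis, read density, upstream/downstream 4-mer
counts around the summit, max-score features for TFBS / DNase / H3K4me3
tracks, mean conservation within the peak, and a Poisson lower-tail
RNA-seq flank difference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cagetss.genomic_io import GenomicInterval, ReadStartProfile, ScoreTrack
from cagetss.peak_calling import Peak, peak_from_interval

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: single (non k-mer) feature column names in canonical order
SINGLE_FEATURES = (
    "kurtosis",
    "read_density",
    "tfbs_max",
    "dnase_max",
    "h3k4me3_max",
    "conservation_mean",
)

EXTERNAL_MAX_FEATURES = ("tfbs_max", "dnase_max", "h3k4me3_max")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FlankPair:
    """Strand-aware windows immediately 5' and 3' of a peak.

    A flank collapsed to zero width at a chromosome edge is None.
    """

    upstream: GenomicInterval | None
    downstream: GenomicInterval | None


def make_flank_pair(peak: Peak, width: int = 100) -> FlankPair:
    iv = peak.interval
    left = (
        GenomicInterval(iv.chrom, max(0, iv.start - width), iv.start, iv.strand)
        if iv.start > 0
        else None
    )
    right = GenomicInterval(iv.chrom, iv.end, iv.end + width, iv.strand)
    if iv.strand == "+":
        return FlankPair(upstream=left, downstream=right)
    return FlankPair(upstream=right, downstream=left)


def peak_summit(peak: Peak, profile: ReadStartProfile) -> int:
    """Position of the maximum single-base count; ties break 5'-most on the strand."""
    return peak_from_interval(peak.interval, profile).summit


def compute_kurtosis(peak: Peak, profile: ReadStartProfile) -> float:
    """Pearson's kurtosis (m4 / m2^2) of read-start positions, count-weighted.

    Population moments; all reads on one base (zero variance) returns NaN,
    to be replaced by the degenerate sentinel at matrix-build time.
    """
    pos, cnt = profile.positions_in(
        peak.interval.chrom, peak.interval.strand,
        peak.interval.start, peak.interval.end,
    )
    n = cnt.sum()
    if n == 0:
        raise ValueError("cannot compute kurtosis of an empty peak")
    pos = pos.astype(float)
    mean = float(np.dot(pos, cnt)) / n
    d = pos - mean
    m2 = float(np.dot(d**2, cnt)) / n
    if m2 == 0.0:
        return float("nan")
    m4 = float(np.dot(d**4, cnt)) / n
    return m4 / m2**2


def compute_read_density(peak: Peak) -> float:
    """Reads inside the peak divided by its width."""
    return peak.total_count / peak.interval.width


def compute_conservation(peak: Peak, track: ScoreTrack) -> float:
    """Mean per-base conservation over scored bases of the peak; NaN when unscored."""
    iv = peak.interval
    return track.per_base_mean(iv.chrom, iv.start, iv.end)


def compute_max_score_feature(
    peak: Peak, track: ScoreTrack, extension: int = 100
) -> float:
    """Maximum track score within the peak extended by ``extension`` bases; 0 if none."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    iv = peak.interval
    value = track.max_over(iv.chrom, max(0, iv.start - extension), iv.end + extension)
    return 0.0 if value is None else value


def kmer_names(k: int = 4) -> list[str]:
    """All k-mers over ACGT in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def kmer_feature_names(k: int = 4) -> list[str]:
    """Column names: the upstream block followed by the downstream block."""
    mers = kmer_names(k)
    return [f"up_{m}" for m in mers] + [f"down_{m}" for m in mers]


def _count_kmers(seq: str, k: int, index: dict[str, int], out: np.ndarray) -> None:
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        idx = index.get(seq[i : i + k])
        if idx is not None:  # k-mers containing non-ACGT are skipped
            out[idx] += 1


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) of a chromosome from a dict of strings or a pyfaidx Fasta."""
    start = max(0, start)
    if end <= start:
        return ""
    record = genome[chrom]
    piece = record[start:end]
    return piece if isinstance(piece, str) else str(piece)


def compute_kmer_features(
    summit: int,
    strand: str,
    genome,
    chrom: str,
    k: int = 4,
    window: int = 500,
    strand_naive: bool = False,
) -> np.ndarray:
    """Overlapping k-mer counts in strand-aware windows flanking the summit.

    Upstream covers the ``window`` bases 5' of the summit (summit base
    excluded), downstream the ``window`` bases 3'. On the minus strand both
    windows are read as reverse complement so "upstream" is cap-proximal
    promoter sequence. Returns counts aligned with :func:`kmer_feature_names`.
    """
    if k < 1 or window < k:
        raise ValueError("require k >= 1 and window >= k")
    index = {m: i for i, m in enumerate(kmer_names(k))}
    left = _fetch(genome, chrom, summit - window, summit)
    right = _fetch(genome, chrom, summit + 1, summit + 1 + window)
    if strand == "-" and not strand_naive:
        up_seq, down_seq = reverse_complement(right), reverse_complement(left)
    else:
        up_seq, down_seq = left, right
    n = len(index)
    counts = np.zeros(2 * n, dtype=np.int64)
    _count_kmers(up_seq, k, index, counts[:n])
    _count_kmers(down_seq, k, index, counts[n:])
    return counts


def compute_rnaseq_difference(
    peak: Peak,
    rnaseq_profile: ReadStartProfile,
    flank: int = 100,
    strand_naive: bool = False,
) -> float:
    """Poisson lower tail P(Y <= y_up; lambda = downstream flank count).

    Flanks are the ``flank``-base windows adjacent to the peak boundaries,
    oriented by the peak's strand; RNA-seq reads on both strands are
    counted (total RNA-seq carries no cap-strand information). Values near
    0 mean much more signal downstream than upstream, i.e. TSS-like.
    """
    iv = peak.interval
    left = (max(0, iv.start - flank), iv.start)
    right = (iv.end, iv.end + flank)
    if iv.strand == "-" and not strand_naive:
        up, down = right, left
    else:
        up, down = left, right

    def both_strands(bounds: tuple[int, int]) -> int:
        return sum(
            rnaseq_profile.count_in(iv.chrom, s, bounds[0], bounds[1])
            for s in ("+", "-")
        )

    y = both_strands(up)
    lam = both_strands(down)
    if lam == 0:
        return 1.0
    return float(stats.poisson.cdf(y, lam))


def impute_missing_conservation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing conservation means by the per-cell-line observed minimum."""
    if "conservation_mean" not in matrix.columns:
        return matrix
    out = matrix.copy()
    col = "conservation_mean"
    for line, idx in out.groupby("cell_line").groups.items():
        values = out.loc[idx, col]
        if values.isna().all():
            raise ValueError(
                f"all conservation values missing for cell line {line!r}"
            )
        out.loc[idx, col] = values.fillna(values.min())
    return out


def _fill_degenerate_kurtosis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Zero-variance peaks take the max kurtosis among non-degenerate peaks per line."""
    out = matrix.copy()
    for line, idx in out.groupby("cell_line").groups.items():
        values = out.loc[idx, "kurtosis"]
        if values.isna().any():
            finite = values.dropna()
            sentinel = float(finite.max()) if len(finite) else 1.0
            out.loc[idx, "kurtosis"] = values.fillna(sentinel)
    return out


def peak_id(peak: Peak) -> str:
    iv = peak.interval
    return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def build_feature_matrix(
    peaks: list[Peak],
    profile: ReadStartProfile,
    genome,
    cell_line: str,
    tracks: dict[str, ScoreTrack] | None = None,
    rnaseq_profile: ReadStartProfile | None = None,
    k: int = 4,
    kmer_window: int = 500,
    extension: int = 100,
    flank: int = 100,
    strand_naive: bool = False,
) -> pd.DataFrame:
    """Assemble the per-peak feature matrix for one cell line.

    ``tracks`` may provide any of ``tfbs``, ``dnase``, ``h3k4me3`` (max-score
    features) and ``conservation`` (per-base mean with minimum imputation).
    The RNA-seq difference column is added when ``rnaseq_profile`` is given.
    Rows are indexed by peak id; a ``cell_line`` metadata column is included.
    """
    tracks = tracks or {}
    kmer_cols = kmer_feature_names(k)
    columns = ["cell_line", "kurtosis", "read_density", *kmer_cols]
    for name, col in (("tfbs", "tfbs_max"), ("dnase", "dnase_max"),
                      ("h3k4me3", "h3k4me3_max")):
        if name in tracks:
            columns.append(col)
    if "conservation" in tracks:
        columns.append("conservation_mean")
    if rnaseq_profile is not None:
        columns.append("rnaseq_diff")

    rows: list[dict] = []
    ids: list[str] = []
    for peak in peaks:
        summit = peak_summit(peak, profile)
        row: dict = {
            "cell_line": cell_line,
            "kurtosis": compute_kurtosis(peak, profile),
            "read_density": compute_read_density(peak),
        }
        kmers = compute_kmer_features(
            summit, peak.interval.strand, genome, peak.interval.chrom,
            k=k, window=kmer_window, strand_naive=strand_naive,
        )
        row.update(zip(kmer_cols, kmers))
        for name, col in (("tfbs", "tfbs_max"), ("dnase", "dnase_max"),
                          ("h3k4me3", "h3k4me3_max")):
            if name in tracks:
                row[col] = compute_max_score_feature(peak, tracks[name], extension)
        if "conservation" in tracks:
            row["conservation_mean"] = compute_conservation(
                peak, tracks["conservation"]
            )
        if rnaseq_profile is not None:
            row["rnaseq_diff"] = compute_rnaseq_difference(
                peak, rnaseq_profile, flank=flank, strand_naive=strand_naive
            )
        rows.append(row)
        ids.append(peak_id(peak))

    matrix = pd.DataFrame(rows, index=ids, columns=columns)
    if not matrix.empty:
        matrix = _fill_degenerate_kurtosis(matrix)
        if "conservation_mean" in matrix.columns:
            matrix = impute_missing_conservation(matrix)
    return matrix
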