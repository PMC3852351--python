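"""Desk-scale synthetic fixtures with known ground truth.

Generates random genomes with optional planted promoter sequence, CAGE
read-start profiles (planted clusters over homogeneous Poisson
background), external score tracks enriched near planted TSS peaks,
RNA-seq flank profiles, and matching transcript annotation — everything
the pipeline consumes, reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cagetss.genomic_io import (
    GenomicInterval,
    ReadStartProfile,
    ScoreTrack,
    TranscriptStart,
    write_fasta,
)

#: fixed promoter block planted upstream of TSS summits so k-mer features
#: carry class signal (contains a TATA box within a GC-skewed context)
PROMOTER_BLOCK = (
    "GCGCGGGGCGGGGCTATAAAAGGGCGGGGCGCGCCCCGCCCCTATAAAAG"
    "GGCGGGCGCGGCCAATGGGCGGGGCCGCCCCGCCTATAAAAGCGCGGGGC"
)


@dataclass(frozen=True)
class PlantedPeak:
    """Ground-truth cluster of read starts."""

    chrom: str
    position: int
    strand: str
    read_count: int
    spread: int = 1
    is_tss: bool = True


@dataclass(frozen=True)
class TruthPeak:
    """Realized span of a planted cluster after sampling."""

    interval: GenomicInterval
    read_count: int
    is_tss: bool
    planted_position: int


@dataclass
class SimulationSpec:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrS": 100_000})
    planted_peaks: list[PlantedPeak] = field(default_factory=list)
    background_rate: float = 0.0  # expected read starts per base per strand
    plant_promoter: bool = True
    promoter_offset: int = 20  # gap between promoter block 3' end and the summit
    track_level_tss: float = 10.0
    track_window: int = 150
    conservation_level_tss: float = 2.0
    conservation_level_other: float = 0.1
    rnaseq_downstream_rate: float = 20.0  # expected reads in the 100b downstream flank
    rnaseq_upstream_rate: float = 0.0
    rnaseq_nontss_rate: float = 5.0  # symmetric flank rate for non-TSS peaks
    flank: int = 100

    def __post_init__(self) -> None:
        for rate in (
            self.background_rate,
            self.rnaseq_downstream_rate,
            self.rnaseq_upstream_rate,
            self.rnaseq_nontss_rate,
        ):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for peak in self.planted_peaks:
            length = self.chrom_lengths[peak.chrom]
            if not 0 <= peak.position < length:
                raise ValueError(f"planted peak at {peak.position} outside genome")
            if peak.position + peak.spread > length:
                raise ValueError("planted peak spread exceeds chromosome end")


def _rng(spec: SimulationSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def simulate_genome(spec: SimulationSpec) -> dict[str, str]:
    """Uniform-random ACGT genome, with a promoter block 5' of each planted TSS."""
    rng = _rng(spec, 1)
    bases = np.array(list("ACGT"))
    genome: dict[str, list[str]] = {}
    for chrom, length in sorted(spec.chrom_lengths.items()):
        genome[chrom] = list("".join(rng.choice(bases, size=length)))
    if spec.plant_promoter:
        block = PROMOTER_BLOCK
        for peak in spec.planted_peaks:
            if not peak.is_tss:
                continue
            seq = genome[peak.chrom]
            summit = peak.position + peak.spread // 2
            if peak.strand == "+":
                start = summit - spec.promoter_offset - len(block)
                insert = block
            else:
                start = summit + spec.promoter_offset + 1
                insert = _revcomp(block)
            if start < 0 or start + len(insert) > len(seq):
                continue
            seq[start : start + len(insert)] = list(insert)
    return {chrom: "".join(seq) for chrom, seq in genome.items()}


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _check_no_overlap(peaks: list[PlantedPeak]) -> None:
    by_key: dict[tuple[str, str], list[PlantedPeak]] = {}
    for p in peaks:
        by_key.setdefault((p.chrom, p.strand), []).append(p)
    for group in by_key.values():
        group.sort(key=lambda p: p.position)
        for prev, nxt in zip(group, group[1:]):
            if prev.position + prev.spread > nxt.position:
                raise ValueError(
                    f"planted peaks overlap on {prev.chrom}{prev.strand}: "
                    f"{prev.position} and {nxt.position}"
                )


def simulate_cage_profile(
    spec: SimulationSpec,
) -> tuple[ReadStartProfile, list[TruthPeak]]:
    """Planted clusters plus homogeneous Poisson background; returns truth spans.

    Each planted peak contributes ``read_count`` starts: one pinned at the
    planted position (so the summit region is always populated) and the rest
    drawn with a center-heavy distribution across ``spread`` bases.
    """
    _check_no_overlap(spec.planted_peaks)
    rng = _rng(spec, 2)
    profile = ReadStartProfile(spec.chrom_lengths)
    truth: list[TruthPeak] = []
    for peak in sorted(
        spec.planted_peaks, key=lambda p: (p.chrom, p.position, p.strand)
    ):
        if peak.spread <= 1:
            positions = np.full(peak.read_count, peak.position, dtype=np.int64)
        else:
            center = peak.position + peak.spread // 2
            # ~70% of reads at the central base, the rest uniform over the spread
            at_center = rng.random(peak.read_count - 1) < 0.7
            scattered = rng.integers(
                peak.position, peak.position + peak.spread,
                size=int((~at_center).sum()),
            )
            positions = np.concatenate(
                [
                    [peak.position],  # pin the planted 5' edge
                    np.full(int(at_center.sum()), center, dtype=np.int64),
                    scattered,
                ]
            ).astype(np.int64)
        for pos in positions:
            profile.add(peak.chrom, peak.strand, int(pos))
        span = GenomicInterval(
            peak.chrom, int(positions.min()), int(positions.max()) + 1, peak.strand
        )
        truth.append(
            TruthPeak(
                interval=span,
                read_count=peak.read_count,
                is_tss=peak.is_tss,
                planted_position=peak.position,
            )
        )
    if spec.background_rate > 0:
        for chrom, length in sorted(spec.chrom_lengths.items()):
            for strand in ("+", "-"):
                n = rng.poisson(spec.background_rate * length)
                for pos in rng.integers(0, length, size=n):
                    profile.add(chrom, strand, int(pos))
    return profile, truth


def simulate_external_tracks(
    spec: SimulationSpec, truth: list[TruthPeak]
) -> tuple[dict[str, ScoreTrack], ReadStartProfile]:
    """Score tracks enriched near TSS truth peaks, plus an RNA-seq flank profile."""
    rng = _rng(spec, 3)
    tracks = {name: ScoreTrack() for name in ("tfbs", "dnase", "h3k4me3", "conservation")}
    rnaseq = ReadStartProfile(spec.chrom_lengths)
    for peak in truth:
        iv = peak.interval
        length = spec.chrom_lengths[iv.chrom]
        lo = max(0, iv.start - spec.track_window)
        hi = min(length, iv.end + spec.track_window)
        if peak.is_tss:
            for name in ("tfbs", "dnase", "h3k4me3"):
                level = spec.track_level_tss * (0.8 + 0.4 * rng.random())
                tracks[name].add(iv.chrom, lo, hi, level)
            tracks["conservation"].add(iv.chrom, iv.start, iv.end, spec.conservation_level_tss)
        else:
            tracks["conservation"].add(iv.chrom, iv.start, iv.end, spec.conservation_level_other)

        # RNA-seq flank reads: strand-aware downstream/upstream of the truth span
        left = (max(0, iv.start - spec.flank), iv.start)
        right = (iv.end, min(length, iv.end + spec.flank))
        if iv.strand == "+":
            up, down = left, right
        else:
            up, down = right, left
        if peak.is_tss:
            up_rate, down_rate = spec.rnaseq_upstream_rate, spec.rnaseq_downstream_rate
        else:
            up_rate = down_rate = spec.rnaseq_nontss_rate
        for (lo_b, hi_b), rate in ((up, up_rate), (down, down_rate)):
            if hi_b <= lo_b or rate <= 0:
                continue
            n = rng.poisson(rate)
            for pos in rng.integers(lo_b, hi_b, size=n):
                rnaseq.add(iv.chrom, "+" if rng.random() < 0.5 else "-", int(pos))
    return tracks, rnaseq


def simulate_annotation(truth: list[TruthPeak]) -> list[TranscriptStart]:
    """One transcript per TSS truth peak, 5' end at the planted position."""
    return [
        TranscriptStart(t.interval.chrom, t.planted_position, t.interval.strand)
        for t in truth
        if t.is_tss
    ]


def write_gtf(
    transcripts: list[TranscriptStart],
    chrom_lengths: dict[str, int],
    path: str,
    transcript_length: int = 1000,
) -> None:
    """Write transcripts as GTF (1-based inclusive), respecting strand polarity."""
    with open(path, "w") as handle:
        for i, ts in enumerate(transcripts, start=1):
            length = chrom_lengths[ts.chrom]
            if ts.strand == "+":
                start0 = ts.position
                end0 = min(length, ts.position + transcript_length)
            else:
                start0 = max(0, ts.position + 1 - transcript_length)
                end0 = ts.position + 1
            attrs = f'gene_id "g{i}"; transcript_id "t{i}";'
            handle.write(
                f"{ts.chrom}\tsim\ttranscript\t{start0 + 1}\t{end0}\t.\t{ts.strand}\t.\t{attrs}\n"
            )


def write_sam(
    profile: ReadStartProfile,
    path: str,
    read_length: int = 27,
    mapq: int = 30,
) -> None:
    """Write one SAM record per read start so loaders reproduce the profile.

    Forward reads start at the profile position; reverse reads end there
    (their 5' cap-proximal base is the rightmost aligned base). Reads are
    shortened at chromosome edges so alignments stay in bounds.
    """
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(profile.chrom_lengths):
            handle.write(f"@SQ\tSN:{chrom}\tLN:{profile.chrom_lengths[chrom]}\n")
        serial = 0
        for chrom, strand in profile.keys():
            length = profile.chrom_lengths[chrom]
            pos, cnt, _ = profile.arrays(chrom, strand)
            for p, c in zip(pos, cnt):
                p = int(p)
                if strand == "+":
                    span = min(read_length, length - p)
                    left = p
                    flag = 0
                else:
                    span = min(read_length, p + 1)
                    left = p - span + 1
                    flag = 16
                for _ in range(int(c)):
                    serial += 1
                    handle.write(
                        f"r{serial}\t{flag}\t{chrom}\t{left + 1}\t{mapq}\t{span}M\t*\t0\t0\t"
                        f"{'A' * span}\t{'I' * span}\n"
                    )


def write_bedgraph(track: ScoreTrack, path: str) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(track._records):
            for start, end, score in sorted(track._records[chrom]):
                handle.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")


def write_truth_bed(truth: list[TruthPeak], path: str) -> None:
    with open(path, "w") as handle:
        for i, t in enumerate(truth, start=1):
            iv = t.interval
            name = f"{'tss' if t.is_tss else 'nontss'}_{i}"
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{t.read_count}\t{iv.strand}\n"
            )


@dataclass
class CellLineData:
    """Everything simulated for one cell line."""

    name: str
    profile: ReadStartProfile
    truth: list[TruthPeak]
    rnaseq: ReadStartProfile


@dataclass
class Study:
    """A multi-cell-line synthetic study sharing one genome and annotation."""

    genome: dict[str, str]
    chrom_lengths: dict[str, int]
    transcripts: list[TranscriptStart]
    tracks: dict[str, ScoreTrack]
    cell_lines: dict[str, CellLineData]


def default_planted_peaks(
    chrom: str,
    chrom_length: int,
    n_tss: int,
    n_non_tss: int,
    rng: np.random.Generator,
    min_reads: int = 40,
    max_reads: int = 120,
) -> list[PlantedPeak]:
    """Evenly spaced alternating TSS / non-TSS clusters with randomized counts.

    TSS clusters are narrow (spread 5); non-TSS clusters are broad
    (spread 40), mimicking recapping signal inside exons.
    """
    total = n_tss + n_non_tss
    margin = 2000
    positions = np.linspace(margin, chrom_length - margin, total).astype(int)
    flags = np.array([True] * n_tss + [False] * n_non_tss)
    rng.shuffle(flags)  # decouple class from genomic order
    peaks: list[PlantedPeak] = []
    for i, (pos, is_tss) in enumerate(zip(positions, flags)):
        peaks.append(
            PlantedPeak(
                chrom=chrom,
                position=int(pos),
                strand="+" if i % 2 == 0 else "-",
                read_count=int(rng.integers(min_reads, max_reads + 1)),
                spread=5 if is_tss else 40,
                is_tss=bool(is_tss),
            )
        )
    return peaks


def simulate_study(
    seed: int = 0,
    n_cell_lines: int = 3,
    chrom_length: int = 120_000,
    n_tss: int = 24,
    n_non_tss: int = 24,
    background_rate: float = 0.001,
) -> Study:
    """Simulate a shared genome/annotation/tracks and per-line CAGE + RNA-seq."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    chrom = "chrS"
    planted = default_planted_peaks(chrom, chrom_length, n_tss, n_non_tss, rng)
    base_spec = SimulationSpec(
        seed=seed,
        chrom_lengths={chrom: chrom_length},
        planted_peaks=planted,
        background_rate=background_rate,
    )
    genome = simulate_genome(base_spec)
    cell_lines: dict[str, CellLineData] = {}
    tracks: dict[str, ScoreTrack] | None = None
    transcripts: list[TranscriptStart] | None = None
    for i in range(n_cell_lines):
        line_rng = np.random.default_rng(np.random.SeedSequence([seed, 100 + i]))
        jittered = [
            replace(p, read_count=int(max(30, p.read_count + line_rng.integers(-10, 11))))
            for p in planted
        ]
        line_spec = replace(base_spec, seed=seed * 1000 + i, planted_peaks=jittered)
        profile, truth = simulate_cage_profile(line_spec)
        line_tracks, rnaseq = simulate_external_tracks(line_spec, truth)
        if tracks is None:
            tracks = line_tracks  # pooled tracks: shared across lines
            transcripts = simulate_annotation(truth)
        cell_lines[f"line{i + 1}"] = CellLineData(
            name=f"line{i + 1}", profile=profile, truth=truth, rnaseq=rnaseq
        )
    assert tracks is not None and transcripts is not None
    return Study(
        genome=genome,
        chrom_lengths=dict(base_spec.chrom_lengths),
        transcripts=transcripts,
        tracks=tracks,
        cell_lines=cell_lines,
    )


def write_study(study: Study, outdir: str) -> dict[str, str]:
    """Write a study to disk as FASTA/SAM/GTF/bedGraph/BED; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    paths["genome"] = os.path.join(outdir, "genome.fa")
    write_fasta(study.genome, paths["genome"])
    paths["annotation"] = os.path.join(outdir, "annotation.gtf")
    write_gtf(study.transcripts, study.chrom_lengths, paths["annotation"])
    for name, track in study.tracks.items():
        key = f"track_{name}"
        paths[key] = os.path.join(outdir, f"{name}.bedGraph")
        write_bedgraph(track, paths[key])
    for name, data in study.cell_lines.items():
        paths[f"cage_{name}"] = os.path.join(outdir, f"{name}.cage.sam")
        write_sam(data.profile, paths[f"cage_{name}"])
        paths[f"rnaseq_{name}"] = os.path.join(outdir, f"{name}.rnaseq.sam")
        write_sam(data.rnaseq, paths[f"rnaseq_{name}"])
        paths[f"truth_{name}"] = os.path.join(outdir, f"{name}.truth.bed")
        write_truth_bed(data.truth, paths[f"truth_{name}"])
    return paths
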