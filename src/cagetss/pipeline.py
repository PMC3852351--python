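"""End-to-end orchestration: callpeaks -> features -> select -> classify.

A single declarative config drives the run; every output directory gets a
manifest stamped with the config hash so identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cagetss import __version__
from cagetss.classification import (
    DEFAULT_COST_GRID,
    SCENARIOS,
    label_peaks,
    loocv,
    rescale_for_scenario,
)
from cagetss.feature_extraction import build_feature_matrix
from cagetss.feature_selection import (
    run_feature_selection,
    standardize_features,
    write_selection,
)
from cagetss.genomic_io import (
    load_read_starts,
    load_score_track,
    load_transcript_starts,
    read_fasta,
    write_peaks_bed,
)
from cagetss.peak_calling import PeakCallingParams, call_peaks

logger = logging.getLogger(__name__)

TRACK_NAMES = ("tfbs", "dnase", "h3k4me3", "conservation")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    genome_fasta: str
    annotation_gtf: str
    cell_lines: dict[str, dict]  # name -> {"cage": path, "rnaseq": path|None}
    outdir: str
    tracks: dict[str, str] = field(default_factory=dict)
    peak_params: PeakCallingParams = field(default_factory=PeakCallingParams)
    scenario: str = "internal"
    selection_threshold: float = 0.5
    correlation_mode: str = "paper"
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    label_half_window: int = 500
    stranded_labels: bool = False
    strand_naive: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        params = raw.pop("peak_params", {})
        if isinstance(params, dict):
            params = PeakCallingParams(**params)
        cost_grid = tuple(float(c) for c in raw.pop("cost_grid", DEFAULT_COST_GRID))
        config = cls(peak_params=params, cost_grid=cost_grid, **raw)
        config.validate()
        return config

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        missing = [p for p in (self.genome_fasta, self.annotation_gtf) if not os.path.exists(p)]
        for name, path in self.tracks.items():
            if name not in TRACK_NAMES:
                raise ValueError(f"unknown track {name!r}; expected one of {TRACK_NAMES}")
            if not os.path.exists(path):
                missing.append(path)
        if len(self.cell_lines) < 2:
            raise ValueError("need at least 2 cell lines for leave-one-out evaluation")
        for line, paths in self.cell_lines.items():
            if "cage" not in paths:
                raise ValueError(f"cell line {line!r} missing 'cage' alignment path")
            if not os.path.exists(paths["cage"]):
                missing.append(paths["cage"])
            if self.scenario == "rnaseq":
                if not paths.get("rnaseq"):
                    raise ValueError(
                        f"scenario 'rnaseq' requires an rnaseq path for cell line {line!r}"
                    )
                if not os.path.exists(paths["rnaseq"]):
                    missing.append(paths["rnaseq"])
        if self.scenario == "pooled":
            absent = [t for t in ("tfbs", "dnase", "h3k4me3") if t not in self.tracks]
            if absent:
                raise ValueError(f"scenario 'pooled' requires tracks: {absent}")
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def to_jsonable(self) -> dict:
        return {
            "genome_fasta": self.genome_fasta,
            "annotation_gtf": self.annotation_gtf,
            "cell_lines": self.cell_lines,
            "outdir": self.outdir,
            "tracks": self.tracks,
            "peak_params": vars(self.peak_params),
            "scenario": self.scenario,
            "selection_threshold": self.selection_threshold,
            "correlation_mode": self.correlation_mode,
            "cost_grid": list(self.cost_grid),
            "label_half_window": self.label_half_window,
            "stranded_labels": self.stranded_labels,
            "strand_naive": self.strand_naive,
            "seed": self.seed,
        }


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict with output paths and metrics."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    stage = "setup"
    try:
        genome = read_fasta(config.genome_fasta)
        transcripts = load_transcript_starts(config.annotation_gtf)
        tracks = {name: load_score_track(path) for name, path in config.tracks.items()}

        datasets: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
        matrices: list[pd.DataFrame] = []
        labels_by_line: dict[str, np.ndarray] = {}
        peak_counts: dict[str, int] = {}
        for line in sorted(config.cell_lines):
            stage = f"callpeaks[{line}]"
            paths = config.cell_lines[line]
            profile = load_read_starts(paths["cage"], config.peak_params.mapq_min)
            peaks = call_peaks(profile, config.peak_params)
            peak_counts[line] = len(peaks)
            logger.info("%s: %d peaks called", line, len(peaks))
            bed_path = os.path.join(config.outdir, f"peaks_{line}.bed")
            write_peaks_bed(peaks, bed_path)

            stage = f"features[{line}]"
            rnaseq = (
                load_read_starts(paths["rnaseq"], 0)
                if paths.get("rnaseq")
                else None
            )
            matrix = build_feature_matrix(
                peaks,
                profile,
                genome,
                cell_line=line,
                tracks=tracks or None,
                rnaseq_profile=rnaseq,
                strand_naive=config.strand_naive,
            )
            matrix.to_csv(
                os.path.join(config.outdir, f"features_{line}.tsv"), sep="\t"
            )
            matrices.append(matrix)

            stage = f"labels[{line}]"
            labels = label_peaks(
                peaks,
                transcripts,
                half_window=config.label_half_window,
                stranded=config.stranded_labels,
            )
            labels_by_line[line] = labels
            logger.info(
                "%s: %d TSS / %d non-TSS labels", line, int(labels.sum()),
                int((~labels).sum()),
            )

        stage = "select"
        pooled = pd.concat(matrices, axis=0)
        standardized = standardize_features(pooled)
        selection = run_feature_selection(
            standardized,
            threshold=config.selection_threshold,
            mode=config.correlation_mode,
        )
        write_selection(selection, os.path.join(config.outdir, "selection.json"))

        stage = "classify"
        for line in sorted(config.cell_lines):
            block = standardized[standardized["cell_line"] == line]
            X = rescale_for_scenario(block, selection, config.scenario)
            datasets[line] = (X, labels_by_line[line])
        result = loocv(datasets, config.cost_grid)
        results_path = os.path.join(config.outdir, "results.tsv")
        result.table.to_csv(results_path, sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "config": config.to_jsonable(),
            "peak_counts": peak_counts,
            "selected_single": selection["single"].selected,
            "n_selected_kmers": len(selection["kmer"].selected),
        }
        with open(os.path.join(config.outdir, "manifest.json"), "w") as handle:
            json.dump(manifest, handle, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    return {
        "outdir": config.outdir,
        "peak_counts": peak_counts,
        "selection": selection,
        "evaluation": result,
    }
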