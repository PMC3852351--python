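"""TSS/non-TSS peak classification.

Peaks are labelled by overlap with windows around annotated transcript
starts, feature blocks are rescaled so each block carries comparable
weight in the margin, and an L2-regularized L2-loss linear SVM (primal)
with per-class error weights is evaluated by leave-one-cell-line-out
cross-validation over a grid of cost values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from cagetss.genomic_io import TranscriptStart
from cagetss.feature_selection import SelectionResult, feature_columns

logger = logging.getLogger(__name__)

SCENARIOS = ("internal", "pooled", "rnaseq")

#: externally-derived max-score features pooled across cell types
POOLED_EXTERNAL = ("tfbs_max", "dnase_max", "h3k4me3_max", "conservation_mean")

DEFAULT_COST_GRID = tuple(10.0**e for e in range(-6, 3))

#: costs included in headline summaries
SUMMARY_MIN_COST = 1e-4


@dataclass
class SvmSpec:
    """L2-regularized L2-loss linear SVM, solved in the primal."""

    cost: float = 1.0
    class_weights: dict[bool, float] = field(default_factory=lambda: {True: 1.0, False: 1.0})

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")


def _merged_label_windows(
    transcript_starts: list[TranscriptStart], half_window: int, stranded: bool
) -> dict:
    """Per (chrom[, strand]): sorted, merged window starts/ends arrays."""
    grouped: dict = {}
    for ts in transcript_starts:
        key = (ts.chrom, ts.strand) if stranded else ts.chrom
        grouped.setdefault(key, []).append(
            (max(0, ts.position - half_window), ts.position + half_window)
        )
    merged: dict = {}
    for key, windows in grouped.items():
        windows.sort()
        out: list[list[int]] = []
        for s, e in windows:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[key] = (
            np.array([w[0] for w in out], dtype=np.int64),
            np.array([w[1] for w in out], dtype=np.int64),
        )
    return merged


def label_peaks(
    peaks,
    transcript_starts: list[TranscriptStart],
    half_window: int = 500,
    stranded: bool = False,
) -> np.ndarray:
    """Boolean TSS labels: True when a peak overlaps any transcript-start window.

    Each transcript start at position p contributes the window
    [p - half_window, p + half_window); any overlap labels the peak TSS.
    Strand is ignored unless ``stranded`` is set.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    windows = _merged_label_windows(transcript_starts, half_window, stranded)
    labels = np.zeros(len(peaks), dtype=bool)
    for i, peak in enumerate(peaks):
        iv = peak.interval
        key = (iv.chrom, iv.strand) if stranded else iv.chrom
        arrs = windows.get(key)
        if arrs is None:
            continue
        starts, ends = arrs
        j = int(np.searchsorted(starts, iv.end, side="left"))
        # merged windows have increasing ends, so only the last candidate matters
        labels[i] = j > 0 and ends[j - 1] > iv.start
    return labels


def class_weights(labels: np.ndarray) -> dict[bool, float]:
    """TSS weight = n_nonTSS / n_TSS; non-TSS weight = 1."""
    labels = np.asarray(labels, dtype=bool)
    n_tss = int(labels.sum())
    n_non = int((~labels).sum())
    if n_tss == 0 or n_non == 0:
        raise ValueError("both classes must be present to compute weights")
    return {True: n_non / n_tss, False: 1.0}


def rescale_for_scenario(
    matrix: pd.DataFrame,
    selection: dict[str, SelectionResult],
    scenario: str = "internal",
) -> pd.DataFrame:
    """Block-rescale standardized features into the scenario's design matrix.

    With m selected k-mers: k-mer columns stay in [0, 1]; each selected
    single internal feature (e.g. kurtosis) is multiplied by m; each pooled
    external feature by 2m/3; the RNA-seq feature by 2m. Returns feature
    columns only (metadata dropped).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    kmer_cols = list(selection["kmer"].selected)
    single_cols = list(selection["single"].selected)
    m = len(kmer_cols)
    if m == 0:
        raise ValueError("no k-mer features selected; refusing to build design matrix")
    available = set(feature_columns(matrix))
    missing = [c for c in kmer_cols + single_cols if c not in available]
    if missing:
        raise ValueError(f"selected features absent from matrix: {missing}")

    internal_singles = [
        c for c in single_cols if c not in POOLED_EXTERNAL and c != "rnaseq_diff"
    ]
    external_singles = [c for c in single_cols if c in POOLED_EXTERNAL]

    pieces: dict[str, pd.Series] = {}
    for col in internal_singles:
        pieces[col] = matrix[col].astype(float) * m
    for col in kmer_cols:
        pieces[col] = matrix[col].astype(float)
    if scenario == "pooled":
        if not external_singles:
            raise ValueError("pooled scenario requested but no external feature selected")
        for col in external_singles:
            pieces[col] = matrix[col].astype(float) * (2.0 * m / 3.0)
    if scenario == "rnaseq":
        if "rnaseq_diff" not in available:
            raise ValueError("rnaseq scenario requested but rnaseq_diff column absent")
        pieces["rnaseq_diff"] = matrix["rnaseq_diff"].astype(float) * (2.0 * m)
    return pd.DataFrame(pieces, index=matrix.index)


def train_svm(
    X, y, spec: SvmSpec | None = None
) -> LinearSVC:
    """Fit the weighted primal linear SVM; deterministic for fixed inputs."""
    if spec is None:
        spec = SvmSpec()
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    model = LinearSVC(
        penalty="l2",
        loss="squared_hinge",
        dual=False,
        C=spec.cost,
        class_weight={True: spec.class_weights[True], False: spec.class_weights[False]},
        tol=1e-6,
        max_iter=20000,
    )
    try:
        model.fit(X, y)
    except Exception as exc:  # surfaced with context per contract
        raise RuntimeError(f"SVM training failed (cost={spec.cost}): {exc}") from exc
    return model


def precision_recall(
    predictions, labels
) -> tuple[float | None, float | None]:
    """(precision, recall) with TSS as the positive class.

    A zero denominator yields None for that metric, never a silent 0.
    """
    predictions = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int((predictions & labels).sum())
    fp = int((predictions & ~labels).sum())
    fn = int((~predictions & labels).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return precision, recall


@dataclass
class EvaluationResult:
    """Per-(held-out line, cost) precision/recall with per-cost summaries."""

    table: pd.DataFrame  # columns: cell_line, cost, precision, recall

    def summary(self, min_cost: float | None = SUMMARY_MIN_COST) -> pd.DataFrame:
        """Per-cost min/mean/max across folds, optionally restricted to cost >= min_cost."""
        table = self.table
        if min_cost is not None:
            table = table[table["cost"] >= min_cost]
        return (
            table.groupby("cost")[["precision", "recall"]]
            .agg(["min", "mean", "max"])
            .reset_index()
        )


def loocv(
    datasets: dict[str, tuple[pd.DataFrame, np.ndarray]],
    cost_grid=DEFAULT_COST_GRID,
) -> EvaluationResult:
    """Leave-one-cell-line-out cross-validation over a cost grid.

    For each cost and each held-out line the SVM is trained on the pooled
    remaining lines with class weights computed from the training pool only.
    Folds whose training pool lacks a class are skipped with a warning.
    """
    lines = sorted(datasets)
    if len(lines) < 2:
        raise ValueError("need at least 2 cell lines for leave-one-out")
    records: list[dict] = []
    for held_out in lines:
        train_X = pd.concat(
            [datasets[line][0] for line in lines if line != held_out], axis=0
        )
        train_y = np.concatenate(
            [np.asarray(datasets[line][1], dtype=bool) for line in lines if line != held_out]
        )
        if train_y.all() or not train_y.any():
            logger.warning("fold %s: training pool lacks a class; skipped", held_out)
            continue
        weights = class_weights(train_y)
        test_X, test_y = datasets[held_out]
        test_y = np.asarray(test_y, dtype=bool)
        for cost in cost_grid:
            model = train_svm(
                train_X.to_numpy(dtype=float),
                train_y,
                SvmSpec(cost=float(cost), class_weights=weights),
            )
            pred = model.predict(test_X.to_numpy(dtype=float)).astype(bool)
            precision, recall = precision_recall(pred, test_y)
            records.append(
                {
                    "cell_line": held_out,
                    "cost": float(cost),
                    "precision": np.nan if precision is None else precision,
                    "recall": np.nan if recall is None else recall,
                }
            )
    return EvaluationResult(table=pd.DataFrame(records, columns=["cell_line", "cost", "precision", "recall"]))
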