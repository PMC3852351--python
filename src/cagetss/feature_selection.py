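"""Feature standardization and PCA-based selection.

Features are scaled to [0, 1] by their per-cell-line maximum, pooled over
all cell lines, and scored by their association with the first principal
component. The default score is the PC1 loading multiplied by the PC1
eigenvalue; a conventional variable-component correlation
(loading x sqrt(eigenvalue) / feature sd) is available as an alternative
mode. Single features and the k-mer block are selected in independent
PCA runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cagetss.genomic_io import META_COLUMNS

logger = logging.getLogger(__name__)

CORRELATION_MODES = ("paper", "textbook")


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """All non-metadata columns of a feature matrix."""
    return [c for c in matrix.columns if c not in META_COLUMNS]


@dataclass
class SelectionResult:
    """Per-feature PC1 association scores and the retained features."""

    feature_correlations: dict[str, float]
    threshold: float = 0.5
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected:
            self.selected = [
                name
                for name, rho in self.feature_correlations.items()
                if abs(rho) >= self.threshold
            ]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "selected": list(self.selected),
            "correlations": dict(self.feature_correlations),
        }


def standardize_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each feature column by its per-cell-line maximum.

    Columns whose maximum is not positive within a cell line are passed
    through unchanged with a warning.
    """
    out = matrix.copy()
    cols = feature_columns(matrix)
    out[cols] = out[cols].astype(float)
    for line, idx in out.groupby("cell_line").groups.items():
        block = out.loc[idx, cols].astype(float)
        maxima = block.max(axis=0)
        bad = maxima[~(maxima > 0)].index
        if len(bad):
            logger.warning(
                "cell line %s: %d feature(s) with non-positive maximum left unscaled",
                line, len(bad),
            )
        scale = maxima.where(maxima > 0, 1.0)
        out.loc[idx, cols] = block / scale
    return out


def pca_feature_correlations(
    matrix: pd.DataFrame,
    columns: list[str] | None = None,
    mode: str = "paper",
) -> pd.Series:
    """Association of each feature with PC1 of the pooled standardized matrix.

    ``paper`` mode returns loading x eigenvalue; ``textbook`` mode the
    variable-component correlation loading x sqrt(eigenvalue) / sd, clipped
    to [-1, 1]. PC1's sign is fixed so the largest-|loading| feature has a
    negative loading.
    """
    if mode not in CORRELATION_MODES:
        raise ValueError(f"mode must be one of {CORRELATION_MODES}")
    if columns is None:
        columns = feature_columns(matrix)
    if len(columns) < 2:
        raise ValueError("need at least 2 features for PCA")
    X = matrix[columns].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for PCA")
    centered = X - X.mean(axis=0)
    if not np.any(centered):
        raise ValueError("constant matrix has no principal components")
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] > 0:
        loading = -loading
    if mode == "paper":
        rho = loading * eigenvalues[0]
    else:
        sd = X.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = loading * np.sqrt(eigenvalues[0]) / sd
        rho = np.clip(np.nan_to_num(rho, nan=0.0, posinf=0.0, neginf=0.0), -1.0, 1.0)
    return pd.Series(rho, index=columns, name="rho")


def select_features(
    correlations: pd.Series | dict[str, float], threshold: float = 0.5
) -> SelectionResult:
    """Retain features with |rho| >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(correlations, pd.Series):
        correlations = correlations.to_dict()
    return SelectionResult(
        feature_correlations={k: float(v) for k, v in correlations.items()},
        threshold=threshold,
    )


def run_feature_selection(
    matrix: pd.DataFrame,
    threshold: float = 0.5,
    mode: str = "paper",
    kmer_prefixes: tuple[str, ...] = ("up_", "down_"),
) -> dict[str, SelectionResult]:
    """Select single features and k-mers in independent PCA runs.

    ``matrix`` must already be standardized; rows from all cell lines are
    pooled. Returns ``{"single": ..., "kmer": ...}``.
    """
    cols = feature_columns(matrix)
    kmer_cols = [c for c in cols if c.startswith(kmer_prefixes)]
    # the RNA-seq feature is scenario-scaled downstream, never PCA-selected
    # (it exists only for a subset of cell lines in the motivating design)
    single_cols = [c for c in cols if c not in kmer_cols and c != "rnaseq_diff"]
    result: dict[str, SelectionResult] = {}
    for block, block_cols in (("single", single_cols), ("kmer", kmer_cols)):
        if len(block_cols) < 2:
            result[block] = SelectionResult(feature_correlations={}, threshold=threshold)
            continue
        rho = pca_feature_correlations(matrix, block_cols, mode=mode)
        result[block] = select_features(rho, threshold)
        logger.info(
            "%s block: %d/%d features selected at |rho| >= %.3g",
            block, len(result[block].selected), len(block_cols), threshold,
        )
    return result


def write_selection(selection: dict[str, SelectionResult], path: str) -> None:
    with open(path, "w") as handle:
        json.dump({k: v.to_dict() for k, v in selection.items()}, handle, indent=2)


def read_selection(path: str) -> dict[str, SelectionResult]:
    with open(path) as handle:
        raw = json.load(handle)
    return {
        k: SelectionResult(
            feature_correlations=v["correlations"],
            threshold=v["threshold"],
            selected=list(v["selected"]),
        )
        for k, v in raw.items()
    }
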