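"""Single-cell detection statistics guided by a bulk-assembled transcript set.

The count matrix is transcripts x cells. Size factors use the
median-of-ratios procedure (per-cell median, over reference transcripts, of
the count divided by the transcript's geometric mean across cells). When no
transcript is nonzero in every cell — common in sparse single-cell data —
a fallback uses transcripts nonzero in at least half the cells, with
geometric means and ratio medians taken over the positive counts only; the
output flags when the fallback was used.

Detection is thresholded on raw counts (default: count >= 1), with
normalized expression reported alongside. The coefficient of variation is
computed over detecting (nonzero) cells by default, because zero inflation
otherwise dominates; ``cv_mode="all"`` switches to all cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .saturation import spearman_rho
from .types import CODING, NONCODING, UNKNOWN


@dataclass
class CellMatrix:
    """Cells x transcripts counts with per-cell tag totals."""

    counts: np.ndarray  # transcripts x cells, non-negative integers
    transcript_ids: list[str]
    barcodes: list[str]
    classes: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (transcripts x cells)")
        if self.counts.shape != (len(self.transcript_ids), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.barcodes)} cells"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def tag_total(self) -> np.ndarray:
        """Per-cell total tag count (column sums)."""
        return self.counts.sum(axis=0)

    def class_of(self, tid: str) -> str:
        return (self.classes or {}).get(tid, UNKNOWN)

    def subset(self, transcript_ids: Sequence[str]) -> "CellMatrix":
        """Restrict to a guiding transcript set (rows), keeping cells."""
        index = {t: i for i, t in enumerate(self.transcript_ids)}
        rows = [index[t] for t in transcript_ids if t in index]
        ids = [self.transcript_ids[i] for i in rows]
        return CellMatrix(
            counts=self.counts[rows, :],
            transcript_ids=ids,
            barcodes=list(self.barcodes),
            classes=None if self.classes is None
            else {t: self.classes[t] for t in ids if t in self.classes},
        )


@dataclass
class NormalizationResult:
    normalized: np.ndarray
    size_factors: np.ndarray
    fallback_used: bool = False


def normalize_median_of_ratios(
    matrix: CellMatrix, fallback: bool = True, fallback_min_cells: float = 0.5
) -> NormalizationResult:
    """Median-of-ratios size factors; normalized count = count / size factor."""
    counts = matrix.counts.astype(float)
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to normalize")
    all_nonzero = np.all(counts > 0, axis=1)
    fallback_used = False
    if all_nonzero.any():
        ref = counts[all_nonzero]
        log_geo = np.mean(np.log(ref), axis=1)
        ratios = np.log(ref) - log_geo[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    else:
        if not fallback:
            raise ValueError(
                "no transcript has nonzero counts in all cells and fallback "
                "is disabled"
            )
        fallback_used = True
        frac_nonzero = np.mean(counts > 0, axis=1)
        ref_rows = np.nonzero(frac_nonzero >= fallback_min_cells)[0]
        if ref_rows.size == 0:
            raise ValueError(
                "no transcript is nonzero in enough cells to normalize"
            )
        with np.errstate(divide="ignore"):
            logs = np.where(counts[ref_rows] > 0, np.log(counts[ref_rows]), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = logs - log_geo[:, None]
        sf = np.exp(np.nanmedian(ratios, axis=0))
        if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
            raise ValueError("could not compute positive size factors for all cells")
    normalized = counts / sf[None, :]
    return NormalizationResult(
        normalized=normalized, size_factors=sf, fallback_used=fallback_used
    )


@dataclass
class DetectionStats:
    """Per-transcript and per-cell detection summaries."""

    per_transcript: pd.DataFrame  # transcript_id, coding_class, pct_cells, mean_norm, cv
    per_cell: pd.DataFrame  # barcode, tag_total, n_detected, n_detected_coding, ...
    threshold: int = 1


def detection_stats(
    matrix: CellMatrix,
    normalized: np.ndarray | None = None,
    threshold: int = 1,
    cv_mode: str = "detecting",
) -> DetectionStats:
    """Detection percentages, mean normalized expression and CV per transcript;
    detected transcript counts per cell and class.

    A transcript is detected in a cell when its raw count >= ``threshold``.
    Mean and CV of normalized expression are over detecting cells
    (``cv_mode="detecting"``) or over all cells (``cv_mode="all"``).
    """
    if cv_mode not in ("detecting", "all"):
        raise ValueError("cv_mode must be 'detecting' or 'all'")
    counts = matrix.counts
    norm = counts.astype(float) if normalized is None else np.asarray(normalized)
    detected = counts >= threshold
    n_cells = matrix.n_cells

    pct = 100.0 * detected.sum(axis=1) / n_cells
    mean_norm = np.full(matrix.n_transcripts, np.nan)
    cv = np.full(matrix.n_transcripts, np.nan)
    for i in range(matrix.n_transcripts):
        vals = norm[i, detected[i]] if cv_mode == "detecting" else norm[i]
        if vals.size:
            mu = float(np.mean(vals))
            mean_norm[i] = mu
            if mu > 0:
                cv[i] = float(np.std(vals) / mu)
    per_transcript = pd.DataFrame(
        {
            "transcript_id": matrix.transcript_ids,
            "coding_class": [matrix.class_of(t) for t in matrix.transcript_ids],
            "pct_cells_detected": pct,
            "mean_normalized": mean_norm,
            "cv": cv,
        }
    )

    cls = np.array([matrix.class_of(t) for t in matrix.transcript_ids])
    per_cell = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "tag_total": matrix.tag_total,
            "n_detected": detected.sum(axis=0),
            "n_detected_coding": detected[cls == CODING].sum(axis=0),
            "n_detected_noncoding": detected[cls == NONCODING].sum(axis=0),
        }
    )
    return DetectionStats(
        per_transcript=per_transcript, per_cell=per_cell, threshold=threshold
    )


def depth_detection_correlation(stats: DetectionStats) -> dict[str, float]:
    """Spearman rho between per-cell tag totals and detected-transcript counts."""
    pc = stats.per_cell
    if len(pc) < 3:
        raise ValueError("need at least 3 cells")
    return {
        "overall": spearman_rho(pc["tag_total"], pc["n_detected"]),
        CODING: spearman_rho(pc["tag_total"], pc["n_detected_coding"]),
        NONCODING: spearman_rho(pc["tag_total"], pc["n_detected_noncoding"]),
    }


def compare_guided_detection(
    matrix_a: CellMatrix,
    matrix_b: CellMatrix,
    threshold: int = 1,
) -> pd.DataFrame:
    """Per-cell paired detection counts under two guiding transcript sets.

    Returns one row per cell and class with (n_detected_a, n_detected_b) and
    an ``above_diagonal`` flag (b strictly greater). The summary fraction of
    cells above the diagonal per class is::

        out.groupby("coding_class")["above_diagonal"].mean()
    """
    if matrix_a.barcodes != matrix_b.barcodes:
        raise ValueError("barcode mismatch between the two matrices")
    stats_a = detection_stats(matrix_a, threshold=threshold)
    stats_b = detection_stats(matrix_b, threshold=threshold)
    rows = []
    for cls, col in (
        ("overall", "n_detected"),
        (CODING, "n_detected_coding"),
        (NONCODING, "n_detected_noncoding"),
    ):
        a = stats_a.per_cell[col].to_numpy()
        b = stats_b.per_cell[col].to_numpy()
        for bc, na, nb in zip(matrix_a.barcodes, a, b):
            rows.append(
                {
                    "barcode": bc,
                    "coding_class": cls,
                    "n_detected_a": int(na),
                    "n_detected_b": int(nb),
                    "above_diagonal": bool(nb > na),
                }
            )
    return pd.DataFrame(rows)
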