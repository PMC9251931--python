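"""Depth-count statistics: rank correlation, loess, increments, binning.

A *depth series* is a tidy table with one row per sample:
``sample_id, group_label, depth, n_all, n_coding, n_noncoding``. The depth
may be measured as total, mapped or transcript-assigned reads; the caller
picks the measure when building the series.

Loess here is the minimal standard variant: degree-1 local regression with
tricube weights over the span-nearest neighbours, no robustness iterations.
Extrapolation beyond the observed depth range is clamped to the boundary
value (recorded in the increment table metadata), since increment grids
start at 0 reads where no data exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .types import CODING, NONCODING, Assembly

SERIES_COLUMNS = [
    "sample_id",
    "group_label",
    "depth",
    "n_all",
    "n_coding",
    "n_noncoding",
]


def depth_series_from_assemblies(
    assemblies: Sequence[Assembly], depth_measure: str = "total"
) -> pd.DataFrame:
    """Build a depth series from per-sample assemblies and their metadata."""
    attr = {
        "total": "total_reads",
        "mapped": "mapped_reads",
        "assigned": "assigned_reads",
    }[depth_measure]
    rows = []
    for asm in assemblies:
        counts = asm.class_counts()
        rows.append(
            {
                "sample_id": asm.meta.sample_id,
                "group_label": asm.meta.group_label,
                "depth": getattr(asm.meta, attr),
                "n_all": len(asm),
                "n_coding": counts[CODING],
                "n_noncoding": counts[NONCODING],
            }
        )
    return pd.DataFrame(rows, columns=SERIES_COLUMNS)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined) for constant input. Requires length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(scipy.stats.spearmanr(x, y).statistic)


@dataclass
class LoessFit:
    """A fitted local-linear smoother over a depth axis."""

    x: np.ndarray
    y: np.ndarray
    span: float
    rho: float
    degree: int = 1

    @property
    def x_min(self) -> float:
        return float(self.x.min())

    @property
    def x_max(self) -> float:
        return float(self.x.max())

    def _neighborhood(self, x0: float):
        n = len(self.x)
        q = max(3, int(np.ceil(self.span * n)))
        q = min(q, n)
        d = np.abs(self.x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
            if w.sum() == 0:  # every neighbor exactly at dmax (tied designs)
                w = np.ones(q)
        return idx, w

    def _point(self, x0: float) -> tuple[float, np.ndarray]:
        """Fitted value at x0 and the equivalent-kernel weight vector l
        (fit = l . y over the neighborhood)."""
        idx, w = self._neighborhood(x0)
        xs, sw = self.x[idx], np.sqrt(w)
        X = np.column_stack([np.ones_like(xs), xs - x0])
        A = X * sw[:, None]
        # fitted(x0) = e1' pinv(A) (sw*y); pinv degrades to a local constant
        # fit when all positively weighted neighbors share one x value
        l = np.linalg.pinv(A)[0] * sw
        return float(l @ self.y[idx]), (idx, l)

    def predict(self, grid, clamp: bool = True) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        if clamp:
            grid = np.clip(grid, self.x_min, self.x_max)
        return np.array([self._point(x0)[0] for x0 in grid])

    def standard_error(self, grid, clamp: bool = True) -> np.ndarray:
        """Pointwise SE band: sigma_hat * ||l||, with sigma_hat from the
        residual variance at the training points."""
        resid = self.y - self.predict(self.x, clamp=False)
        dof = max(len(self.x) - 2, 1)
        sigma = float(np.sqrt(np.sum(resid**2) / dof))
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        if clamp:
            grid = np.clip(grid, self.x_min, self.x_max)
        return np.array(
            [sigma * float(np.linalg.norm(self._point(x0)[1][1])) for x0 in grid]
        )


def loess_fit(depths, counts, span: float = 0.75) -> LoessFit:
    """Fit a tricube-weighted local linear regression of counts on depth."""
    x = np.asarray(depths, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(x) != len(y):
        raise ValueError("depths and counts must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 points for a loess fit")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if int(np.ceil(span * len(x))) < 3:
        raise ValueError("span too small: neighborhoods would have < 3 points")
    rho = spearman_rho(x, y) if len(x) >= 3 else float("nan")
    return LoessFit(x=x, y=y, span=span, rho=rho)


@dataclass
class IncrementTable:
    """Predicted counts on a 0..max_depth grid and per-step increments."""

    grid: np.ndarray
    predicted: np.ndarray
    increments: np.ndarray
    step: float
    clamped: bool = True  # predictions outside the data range are clamped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.grid[1:],
                "predicted": self.predicted[1:],
                "increment": self.increments,
            }
        )


def increments(fit: LoessFit, max_depth: float, step: float = 1e7) -> IncrementTable:
    """Increment in predicted count per additional ``step`` reads.

    ``increment_i = fit((i+1) step) - fit(i step)``; increments telescope to
    ``fit(max) - fit(0)`` (with boundary clamping for the 0-read end).
    """
    n_steps = int(np.floor(max_depth / step + 1e-9))
    grid = np.arange(n_steps + 1) * step
    pred = fit.predict(grid, clamp=True)
    return IncrementTable(
        grid=grid, predicted=pred, increments=np.diff(pred), step=step
    )


def bin_by_depth(series: pd.DataFrame, width: float = 1e7) -> pd.DataFrame:
    """Group samples into half-open depth bins [i*width, (i+1)*width).

    Returns per-bin boxplot-style summaries (count, min, quartiles, max) of
    each transcript-count column.
    """
    df = series.copy()
    df["bin"] = (df["depth"] // width).astype(int)
    pieces = []
    for col in ("n_all", "n_coding", "n_noncoding"):
        g = df.groupby("bin")[col]
        summ = g.agg(
            n="count",
            min="min",
            q1=lambda s: s.quantile(0.25),
            median="median",
            q3=lambda s: s.quantile(0.75),
            max="max",
        )
        summ["column"] = col
        pieces.append(summ.reset_index())
    return pd.concat(pieces, ignore_index=True)


def coding_noncoding_ratio(series: pd.DataFrame) -> pd.Series:
    """n_coding / n_noncoding per row; zero noncoding -> NaN (undefined)."""
    ratio = series["n_coding"] / series["n_noncoding"].replace(0, np.nan)
    ratio.name = "coding_noncoding_ratio"
    return ratio


def observed_minus_predicted(
    series: pd.DataFrame,
    fit: LoessFit,
    column: str = "n_all",
    min_replicates: int = 8,
) -> pd.DataFrame:
    """Per-group deviations (observed - loess-predicted) for well-replicated groups.

    Groups with fewer than ``min_replicates`` samples are excluded. ``fit``
    should be trained on the full series for ``column``.
    """
    keep = series.groupby("group_label")["sample_id"].transform("count") >= min_replicates
    sub = series[keep].copy()
    if sub.empty:
        return pd.DataFrame(
            columns=["group_label", "sample_id", "depth", "observed", "predicted",
                     "deviation"]
        )
    pred = fit.predict(sub["depth"].to_numpy())
    out = pd.DataFrame(
        {
            "group_label": sub["group_label"].to_numpy(),
            "sample_id": sub["sample_id"].to_numpy(),
            "depth": sub["depth"].to_numpy(),
            "observed": sub[column].to_numpy(dtype=float),
            "predicted": pred,
        }
    )
    out["deviation"] = out["observed"] - out["predicted"]
    return out
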