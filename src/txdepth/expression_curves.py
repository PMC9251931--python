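"""Expression-ranked cumulative statistics.

Transcripts are ranked by expression (descending, ties broken by
transcript_id so every curve is deterministic). Percentiles are rank-based:
percentile = 100 * rank / n, i.e. the share of transcripts at or above a
row. Cumulative expression, cumulative precision (share of reference-matched
transcripts among the top-r) and the cumulative coding:noncoding ratio are
all prefix statistics of this ordering.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import CODING, NONCODING, Assembly


def rank_by_expression(data) -> pd.DataFrame:
    """Build a ranked expression table from an Assembly or a DataFrame.

    DataFrame input needs columns ``transcript_id`` and ``expression``;
    optional ``coding_class``, ``matched`` and ``annotated`` columns are
    carried through. Raises if total expression is zero.
    """
    if isinstance(data, Assembly):
        df = pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in data],
                "expression": [t.expression for t in data],
                "coding_class": [t.coding_class for t in data],
            }
        )
    else:
        df = data.copy()
    if df.empty:
        raise ValueError("no transcripts to rank")
    if (df["expression"] < 0).any():
        raise ValueError("negative expression")
    total = df["expression"].sum()
    if total == 0:
        raise ValueError("all-zero expression: nothing to rank")
    df = df.sort_values(
        ["expression", "transcript_id"], ascending=[False, True]
    ).reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["percentile"] = 100.0 * df["rank"] / n
    cs = np.cumsum(df["expression"].to_numpy())
    # divide by the prefix total so the curve ends at exactly 100%
    df["cum_expression_pct"] = 100.0 * cs / cs[-1]
    return df


def quantile_for_share(table: pd.DataFrame, share: float) -> float:
    """Smallest top-rank percentile whose cumulative expression >= ``share`` %."""
    if not 0 < share <= 100:
        raise ValueError("share must be in (0, 100]")
    hit = table.loc[table["cum_expression_pct"] >= share - 1e-12, "percentile"]
    return float(hit.iloc[0])


def cumulative_precision(table: pd.DataFrame) -> pd.Series:
    """Precision over the top-r transcripts, at each rank r."""
    if "matched" not in table.columns:
        raise ValueError("table needs a 'matched' column")
    m = table["matched"].astype(float).to_numpy()
    curve = np.cumsum(m) / np.arange(1, len(m) + 1)
    return pd.Series(curve, index=table.index, name="cumulative_precision")


def assign_precision_classes(
    table: pd.DataFrame, boundaries: Sequence[float] = (30.0, 60.0)
) -> pd.DataFrame:
    """Split the ranked list into classes A/B/C at rank-percentile boundaries.

    A = percentile <= b1, B = (b1, b2], C = (b2, 100]. Returns the table with
    a ``precision_class`` column; the per-class share of annotated
    transcripts is available via :func:`class_annotated_share`.
    """
    b1, b2 = boundaries
    if not (0 < b1 < b2 < 100):
        raise ValueError("boundaries must be increasing within (0, 100)")
    df = table.copy()
    n = len(df)
    # "top b percent" = the first ceil(b*n/100) ranks, so that short lists
    # still have a top class (a singleton list is all class A)
    r1 = int(np.ceil(b1 * n / 100.0))
    r2 = int(np.ceil(b2 * n / 100.0))
    rank = df["rank"]
    df["precision_class"] = np.where(rank <= r1, "A", np.where(rank <= r2, "B", "C"))
    return df


def class_annotated_share(classed: pd.DataFrame) -> pd.Series:
    """Percentage of annotated transcripts within each precision class."""
    if "annotated" not in classed.columns:
        raise ValueError("table needs an 'annotated' column")
    return classed.groupby("precision_class")["annotated"].mean() * 100.0


def cumulative_class_ratio(table: pd.DataFrame) -> pd.Series:
    """Coding:noncoding ratio among the top-r transcripts, at each rank r.

    Undefined (NaN) until the first noncoding transcript appears.
    """
    if "coding_class" not in table.columns:
        raise ValueError("table needs a 'coding_class' column")
    coding = np.cumsum((table["coding_class"] == CODING).to_numpy())
    noncoding = np.cumsum((table["coding_class"] == NONCODING).to_numpy()).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(noncoding > 0, coding / np.where(noncoding > 0, noncoding, 1), np.nan)
    return pd.Series(ratio, index=table.index, name="cumulative_coding_noncoding_ratio")


def ratio_at_percentile(table: pd.DataFrame, top_pct: float) -> float:
    """Cumulative coding:noncoding ratio at the given top percentile."""
    curve = cumulative_class_ratio(table)
    mask = table["percentile"] <= top_pct
    if not mask.any():
        return float("nan")
    return float(curve[mask].iloc[-1])
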