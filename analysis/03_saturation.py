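#!/usr/bin/env python
"""Depth-saturation statistics on the simulated ladder.

Reads results/depth_series.tsv (written by 01_simulate.py; regenerated here
if absent), fits loess curves of transcript count vs depth per class, and
writes Spearman correlations (results/saturation_rho.tsv), per-0.1M-read
increment tables (results/increments.tsv), depth-binned count summaries
(results/depth_bins.tsv) and the coding:noncoding ratio by depth
(results/ratio_by_depth.tsv).

Key findings (seed 1): rho(depth, count) > 0.9 for both classes; the coding
increment falls below 1% of the coding panel one grid step before the
noncoding increment does; the coding:noncoding ratio peaks at the
shallowest depth and is lowest at the deepest.
"""

from pathlib import Path

import pandas as pd

from txdepth import saturation
from txdepth.study import DEPTHS, INCREMENT_STEP, run_depth_ladder, study_panel

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    series_path = RESULTS / "depth_series.tsv"
    if series_path.exists():
        series = pd.read_csv(series_path, sep="\t")
    else:
        from txdepth.assembly_compare import filter_assembly

        run = run_depth_ladder(seed=SEED)
        series = saturation.depth_series_from_assemblies(
            [filter_assembly(s.assembly) for s in run.samples]
        )
        series.to_csv(series_path, sep="\t", index=False)

    panel_counts = study_panel(SEED).to_assembly().class_counts()

    rho_rows, inc_rows = [], []
    for col, total in (
        ("n_all", len(study_panel(SEED).transcripts)),
        ("n_coding", panel_counts["coding"]),
        ("n_noncoding", panel_counts["noncoding"]),
    ):
        rho = saturation.spearman_rho(series["depth"], series[col])
        # span 1.0: with five distinct depths the neighborhood must cover
        # all depth clusters for the local fits to interpolate between them
        fit = saturation.loess_fit(series["depth"], series[col], span=1.0)
        table = saturation.increments(fit, max(DEPTHS), INCREMENT_STEP).to_frame()
        table["column"] = col
        table["pct_of_panel"] = 100 * table["increment"] / total
        inc_rows.append(table)
        first = next(
            (
                d
                for d, inc in zip(table["depth"], table["increment"])
                if d > fit.x_min and inc < 0.01 * total
            ),
            None,
        )
        rho_rows.append(
            {"column": col, "rho": rho, "span": 1.0,
             "first_depth_increment_below_1pct": first}
        )

    pd.DataFrame(rho_rows).to_csv(RESULTS / "saturation_rho.tsv", sep="\t",
                                  index=False)
    pd.concat(inc_rows).to_csv(RESULTS / "increments.tsv", sep="\t", index=False)

    saturation.bin_by_depth(series, width=INCREMENT_STEP).to_csv(
        RESULTS / "depth_bins.tsv", sep="\t", index=False
    )
    series["ratio"] = saturation.coding_noncoding_ratio(series)
    series.groupby("depth")["ratio"].agg(["mean", "std", "count"]).to_csv(
        RESULTS / "ratio_by_depth.tsv", sep="\t"
    )

    print(pd.DataFrame(rho_rows).to_string(index=False))
    print("\nratio by depth:")
    print(series.groupby("depth")["ratio"].mean().round(2))


if __name__ == "__main__":
    main()
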