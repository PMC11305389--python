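#!/usr/bin/env python
"""Correlation screen: spine traits vs cognition and pathology scores.

Uses the entire complete-case cohort (both halves pooled, n = 125 at the
default size) and computes, per region, Spearman correlations between every
aggregated spine feature and every cognition/pathology score, with Storey
q-value FDR control over each region's grid.  Writes the long-format cell
table and the feature × score rho matrix; cells with q < 0.1 and p < 0.05
carry a single asterisk, q < 0.05 a double asterisk.
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from spinemem import correlation_matrix, filter_complete_cases, heatmap_matrix
from spinemem.experiments import REQUIRED_CASE_COLUMNS, SCORE_COLUMNS
from spinemem.io import read_cases_csv


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fdr", nargs=2, type=float, default=(0.1, 0.05))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    feats = pd.read_csv(args.outdir / "features.csv")
    cases = filter_complete_cases(read_cases_csv(args.outdir / "cases.csv"),
                                  REQUIRED_CASE_COLUMNS)
    grids = []
    for region in sorted(feats.region.unique()):
        sub = feats[feats.region == region]
        grid = correlation_matrix(sub, cases, SCORE_COLUMNS,
                                  fdr_levels=tuple(args.fdr))
        grids.append(grid.assign(region=region))
        n10 = int(grid.sig_q10.sum())
        n05 = int(grid.sig_q05.sum())
        print(f"{region}: {len(grid)} cells, {n10} at q<{args.fdr[0]}, "
              f"{n05} at q<{args.fdr[1]}")
        hd = grid.query("feature == 'mean_head_diameter' and "
                        "score == 'episodic_memory'").iloc[0]
        print(f"    head diameter vs episodic memory: rho {hd.rho:+.3f}, "
              f"p {hd.p_value:.2e}, q {hd.q_value:.2e} {hd.annotation}")
        heatmap_matrix(grid).to_csv(args.outdir / f"heatmap_{region}.csv")
    pd.concat(grids).to_csv(args.outdir / "correlations.csv", index=False)
    print(f"wrote {args.outdir / 'correlations.csv'}")


if __name__ == "__main__":
    main()
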