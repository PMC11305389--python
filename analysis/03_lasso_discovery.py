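#!/usr/bin/env python
"""LASSO discovery: which spine traits associate with episodic memory?

Filters to complete cases, splits them into discovery/validation halves
(63/62 at the default cohort size), and runs L1-penalized regression of
episodic memory on the four spine traits (density, length, head diameter,
volume) of each region's discovery half.  λ is the median CV-minimiser over
1000 reshuffled 10-fold cross-validations of a 100-value grid.  Writes the
per-region coefficient tables (bar-chart data) and the split membership.
"""

import argparse
import json
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from spinemem import (LassoConfig, analysis_table, filter_complete_cases,
                      rank_traits, select_lambda, split_discovery_validation)
from spinemem.experiments import REQUIRED_CASE_COLUMNS, TRAIT_COLUMNS
from spinemem.io import read_cases_csv
from spinemem.lasso import SPINE_TRAITS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--cv-repeats", type=int, default=1000)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    feats = pd.read_csv(args.outdir / "features.csv")
    cases = read_cases_csv(args.outdir / "cases.csv")
    complete = filter_complete_cases(cases, REQUIRED_CASE_COLUMNS)
    disc, val = split_discovery_validation(complete, seed=args.seed)
    print(f"{len(cases)} cases -> {len(complete)} complete -> "
          f"{len(disc)} discovery / {len(val)} validation")
    pd.concat([disc.assign(split="discovery"), val.assign(split="validation")]
              )[["case_id", "split"]].to_csv(args.outdir / "split.csv",
                                             index=False)

    rows = []
    for region in sorted(feats.region.unique()):
        tab = analysis_table(feats, disc, region)
        X = tab[[TRAIT_COLUMNS[t] for t in SPINE_TRAITS]].to_numpy(float)
        y = tab["episodic_memory"].to_numpy(float)
        res = select_lambda(X, y, LassoConfig(cv_repeats=args.cv_repeats,
                                              seed=args.seed))
        ranking = rank_traits(res)
        label = " > ".join(f"{n} ({c:+.3f})" for n, c in ranking) or \
            "null model (all coefficients zero)"
        print(f"{region}: lambda = {res.selected_lambda:.4f}; {label}")
        for trait in SPINE_TRAITS:
            rows.append(dict(region=region, trait=trait,
                             coef=res.coefficients[trait],
                             coef_std=res.coefficients_std[trait],
                             selected_lambda=res.selected_lambda))
    pd.DataFrame(rows).to_csv(args.outdir / "lasso_coefficients.csv",
                              index=False)
    print(f"wrote {args.outdir / 'lasso_coefficients.csv'}")


if __name__ == "__main__":
    main()
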