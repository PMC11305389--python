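#!/usr/bin/env python
"""Nested-model validation: does head diameter add predictive value?

On each region's validation half, compares nested linear models for
episodic memory by leave-one-out cross-validated MSE: the full model (age,
sex, pathology, four spine traits), the full model without age, pathology+
sex plus the focal spine trait, pathology+sex alone, and pathology plus the
focal trait.  Percentile bootstrap intervals (case resampling) accompany
each model's MSE.  Writes the comparison table and per-model observed vs
predicted scores for density plots.
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from spinemem import (analysis_table, compare_models, default_model_specs,
                      filter_complete_cases, reports_frame,
                      split_discovery_validation)
from spinemem.experiments import REQUIRED_CASE_COLUMNS
from spinemem.io import read_cases_csv
from spinemem.validation import attach_bootstrap


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    feats = pd.read_csv(args.outdir / "features.csv")
    cases = read_cases_csv(args.outdir / "cases.csv")
    complete = filter_complete_cases(cases, REQUIRED_CASE_COLUMNS)
    _, val = split_discovery_validation(complete, seed=args.seed)

    frames, preds = [], []
    for region in sorted(feats.region.unique()):
        tab = analysis_table(feats, val, region)
        reports = compare_models(tab, default_model_specs("head_diameter"))
        for rep in reports:
            attach_bootstrap(rep, tab, B=args.bootstrap, level=0.90,
                             seed=args.seed)
            preds.append(pd.DataFrame(dict(
                region=region, model=rep.spec.name,
                observed=rep.observed, predicted=rep.predictions)))
        df = reports_frame(reports).assign(region=region)
        frames.append(df)
        best = reports[0]
        print(f"{region}: best model = {best.spec.name} "
              f"(MSE-CV {best.loocv_mse:.4f}, R2 {best.r_squared:.3f}, "
              f"r {best.pearson_observed_vs_predicted:.3f})")
        for _, r in df.iterrows():
            print(f"    {r.model:32s} MSE {r.loocv_mse:.4f} "
                  f"[{r.mse_ci_lo:.4f}, {r.mse_ci_hi:.4f}]  R2 {r.r_squared:.3f}")
    pd.concat(frames).to_csv(args.outdir / "model_comparison.csv", index=False)
    pd.concat(preds).to_csv(args.outdir / "observed_vs_predicted.csv",
                            index=False)
    print(f"wrote {args.outdir / 'model_comparison.csv'}")


if __name__ == "__main__":
    main()
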