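#!/usr/bin/env python
"""Aggregate spine-level morphometry to the per-case trait table.

Reads the measured spine and segment tables written by 01_simulate_cohort,
computes per (case, region) spine density (per 10 µm, segment-averaged) and
pooled means of length, head diameter and volume — overall and per
morphology class — and writes the feature table the models consume.
"""

import argparse
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from spinemem import aggregate_features
from spinemem.io import read_measured_spines_csv, read_segments_csv


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--aggregation", choices=("pooled", "per_neuron"),
                    default="pooled")
    args = ap.parse_args()

    spines = read_measured_spines_csv(args.outdir / "spines.csv")
    segments = read_segments_csv(args.outdir / "segments.csv")
    feats = aggregate_features(spines, segments, aggregation=args.aggregation)
    feats.to_csv(args.outdir / "features.csv", index=False)

    for region, sub in feats.groupby("region"):
        print(f"{region}: {len(sub)} cases | "
              f"density {sub.mean_density.mean():.2f}/10um | "
              f"head diameter {sub.mean_head_diameter.mean():.3f} um | "
              f"length {sub.mean_length.mean():.2f} um | "
              f"volume {sub.mean_volume.mean():.4f} um^3")
    print(f"wrote {args.outdir / 'features.csv'}")


if __name__ == "__main__":
    main()
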