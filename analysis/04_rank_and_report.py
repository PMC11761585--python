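#!/usr/bin/env python
"""Ranking stage: order the source types by PA amplitude per position.

Reads the initial-PA slices and reconstructed amplitude maps, extracts
the X-profiles at z = 11 / 12 / 13 mm, ranks the sources at x = 7 mm
for each stage, and writes the top-3 maxima / minima tables
(results/ranking_<stage>.csv) plus the full ordering
(results/ranking_full.csv).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pabrain.pipeline import ProfileSet, rank_sources

DEPTHS = (11.0, 12.0, 13.0)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    slices = np.load(args.results / "initial_pa.npz")
    recon = np.load(args.results / "recon.npz")
    sources = [k for k in slices.files if k not in ("seed", "photons")]

    profiles = ProfileSet(sources=tuple(sources))
    for kind in sources:
        fields = {"initial": slices[kind]}
        for stage in ("recon_homo", "recon_hetero"):
            key = f"{kind}:{stage}"
            if key in recon.files:
                fields[stage] = recon[key]
        for stage, field in fields.items():
            profiles.profiles[(kind, stage)] = {
                "z": field[70, :].copy(),
                "x": {z: field[:, int(z * 10)].copy() for z in DEPTHS},
            }

    stages = sorted({s for (_, s) in profiles.profiles})
    full_rows = []
    for stage in stages:
        rows = []
        for z in DEPTHS:
            r = rank_sources(profiles, (7.0, z), stage)
            row = {"z_mm": z}
            for i, (src, val) in enumerate(r.top_maxima, 1):
                row[f"max{i}_source"], row[f"max{i}_value"] = src, val
            for i, (src, val) in enumerate(r.top_minima, 1):
                row[f"min{i}_source"], row[f"min{i}_value"] = src, val
            rows.append(row)
            for rank, (src, val) in enumerate(r.ordered, 1):
                full_rows.append(
                    {"stage": stage, "z_mm": z, "rank": rank, "source": src, "value": val}
                )
            print(f"{stage} z={z:g} mm  max: {[s for s, _ in r.top_maxima]}  "
                  f"min: {[s for s, _ in r.top_minima]}")
        pd.DataFrame(rows).to_csv(args.results / f"ranking_{stage}.csv", index=False)
    pd.DataFrame(full_rows).to_csv(args.results / "ranking_full.csv", index=False)
    print(f"wrote ranking tables under {args.results}/")


if __name__ == "__main__":
    main()
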