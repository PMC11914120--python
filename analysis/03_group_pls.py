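#!/usr/bin/env python
"""Mean-centered PLS across age groups for every (frequency, metric) block.

Each of the ten analyses decomposes the centered group-mean matrix with the
SVD, tests LV1 with 2000 permutations of participants across groups, and
quantifies channel robustness with 2000 within-group bootstraps (bootstrap
ratios ~ z-scores), averaged into sensor-site values for the topography
export.

Reads scratch/features/, writes results/pls/ (per-analysis JSON, channel and
site BSR TSVs, topography tables) and results/pls/summary.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from envtails.pipeline import analyze_block, export_topography, _site_positions
from envtails.synthetic import load_cohort
from envtails.tails import read_feature_block

ROOT = Path(__file__).resolve().parents[1]
SEED = 2026
N_PERM = 2000
N_BOOT = 2000


def main() -> None:
    recordings, design = load_cohort(ROOT / "scratch" / "cohort.npz")
    site_id = recordings[0].site_id
    site_pos = _site_positions(recordings[0].positions, site_id)
    outdir = ROOT / "results" / "pls"
    outdir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(SEED)
    rows = []
    feature_files = sorted((ROOT / "scratch" / "features").glob("features_*.tsv"))
    children = master.spawn(2 * len(feature_files))
    for i, path in enumerate(feature_files):
        block = read_feature_block(path)
        result = analyze_block(
            block, design, site_id, N_PERM, N_BOOT,
            perm_seed=children[2 * i], boot_seed=children[2 * i + 1],
        )
        stem = f"pls_{block.metric}_{block.frequency:g}Hz"
        (outdir / f"{stem}.json").write_text(json.dumps(result, indent=2))
        pd.DataFrame(
            {"channel": np.arange(len(result["bsr_lv1"])), "bsr_lv1": result["bsr_lv1"]}
        ).to_csv(outdir / f"{stem}_channels.tsv", sep="\t", index=False)
        export_topography(
            np.asarray(result["site_bsr_lv1"]), site_pos,
            outdir / f"{stem}_topography.tsv", site_ids=np.unique(site_id),
        )
        rows.append(
            {
                "frequency": block.frequency,
                "metric": block.metric,
                "p_lv1": result["p_lv1"],
                "explained_lv1": result["explained"][0],
                "contrast_lv1": np.round(result["contrast_lv1"], 3).tolist(),
            }
        )
        print(f"  {block.metric:8s} @ {block.frequency:>4g} Hz: "
              f"p = {result['p_lv1']:.4g}, LV1 explains {result['explained'][0]:.0%}")
    summary = pd.DataFrame(rows).sort_values(["frequency", "metric"])
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    print(f"wrote {len(rows)} analyses to {outdir}")


if __name__ == "__main__":
    main()
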