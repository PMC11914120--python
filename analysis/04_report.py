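#!/usr/bin/env python
"""Summarize the group analyses: contrast shapes, significance, effect sites.

Reads results/pls/summary.tsv and the per-analysis JSON, classifies each LV1
contrast as monotonic (rank-perfect in group order) or peaked, counts robust
channels (|BSR| > 3), and writes results/report.md.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

ROOT = Path(__file__).resolve().parents[1]
PLS_DIR = ROOT / "results" / "pls"


def contrast_shape(contrast: np.ndarray) -> str:
    rho = spearmanr(contrast, np.arange(len(contrast))).statistic
    if abs(rho) > 1 - 1e-12:
        return "monotonic"
    interior_peak = int(np.argmax(np.abs(contrast)))
    if 0 < interior_peak < len(contrast) - 1:
        return "peaked (inverted-U-like)"
    return "mixed"


def main() -> None:
    lines = ["# Group-analysis report", ""]
    lines.append("| frequency | metric | p (LV1) | LV1 var. | shape | robust channels |")
    lines.append("|---|---|---|---|---|---|")
    for path in sorted(PLS_DIR.glob("pls_*.json")):
        r = json.loads(path.read_text())
        contrast = np.asarray(r["contrast_lv1"])
        bsr = np.asarray(r["bsr_lv1"])
        robust = np.flatnonzero(np.abs(bsr) > 3)
        shape = contrast_shape(contrast)
        sig = "significant" if r["p_lv1"] < 0.05 else "n.s."
        lines.append(
            f"| {r['frequency']:g} Hz | {r['metric']} | {r['p_lv1']:.4g} ({sig}) "
            f"| {r['explained'][0]:.0%} | {shape} | {len(robust)} |"
        )
        print(f"{r['frequency']:>4g} Hz {r['metric']:8s}: p={r['p_lv1']:.4g} "
              f"{shape}, robust channels: {[int(c) for c in robust]}")
    out = ROOT / "results" / "report.md"
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
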