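#!/usr/bin/env python
"""Narrate the relevance analysis of the trained experiment.

Reads the similarity table and shortcut summary written by
04_train_configurations.py and reports (a) how similar each alternative
model's mean heatmap is to the skull-stripped reference (A2) and (b) the
boundary relevance share — the fraction of top-10% relevance voxels inside
a 2-voxel shell around the brain-mask contour, the quantitative signature
of the skull-stripping shortcut.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"
EXP = RESULTS / "experiment"

if not (EXP / "similarity.tsv").exists():
    raise SystemExit("run analysis/04_train_configurations.py first")

similarity = pd.read_csv(EXP / "similarity.tsv", sep="\t")
cols = ["configuration", "n_pairs", "rmse_mean", "pearson_mean",
        "mssim_mean", "emd_mean", "iou_top40_mean", "iou_top10_mean"]
print("mean heatmap similarity vs reference A2 (per aligned session pair):")
print(similarity[cols].to_string(index=False))
print()

summary = json.loads((EXP / "summary.json").read_text())
shortcut = summary["shortcut"]
print("boundary relevance share (top-10% relevance within the 2-voxel "
      "mask-contour shell):")
for cid in sorted(shortcut):
    s = shortcut[cid]
    print(f"  {cid}: boundary {s['boundary_share']:.3f}  "
          f"interior {s['interior_share']:.3f}  "
          f"exterior {s['exterior_share']:.3f}")
stripped = [s for c, s in shortcut.items() if c.endswith("2")]
aligned = [s for c, s in shortcut.items() if c.endswith("1")]
if stripped and aligned:
    ms = sum(s["boundary_share"] for s in stripped) / len(stripped)
    ma = sum(s["boundary_share"] for s in aligned) / len(aligned)
    print(f"\nmean boundary share: skull-stripped {ms:.3f} vs aligned {ma:.3f}")
    if ms > ma:
        print("the contour introduced by skull-stripping attracts relevance "
              "at this seed; the multi-seed acceptance check quantifies how "
              "consistently.")
    else:
        print("at this single seed the aligned models also concentrate on "
              "the brain edge (it borders the bright skull); the multi-seed "
              "acceptance check is the reliable comparison.")
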