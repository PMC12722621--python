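#!/usr/bin/env python
"""Narrate the paired statistics and the relevance-map clustering.

Reads the exact-McNemar comparison table (discrete Bonferroni-Holm
corrected) and the spectral clustering of the reference model's relevance
maps written by 04_train_configurations.py.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"
EXP = RESULTS / "experiment"

if not (EXP / "comparisons.tsv").exists():
    raise SystemExit("run analysis/04_train_configurations.py first")

comparisons = pd.read_csv(EXP / "comparisons.tsv", sep="\t")
summary = json.loads((EXP / "summary.json").read_text())

print(f"{summary['significant_comparisons']} of "
      f"{summary['total_comparisons']} exact McNemar comparisons against "
      "the reference model remain significant after discrete Holm "
      "correction")
by_config = comparisons.groupby("configuration")["significant"].sum()
print("significant comparisons per configuration:")
print(by_config.to_string())
print()
print("smallest raw p-values:")
print(comparisons.nsmallest(5, "p_value")[
    ["configuration", "metric", "n01", "n10", "p_value", "significant"]
].to_string(index=False))

clusters = EXP / "clusters.tsv"
if clusters.exists():
    tab = pd.read_csv(clusters, sep="\t")
    print(f"\nspectral clustering of the reference model's relevance maps: "
          f"{tab['cluster'].nunique()} cluster(s) over {len(tab)} maps")
    print(tab["cluster"].value_counts().to_string())
else:
    print("\ntoo few relevance maps for clustering at this profile")
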